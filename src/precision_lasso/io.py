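"""Dataset loading: CSV tables and PLINK1 binary genotype filesets.

CSV convention: header row carries variable names, the first column carries
sample IDs; every remaining cell must be numeric and present. The optional
phenotype file is one value per sample, matched by position.

PLINK1 .bed files are parsed in SNP-major mode (magic bytes 0x6c 0x1b 0x01)
with the canonical two-bit encoding — 00 hom A1, 01 missing, 10 het,
11 hom A2 — and dosage counted on the A1 allele (0/1/2). Missing genotypes
are imputed to the per-variant mean of observed dosages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "read_csv_dataset",
    "write_csv_dataset",
    "read_plink_dataset",
    "write_plink_dataset",
    "write_coefficients_tsv",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
#: two-bit code -> A1 dosage (code 1 is missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_FAM_MISSING_PHENO = {-9.0, 0.0}


@dataclass
class Dataset:
    X: DesignMatrix
    y: np.ndarray | None
    sample_ids: list[str]
    source: str


def _require_numeric(df: pd.DataFrame, path) -> np.ndarray:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    missing = df.isna()
    nonnum = coerced.isna() & ~missing
    problems = []
    for mask, what in ((missing, "missing"), (nonnum, "non-numeric")):
        if mask.to_numpy().any():
            locs = np.argwhere(mask.to_numpy())[:5]
            cells = [f"(row {df.index[i]!r}, column {df.columns[j]!r})" for i, j in locs]
            problems.append(f"{int(mask.to_numpy().sum())} {what} cell(s), e.g. {', '.join(cells)}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return coerced.to_numpy(dtype=float)


def read_csv_dataset(x_path, y_path=None) -> Dataset:
    """Load a design matrix (and optional phenotype) from CSV."""
    x_path = Path(x_path)
    if not x_path.exists():
        raise FileNotFoundError(f"design file not found: {x_path}")
    try:
        df = pd.read_csv(x_path, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{x_path}: malformed CSV ({exc})") from exc
    if df.shape[1] < 1:
        raise ValueError(f"{x_path}: no variable columns after the sample-ID column")
    values = _require_numeric(df, x_path)
    sample_ids = [str(i) for i in df.index]
    X = DesignMatrix(values, [str(c) for c in df.columns])

    y = None
    if y_path is not None:
        y_path = Path(y_path)
        if not y_path.exists():
            raise FileNotFoundError(f"phenotype file not found: {y_path}")
        ydf = pd.read_csv(y_path, float_precision="round_trip")
        col = ydf.iloc[:, -1] if ydf.shape[1] >= 2 else ydf.iloc[:, 0]
        y = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        if y.shape[0] != X.n:
            raise ValueError(
                f"{y_path}: {y.shape[0]} phenotype values for {X.n} samples"
            )
        if np.isnan(y).any():
            raise ValueError(f"{y_path}: non-numeric or missing phenotype values")
    return Dataset(X=X, y=y, sample_ids=sample_ids, source="csv")


def write_csv_dataset(X: DesignMatrix, y, sample_ids, x_path, y_path=None) -> None:
    """Write X (and optionally y) in the CSV dialect read_csv_dataset expects.

    Floats are written at 17 significant digits, so the round trip is
    lossless for finite doubles.
    """
    ids = [str(s) for s in sample_ids]
    pd.DataFrame(X.values, index=ids, columns=X.column_names).to_csv(
        x_path, float_format="%.17g", index_label="sample_id"
    )
    if y_path is not None and y is not None:
        pd.DataFrame({"y": np.asarray(y, dtype=float)}, index=ids).to_csv(
            y_path, float_format="%.17g", index_label="sample_id"
        )


def _encode_bed_column(dosages: np.ndarray) -> bytes:
    """Pack one variant's 0/1/2/NaN dosages into PLINK1 two-bit codes."""
    codes = np.full(dosages.shape[0], 1, dtype=np.uint8)  # missing
    codes[dosages == 2.0] = 0
    codes[dosages == 1.0] = 2
    codes[dosages == 0.0] = 3
    n = codes.shape[0]
    nbytes = (n + 3) // 4
    padded = np.zeros(nbytes * 4, dtype=np.uint8)
    padded[:n] = codes
    padded[n:] = 3  # pad with hom A2 (dosage 0), the PLINK convention
    byte_view = padded.reshape(-1, 4)
    out = (byte_view[:, 0]
           | (byte_view[:, 1] << 2)
           | (byte_view[:, 2] << 4)
           | (byte_view[:, 3] << 6))
    return out.astype(np.uint8).tobytes()


def _decode_bed_bytes(raw: np.ndarray, n_samples: int) -> np.ndarray:
    """Unpack one variant's bytes into dosages with NaN for missing."""
    codes = np.empty(raw.shape[0] * 4, dtype=np.uint8)
    for k in range(4):
        codes[k::4] = (raw >> (2 * k)) & 0b11
    return _CODE_TO_DOSAGE[codes[:n_samples]]


def write_plink_dataset(
    prefix,
    genotypes: np.ndarray,
    sample_ids,
    variant_ids,
    phenotypes=None,
) -> None:
    """Write a .bed/.bim/.fam fileset from a 0/1/2 dosage matrix
    (NaN = missing genotype). Intended for small synthetic filesets."""
    prefix = Path(prefix)
    geno = np.asarray(genotypes, dtype=float)
    n, p = geno.shape
    sample_ids = [str(s) for s in sample_ids]
    variant_ids = [str(v) for v in variant_ids]
    if phenotypes is None:
        phenotypes = [-9] * n
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid, ph in zip(sample_ids, phenotypes):
            fh.write(f"{sid} {sid} 0 0 0 {ph:g}\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, vid in enumerate(variant_ids):
            fh.write(f"1\t{vid}\t0\t{j + 1}\tA\tB\n")
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(p):
            fh.write(_encode_bed_column(geno[:, j]))


def read_plink_dataset(prefix) -> Dataset:
    """Load a PLINK1 .bed/.bim/.fam fileset as 0/1/2 A1 dosages.

    Missing genotypes are imputed to the per-variant mean (count logged);
    all-missing variants are dropped with a warning. The .fam phenotype
    column becomes y unless every value is the missing code (-9 or 0).
    """
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(ext) for ext in (".bed", ".bim", ".fam")}
    for ext, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"PLINK member file not found: {path}")
    fam = pd.read_csv(paths[".fam"], sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    bim = pd.read_csv(paths[".bim"], sep=r"\s+", header=None,
                      names=["chrom", "vid", "cm", "pos", "a1", "a2"])
    n, p = fam.shape[0], bim.shape[0]
    raw = np.fromfile(paths[".bed"], dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(
            f"{paths['.bed']}: bad magic bytes {raw[:3].tobytes()!r} "
            "(expected PLINK1 SNP-major 6c 1b 01)"
        )
    nbytes = (n + 3) // 4
    body = raw[3:]
    if body.shape[0] != nbytes * p:
        raise ValueError(
            f"{paths['.bed']}: expected {nbytes * p} data bytes for "
            f"{n} samples x {p} variants, found {body.shape[0]}"
        )
    body = body.reshape(p, nbytes)

    columns, names = [], []
    n_imputed = 0
    for j in range(p):
        dos = _decode_bed_bytes(body[j], n)
        miss = np.isnan(dos)
        if miss.all():
            logger.warning("variant %s has no observed genotypes; dropped",
                           bim["vid"].iloc[j])
            continue
        if miss.any():
            dos[miss] = float(dos[~miss].mean())
            n_imputed += int(miss.sum())
        columns.append(dos)
        names.append(str(bim["vid"].iloc[j]))
    if n_imputed:
        logger.info("imputed %d missing genotype(s) to per-variant means", n_imputed)
    if not columns:
        raise ValueError(f"{prefix}: no variants with observed genotypes")
    X = DesignMatrix(np.column_stack(columns), names)

    pheno = pd.to_numeric(fam["pheno"], errors="coerce").to_numpy(dtype=float)
    y = None if set(np.unique(pheno)) <= _FAM_MISSING_PHENO else pheno
    return Dataset(X=X, y=y, sample_ids=[str(s) for s in fam["iid"]], source="plink")


def write_coefficients_tsv(path, column_names, beta, selected) -> None:
    """Coefficient output: TSV with columns variable, beta, selected(0/1)."""
    sel = set(int(i) for i in selected)
    with open(path, "w") as fh:
        fh.write("variable\tbeta\tselected\n")
        for j, name in enumerate(column_names):
            fh.write(f"{name}\t{beta[j]:.17g}\t{int(j in sel)}\n")
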