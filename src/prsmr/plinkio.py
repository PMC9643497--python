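"""PLINK1 bed/bim/fam and delimited-text I/O.

The .bed codec is the variant-major PLINK1 format (magic bytes
``0x6c 0x1b 0x01``): one genotype per sample packed two bits at a time,
least-significant bits first, one byte row per four samples.

Two-bit codes (counting the A1 allele):

====  ==========================
code  meaning
====  ==========================
0b00  homozygous A1/A1 (dose 2)
0b01  missing
0b10  heterozygous   (dose 1)
0b11  homozygous A2/A2 (dose 0)
====  ==========================
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# byte value -> four dosages (np.nan for missing), sample order low bits first
_DECODE = np.empty((256, 4), dtype=np.float64)
for _b in range(256):
    for _k in range(4):
        code = (_b >> (2 * _k)) & 0b11
        _DECODE[_b, _k] = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}[code]

_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}

BIM_COLS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
FAM_COLS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def write_bed(prefix: str | Path, dosages: np.ndarray, variants: pd.DataFrame,
              sample_ids: list[str] | pd.Series) -> dict[str, Path]:
    """Write a samples x variants dosage matrix as a PLINK1 triplet.

    ``dosages`` holds A1-allele counts in {0, 1, 2} with NaN for missing.
    ``variants`` needs columns snp_id, chrom, pos, a1, a2.
    """
    prefix = Path(prefix)
    n, m = dosages.shape
    if len(variants) != m:
        raise ValueError(f"variants table has {len(variants)} rows for {m} dosage columns")
    if len(sample_ids) != n:
        raise ValueError(f"{len(sample_ids)} sample ids for {n} dosage rows")

    # codes per entry, then pack 4 samples/byte, variant-major
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    d = dosages.T
    for dose, code in _ENCODE.items():
        codes[d == dose] = code
    n_bytes = (n + 3) // 4
    padded = np.ones((m, n_bytes * 4), dtype=np.uint8) * 0b11  # pad with hom A2 (ignored)
    padded[:, :n] = codes
    shifted = padded.reshape(m, n_bytes, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = np.bitwise_or.reduce(shifted, axis=2).astype(np.uint8)

    bed = prefix.with_suffix(".bed")
    with open(bed, "wb") as fh:
        fh.write(_MAGIC)
        packed.tofile(fh)

    bim = prefix.with_suffix(".bim")
    pd.DataFrame({
        "chrom": variants["chrom"].values,
        "snp_id": variants["snp_id"].values,
        "cm": 0,
        "pos": variants["pos"].values,
        "a1": variants["a1"].values,
        "a2": variants["a2"].values,
    }).to_csv(bim, sep="\t", header=False, index=False)

    fam = prefix.with_suffix(".fam")
    pd.DataFrame({
        "fid": list(sample_ids),
        "iid": list(sample_ids),
        "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
    }).to_csv(fam, sep="\t", header=False, index=False)
    return {"bed": bed, "bim": bim, "fam": fam}


def read_bed(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK1 triplet; returns (dosages, variants, samples).

    Dosages are A1-allele counts (float, NaN = missing), samples x variants.
    """
    prefix = Path(prefix)
    bed = prefix.with_suffix(".bed")
    if not bed.exists():
        raise FileNotFoundError(f"missing PLINK bed file: {bed}")
    variants = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                           names=BIM_COLS, dtype={"chrom": str, "a1": str, "a2": str})
    samples = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                          names=FAM_COLS, dtype={"fid": str, "iid": str})
    n, m = len(samples), len(variants)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{bed}: not a variant-major PLINK1 bed file")
    body = raw[3:]
    if body.size != m * n_bytes:
        raise ValueError(f"{bed}: expected {m * n_bytes} data bytes, found {body.size}")
    decoded = _DECODE[body.reshape(m, n_bytes)].reshape(m, n_bytes * 4)[:, :n]
    return decoded.T.copy(), variants, samples


GWAS_COLS = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N", "INFO"]


def write_gwas(path: str | Path, gwas: pd.DataFrame) -> Path:
    """Write base summary statistics as tab-delimited text with header."""
    path = Path(path)
    gwas.to_csv(path, sep="\t", index=False, columns=GWAS_COLS, na_rep="NA")
    return path


def read_gwas(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = [c for c in GWAS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: summary statistics missing columns {missing}")
    return df


def write_phenotypes(path: str | Path, cohort: pd.DataFrame) -> Path:
    """Write the phenotype/covariate table (FID IID first, NA for missing)."""
    path = Path(path)
    out = cohort.copy()
    out.insert(0, "IID", out["sample_id"])
    out.insert(0, "FID", out["sample_id"])
    out = out.drop(columns=["sample_id"])
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"FID": str, "IID": str})
    df = df.rename(columns={"IID": "sample_id"}).drop(columns=["FID"])
    return df


def ensure_writable(directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise PermissionError(f"output directory not writable: {directory}")
    return directory
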