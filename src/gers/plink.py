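"""Minimal PLINK-1 binary genotype I/O (.bed/.bim/.fam).

Only the variant-major .bed layout (magic ``6c 1b 01``) is supported, which is
the layout every tool since PLINK 1.07 writes.  Genotypes are exposed as counts
of the A1 allele in {0, 1, 2} with ``nan`` for missing, i.e. the same
orientation PLINK uses for ``--score``.

Two-bit codes per sample (little-endian within each byte):

====  =========================
code  meaning
====  =========================
0b00  homozygous A1 (count 2)
0b01  missing
0b10  heterozygous (count 1)
0b11  homozygous A2 (count 0)
====  =========================
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# code -> A1 allele count; 1 (missing) -> nan
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLS = ["chrom", "id", "cm", "pos", "a1", "a2"]
FAM_COLS = ["FID", "IID", "father", "mother", "sex", "pheno"]


def read_bim(prefix: str) -> pd.DataFrame:
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, names=BIM_COLS,
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    return bim


def read_fam(prefix: str) -> pd.DataFrame:
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, names=FAM_COLS,
                      dtype={"FID": str, "IID": str})
    return fam


def read_plink(prefix: str) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read ``prefix``.bed/.bim/.fam.

    Returns
    -------
    (fam, bim, calls)
        ``calls`` is a ``(n_samples, n_variants)`` float array of A1-allele
        counts with ``nan`` for missing genotypes.
    """
    fam = read_fam(prefix)
    bim = read_bim(prefix)
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(
                f"{prefix}.bed is not a variant-major PLINK-1 .bed file "
                f"(magic bytes {magic.hex()})")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_variant = (n + 3) // 4
    if data.size != bytes_per_variant * m:
        raise ValueError(
            f"{prefix}.bed has {data.size} payload bytes; expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants")
    data = data.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    calls = _DECODE[codes[:, :n]].T  # -> samples x variants
    return fam, bim, np.ascontiguousarray(calls)


def write_plink(prefix: str, fam: pd.DataFrame, bim: pd.DataFrame,
                calls: np.ndarray) -> None:
    """Write ``prefix``.bed/.bim/.fam from A1-allele counts (nan = missing)."""
    n, m = calls.shape
    if len(fam) != n or len(bim) != m:
        raise ValueError("calls shape does not match fam/bim lengths")
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    fam_out = fam.copy()
    for col, default in [("father", 0), ("mother", 0), ("sex", 0), ("pheno", -9)]:
        if col not in fam_out:
            fam_out[col] = default
    fam_out[FAM_COLS].to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim_out = bim.copy()
    if "cm" not in bim_out:
        bim_out["cm"] = 0
    bim_out[BIM_COLS].to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    # encode: count 2 -> 0b00, missing -> 0b01, 1 -> 0b10, 0 -> 0b11
    codes = np.where(np.isnan(calls), 1,
                     np.where(calls == 2, 0, np.where(calls == 1, 2, 3)))
    codes = codes.astype(np.uint8).T  # variant-major
    pad = (-n) % 4
    if pad:
        # pad codes are zero bits per the spec; 0b00 filler is what plink emits
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    packed = np.zeros((m, codes.shape[1] // 4), dtype=np.uint8)
    for shift in range(4):
        packed |= codes[:, shift::4] << (2 * shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
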