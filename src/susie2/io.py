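"""Readers and writers for genotypes, phenotypes, LD, and fit tables.

Genotypes are accepted as PLINK bed/bim/fam triples or as delimited
numeric matrices (samples x variants); phenotypes and LD matrices as
delimited text.  Fits are emitted as tab-delimited per-variant tables
plus a JSON run manifest (configuration echo, seed, convergence info).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_genotypes",
    "read_plink",
    "read_matrix",
    "read_vector",
    "write_fit_table",
    "write_manifest",
]

_BED_MAGIC = b"\x6c\x1b\x01"


def read_plink(prefix: str | Path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK 1 bed/bim/fam triple.

    Returns ``(X, bim, fam)`` where ``X`` is an ``n x p`` dosage matrix
    counting copies of the bim A1 allele (NaN for missing), in
    SNP-major order as written by PLINK.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1 bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * p:
        raise ValueError(
            f"{prefix}.bed: expected {bytes_per_snp * p} data bytes, got {body.size}"
        )
    body = body.reshape(p, bytes_per_snp)
    # unpack 2-bit codes: 0 -> hom A1 (2 copies), 1 -> missing, 2 -> het, 3 -> hom A2
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    lookup = np.array([2.0, np.nan, 1.0, 0.0])
    return lookup[codes].T.copy(), bim, fam


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace/comma-delimited numeric matrix (no header)."""
    try:
        arr = np.loadtxt(path, ndmin=2, comments="#")
    except ValueError:
        arr = np.loadtxt(path, ndmin=2, comments="#", delimiter=",")
    return arr


def read_vector(path: str | Path) -> np.ndarray:
    """Read a single-column phenotype/expression vector."""
    arr = read_matrix(path)
    if arr.ndim == 2 and 1 in arr.shape:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"{path}: expected a single column, got shape {arr.shape}")
    return arr


def read_genotypes(path: str | Path) -> np.ndarray:
    """Read genotypes from a PLINK prefix or a delimited matrix file."""
    path = Path(path)
    if path.with_suffix(".bed").exists() and not path.exists():
        return read_plink(path)[0]
    if path.suffix == ".bed":
        return read_plink(path.with_suffix(""))[0]
    return read_matrix(path)


def write_fit_table(
    path: str | Path,
    fit,
    variant_ids: list[str] | None = None,
    prior: np.ndarray | None = None,
    extra: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Write a per-variant table: id, PIP, credible-set id, purity.

    ``fit`` is a :class:`~susie2.susie.SusieFit`; variants in no
    credible set get an empty ``cs`` field.  Returns the table.
    """
    p = fit.pip.size
    if variant_ids is None:
        variant_ids = [f"snp{j + 1}" for j in range(p)]
    cs_id = np.array([""] * p, dtype=object)
    purity = np.full(p, np.nan)
    for i, cs in enumerate(fit.credible_sets, start=1):
        for j in cs.members:
            cs_id[j] = f"CS{i}"
            purity[j] = cs.purity
    table = pd.DataFrame({"variant": variant_ids, "pip": fit.pip})
    if prior is not None:
        table.insert(1, "prior", prior)
    if extra:
        for name, values in extra.items():
            table[name] = values
    table["cs"] = cs_id
    table["purity"] = purity
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    return table


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (config echo, seed, convergence info)."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return str(obj)

    Path(path).write_text(json.dumps(entries, indent=2, default=default) + "\n")
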