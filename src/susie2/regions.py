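"""GWAS summary-statistics parsing, filtering, and candidate regions.

Loads delimited summary-statistic tables under a small dialect map of
common column names, applies minor-allele-frequency and per-SNP
sample-size filters, and builds candidate fine-mapping regions by
windowing around genome-wide-significant hits and transitively merging
overlapping windows.  Positions are 1-based inclusive throughout (the
bim/sumstat convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SumstatRecord",
    "RegionSpec",
    "load_and_filter_sumstats",
    "define_candidate_regions",
    "harmonize_alleles",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

# recognized header spellings, lower-cased, per canonical field
_DIALECTS: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "rsid", "rs_id", "variant", "variant_id", "id", "markername"),
    "chrom": ("chr", "chrom", "chromosome", "#chrom"),
    "pos": ("bp", "pos", "position", "base_pair_location"),
    "a1": ("a1", "ea", "effect_allele", "alt", "allele1"),
    "a2": ("a2", "oa", "nea", "other_allele", "ref", "allele2"),
    "z": ("z", "zscore", "z_score", "stat"),
    "beta": ("beta", "b", "effect", "effect_size", "log_odds"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "p_value": ("p", "pval", "p_value", "pvalue"),
    "n": ("n", "n_samples", "sample_size", "neff", "n_total"),
    "maf": ("maf", "freq", "eaf", "af", "a1freq", "effect_allele_frequency"),
}


@dataclass
class SumstatRecord:
    """One summary-statistic row after parsing and harmonization."""

    snp: str
    chrom: str
    pos: int
    a1: str | None = None
    a2: str | None = None
    z: float | None = None
    beta: float | None = None
    se: float | None = None
    p_value: float | None = None
    n: float | None = None
    maf: float | None = None

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp}: position must be >= 1, got {self.pos}")
        for allele in (self.a1, self.a2):
            if allele is not None and allele not in _VALID_ALLELES:
                logger.warning("%s: non-SNV or unrecognized allele %r", self.snp, allele)
        if self.z is not None and self.p_value is not None and self.p_value > 0:
            implied = 2.0 * norm.sf(abs(self.z))
            if implied > 0 and not (
                0.9 <= self.p_value / implied <= 1.1 or abs(self.p_value - implied) < 1e-12
            ):
                raise ValueError(
                    f"{self.snp}: p-value {self.p_value:.3g} inconsistent with "
                    f"z={self.z:.3f} (implies {implied:.3g})"
                )

    @property
    def zscore(self) -> float | None:
        """z, falling back to beta/se."""
        if self.z is not None:
            return self.z
        if self.beta is not None and self.se is not None and self.se > 0:
            return self.beta / self.se
        return None

    @property
    def pvalue(self) -> float | None:
        """Two-sided normal p-value, derived from z when absent."""
        if self.p_value is not None:
            return self.p_value
        zs = self.zscore
        return None if zs is None else float(2.0 * norm.sf(abs(zs)))

    def is_strand_ambiguous(self) -> bool:
        if self.a1 is None or self.a2 is None:
            return False
        return frozenset((self.a1, self.a2)) in _AMBIGUOUS_PAIRS


@dataclass
class RegionSpec:
    """A candidate fine-mapping region (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)
    index_signals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def overlaps(self, other: "RegionSpec") -> bool:
        """Interval intersection, shared endpoints included."""
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start
        )


def _resolve_columns(
    header: list[str], overrides: dict[str, str] | None
) -> dict[str, str]:
    overrides = overrides or {}
    lower = {c.lower(): c for c in header}
    mapping: dict[str, str] = {}
    for fieldname, aliases in _DIALECTS.items():
        if fieldname in overrides:
            if overrides[fieldname] not in header:
                raise ValueError(
                    f"column {overrides[fieldname]!r} (for {fieldname}) not in header"
                )
            mapping[fieldname] = overrides[fieldname]
            continue
        hits = [lower[a] for a in aliases if a in lower]
        if len(hits) > 1:
            raise ValueError(
                f"ambiguous columns for {fieldname!r}: {hits}; "
                "disambiguate with an explicit column mapping"
            )
        if hits:
            mapping[fieldname] = hits[0]
    return mapping


def load_and_filter_sumstats(
    path,
    maf_min: float = 0.01,
    n_min: float | None = None,
    columns: dict[str, str] | None = None,
) -> list[SumstatRecord]:
    """Load a delimited summary-statistics table and apply QC filters.

    Rows with minor allele frequency below ``maf_min`` (allele
    frequencies are folded to the minor allele) or per-SNP sample size
    below ``n_min`` are removed; removal counts are logged.  An empty
    result after filtering, and malformed rows, raise errors.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    mapping = _resolve_columns(list(df.columns), columns)
    for required in ("snp", "chrom", "pos"):
        if required not in mapping:
            raise ValueError(
                f"{path}: could not identify a column for {required!r} "
                f"in header {list(df.columns)}"
            )

    records: list[SumstatRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        raw = dict(zip(df.columns, row))

        def get(fieldname, cast=float):
            col = mapping.get(fieldname)
            if col is None:
                return None
            val = raw[col]
            if pd.isna(val):
                return None
            try:
                return cast(val)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path} line {i}: bad value {val!r} in column {col!r}"
                ) from exc

        rec = SumstatRecord(
            snp=str(raw[mapping["snp"]]),
            chrom=str(raw[mapping["chrom"]]),
            pos=get("pos", int),
            a1=get("a1", lambda v: str(v).upper()),
            a2=get("a2", lambda v: str(v).upper()),
            z=get("z"),
            beta=get("beta"),
            se=get("se"),
            p_value=get("p_value"),
            n=get("n"),
            maf=get("maf"),
        )
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
        records.append(rec)

    n_in = len(records)
    if maf_min > 0:
        kept = []
        for r in records:
            if r.maf is None:
                kept.append(r)
                continue
            folded = min(r.maf, 1.0 - r.maf)
            if folded >= maf_min:
                kept.append(r)
        logger.info("MAF filter (< %g): removed %d of %d", maf_min, n_in - len(kept), n_in)
        records = kept
    if n_min is not None:
        before = len(records)
        records = [r for r in records if r.n is None or r.n >= n_min]
        logger.info("N filter (< %g): removed %d of %d", n_min, before - len(records), before)
    if not records:
        raise ValueError(f"{path}: no records left after filtering")
    return records


def define_candidate_regions(
    records: list[SumstatRecord],
    p_threshold: float = 5e-7,
    window_bp: int = 50_000,
) -> list[RegionSpec]:
    """Build candidate regions around significant association signals.

    Each hit with p-value below ``p_threshold`` seeds a window
    ``[pos - window_bp, pos + window_bp]`` (clamped at 1); overlapping
    or touching windows on the same chromosome are merged transitively.
    Member variants are assigned by position.  No significant hits
    yields an empty list.
    """
    hits = [
        r for r in records if r.pvalue is not None and r.pvalue < p_threshold
    ]
    if not hits:
        return []
    hits.sort(key=lambda r: (r.chrom, r.pos))

    merged: list[RegionSpec] = []
    for r in hits:
        win = RegionSpec(
            chrom=r.chrom,
            start=max(1, r.pos - window_bp),
            end=r.pos + window_bp,
            index_signals=[r.snp],
        )
        if merged and merged[-1].overlaps(win):
            merged[-1].end = max(merged[-1].end, win.end)
            merged[-1].index_signals.extend(win.index_signals)
        else:
            merged.append(win)

    for region in merged:
        region.members = [
            r.snp
            for r in records
            if r.chrom == region.chrom and region.start <= r.pos <= region.end
        ]
    return merged


def harmonize_alleles(
    target: SumstatRecord,
    other_a1: str,
    other_a2: str,
) -> int:
    """Align another dataset's allele coding to ``target``.

    Matching is on the unordered allele pair.  Returns ``+1`` when
    effect alleles agree, ``-1`` when they are swapped (flip the z
    sign), and raises when the allele pairs differ.  Strand-ambiguous
    variants are logged.
    """
    a1, a2 = other_a1.upper(), other_a2.upper()
    if target.a1 is None or target.a2 is None:
        raise ValueError(f"{target.snp}: target record lacks alleles")
    if target.is_strand_ambiguous():
        logger.warning("%s: strand-ambiguous allele pair %s/%s", target.snp, a1, a2)
    if (target.a1, target.a2) == (a1, a2):
        return 1
    if (target.a1, target.a2) == (a2, a1):
        return -1
    raise ValueError(
        f"allele mismatch at {target.snp}: {target.a1}/{target.a2} vs {a1}/{a2}"
    )
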