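"""Replicate-level benchmarking of fine-mapping output.

Metrics follow the standard credible-set accounting:

* **power** — proportion of true causal SNPs included in at least one
  credible set;
* **coverage** — proportion of credible sets containing at least one
  true causal SNP;
* **average size** — mean cardinality of the detected credible sets.

Power and coverage are reported both pooled over replicates (total
counts) and as per-replicate means with empirical standard errors.
Coverage is undefined — reported as missing, never zero — when no
credible sets were produced.

PIP calibration groups pooled SNPs into evenly spaced PIP bins and
compares each bin's mean predicted PIP with its fraction of truly
causal SNPs; a calibrated method tracks the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .susie import CredibleSet

__all__ = ["EvalReport", "CalibrationTable", "evaluate_credible_sets", "pip_calibration"]


@dataclass
class EvalReport:
    """Power / coverage / size summary over replicates."""

    power: float                    # pooled over replicates
    coverage: float | None          # pooled; None when no CS was produced
    avg_size: float | None
    n_cs: int
    power_mean: float               # mean of per-replicate power
    coverage_mean: float | None     # mean over replicates with >= 1 CS
    se: dict = field(default_factory=dict)
    per_replicate: list = field(default_factory=list)


@dataclass
class CalibrationTable:
    """Binned PIP calibration (right-closed bins on [0, 1])."""

    bin_edges: np.ndarray
    mean_pip: np.ndarray            # NaN for empty bins
    causal_frac: np.ndarray         # NaN for empty bins
    counts: np.ndarray


def _members(cs: CredibleSet | set | frozenset | tuple | list) -> set[int]:
    if isinstance(cs, CredibleSet):
        return set(cs.members)
    return set(int(j) for j in cs)


def evaluate_credible_sets(cs_lists, causal_sets) -> EvalReport:
    """Score per-replicate credible sets against per-replicate truth.

    Parameters
    ----------
    cs_lists
        One list of credible sets (``CredibleSet`` or plain index
        collections) per replicate.
    causal_sets
        The true causal index set for each replicate, aligned by
        position with ``cs_lists``.
    """
    if len(cs_lists) != len(causal_sets):
        raise ValueError(
            f"{len(cs_lists)} replicates of credible sets vs "
            f"{len(causal_sets)} truth sets"
        )

    tot_causal = tot_captured = tot_cs = tot_covered = tot_size = 0
    per_rep = []
    powers, coverages = [], []
    for rep, (css, causal) in enumerate(zip(cs_lists, causal_sets)):
        causal = set(int(j) for j in causal)
        members = [_members(cs) for cs in css]
        captured = {j for m in members for j in m & causal}
        covered = sum(1 for m in members if m & causal)
        sizes = [len(m) for m in members]

        tot_causal += len(causal)
        tot_captured += len(captured)
        tot_cs += len(members)
        tot_covered += covered
        tot_size += sum(sizes)

        rep_power = len(captured) / len(causal) if causal else np.nan
        rep_cov = covered / len(members) if members else None
        if causal:
            powers.append(rep_power)
        if members:
            coverages.append(rep_cov)
        per_rep.append(
            {
                "replicate": rep,
                "n_causal": len(causal),
                "n_captured": len(captured),
                "power": rep_power,
                "n_cs": len(members),
                "coverage": rep_cov,
                "avg_size": float(np.mean(sizes)) if sizes else None,
            }
        )

    def _se(vals: list[float]) -> float | None:
        if len(vals) < 2:
            return None
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    return EvalReport(
        power=tot_captured / tot_causal if tot_causal else np.nan,
        coverage=tot_covered / tot_cs if tot_cs else None,
        avg_size=tot_size / tot_cs if tot_cs else None,
        n_cs=tot_cs,
        power_mean=float(np.mean(powers)) if powers else np.nan,
        coverage_mean=float(np.mean(coverages)) if coverages else None,
        se={"power": _se(powers), "coverage": _se(coverages)},
        per_replicate=per_rep,
    )


def pip_calibration(
    pips: np.ndarray,
    causal_mask: np.ndarray,
    n_bins: int = 10,
) -> CalibrationTable:
    """Bin pooled PIPs and compare predicted vs realized causal fractions.

    Bins are right-closed: ``(0.0, 0.1], (0.1, 0.2], ...`` with PIP 0
    assigned to the first bin and PIP 1 to the last.
    """
    pips = np.asarray(pips, dtype=float)
    causal_mask = np.asarray(causal_mask, dtype=bool)
    if pips.shape != causal_mask.shape:
        raise ValueError(
            f"pips shape {pips.shape} != causal mask shape {causal_mask.shape}"
        )
    if np.any(pips < 0) or np.any(pips > 1):
        raise ValueError("PIPs must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.ceil(pips * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mean_pip = np.full(n_bins, np.nan)
    causal_frac = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = idx == b
        if counts[b]:
            mean_pip[b] = pips[mask].mean()
            causal_frac[b] = causal_mask[mask].mean()
    return CalibrationTable(
        bin_edges=edges, mean_pip=mean_pip, causal_frac=causal_frac, counts=counts
    )
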