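"""Replicate runners for the simulation benchmarks.

Convenience orchestration shared by the test suite and the acceptance
script: simulate a batch of regions under a scenario preset, fit
single-trait SuSiE and SuSiE2 on each (summary statistics + in-sample
LD), and collect credible sets, PIPs, and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import EvalReport, evaluate_credible_sets
from .pipeline import fit_region_both
from .simulate import scenario_preset, simulate_region

__all__ = ["BatchResult", "run_scenario_batch"]


@dataclass
class BatchResult:
    """Credible sets, PIPs, and truth collected over replicates."""

    cs_susie: list = field(default_factory=list)
    cs_susie2: list = field(default_factory=list)
    pip_susie: list = field(default_factory=list)
    pip_susie2: list = field(default_factory=list)
    truth: list = field(default_factory=list)
    p: int = 0

    def report(self, method: str = "susie2") -> EvalReport:
        cs = self.cs_susie2 if method == "susie2" else self.cs_susie
        return evaluate_credible_sets(cs, self.truth)

    def pooled_pips(self, method: str = "susie2") -> tuple[np.ndarray, np.ndarray]:
        """Pooled PIP vector and causal indicator across replicates."""
        pips = self.pip_susie2 if method == "susie2" else self.pip_susie
        pip = np.concatenate(pips)
        mask = np.zeros(pip.size, dtype=bool)
        for r, causal in enumerate(self.truth):
            mask[np.asarray(causal, int) + r * self.p] = True
        return pip, mask


def run_scenario_batch(
    scenario: str,
    n_reps: int,
    seed: int,
    h2_total: float | None = None,
    p: int = 500,
    n_t: int = 10000,
    n_e: int = 500,
    K: int = 5,
    level: float = 0.95,
    min_purity: float = 0.5,
    **preset_overrides,
) -> BatchResult:
    """Simulate and fine-map ``n_reps`` regions under a scenario preset.

    Replicate ``r`` uses region seed ``(seed * 100003 + r) mod 2^31`` so
    batches with different base seeds do not share regions.
    """
    out = BatchResult(p=p)
    overrides = dict(p=p, n_t=n_t, n_e=n_e, **preset_overrides)
    if h2_total is not None:
        overrides["h2_total"] = h2_total
    for r in range(n_reps):
        cfg = scenario_preset(
            scenario, seed=(seed * 100003 + r) % 2**31, **overrides
        )
        region = simulate_region(cfg)
        susie_fit, s2 = fit_region_both(
            region, K=K, level=level, min_purity=min_purity
        )
        out.cs_susie.append(susie_fit.credible_sets)
        out.cs_susie2.append(s2.trait_fit.credible_sets)
        out.pip_susie.append(susie_fit.pip)
        out.pip_susie2.append(s2.trait_fit.pip)
        out.truth.append(region.causal_trait)
    return out
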