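"""Bootstrap-style subsampling to check robustness under group imbalance.

With 498 animals of one breed next to 85 of another, a significant test can
in principle be an artefact of unequal sample sizes.  The remedy
implemented here repeatedly subsamples every group, without replacement,
down to the size of the smallest group, re-runs the test on the balanced
subsample, and summarises the distribution of p-values across iterations.
A comparison is called stable when the per-iteration p-value falls below
0.05 in (by default) at least 95% of iterations — the fraction itself is
always reported so users can apply their own cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceTable, SampleMetadata
from .diversity import ALPHA_INDICES, _kruskal_p, _rank_sum_p, alpha_diversity, bray_curtis
from .permanova import permanova

__all__ = ["BootstrapPlan", "BootstrapSummary", "bootstrap_alpha",
           "bootstrap_beta"]


@dataclass
class BootstrapPlan:
    """Settings for one subsampling experiment.

    ``group_by`` names the factor whose groups are equalised and tested
    (breed).  For beta-diversity runs, ``cross_with`` additionally crosses
    the groups with a second factor (farm) so every breed-within-farm cell
    is subsampled to the globally smallest cell.  ``subsample_size`` is
    derived as the minimum group size when left unset; an explicit value
    must not exceed any group's size.
    """

    group_by: str = "breed"
    cross_with: str | None = None
    n_iterations: int = 1000
    subsample_size: int | None = None
    inner_permutations: int = 999
    significance: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.subsample_size is not None and self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2")
        if not (0 < self.significance < 1):
            raise ValueError("significance must lie in (0, 1)")


@dataclass
class BootstrapSummary:
    """Distribution of per-iteration p-values and its stability summary."""

    p_values: np.ndarray
    stability_fraction: float
    subsample_size: int
    seed: int
    significance: float
    median_p: float
    p_interval: tuple[float, float]

    @classmethod
    def from_p_values(cls, p: np.ndarray, subsample_size: int, seed: int,
                      significance: float) -> "BootstrapSummary":
        p = np.asarray(p, dtype=float)
        return cls(p_values=p,
                   stability_fraction=float((p < significance).mean()),
                   subsample_size=int(subsample_size), seed=int(seed),
                   significance=float(significance),
                   median_p=float(np.median(p)),
                   p_interval=(float(np.quantile(p, 0.025)),
                               float(np.quantile(p, 0.975))))


def _group_indices(meta: SampleMetadata, tab_ids: list[str],
                   columns: list[str]) -> dict[tuple, np.ndarray]:
    mf = meta.align_to(tab_ids).frame
    key = list(zip(*(mf[c] for c in columns)))
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(key):
        groups.setdefault(k, []).append(i)
    return {k: np.asarray(v) for k, v in sorted(groups.items())}


def _resolve_size(plan: BootstrapPlan, groups: dict) -> int:
    sizes = {k: len(v) for k, v in groups.items()}
    m = plan.subsample_size if plan.subsample_size is not None else min(sizes.values())
    too_small = {k: s for k, s in sizes.items() if s < m}
    if too_small:
        raise ValueError(f"groups smaller than subsample size {m}: {too_small}")
    if m < 2:
        raise ValueError("smallest group has fewer than 2 samples")
    return int(m)


def bootstrap_alpha(tab: AbundanceTable, meta: SampleMetadata,
                    plan: BootstrapPlan) -> dict[str, BootstrapSummary]:
    """Subsampled alpha-diversity comparisons, one summary per index.

    Intended to run within one stratum (e.g. the samples of a single farm).
    Each iteration draws ``subsample_size`` samples per group without
    replacement, recomputes nothing per sample (the indices are per-sample
    quantities, computed once), and applies the omnibus non-parametric test:
    Kruskal-Wallis for three or more groups, Wilcoxon rank-sum for two.
    """
    if len(meta.sample_ids) < len(tab.sample_ids):
        tab = tab.select_samples(meta.sample_ids)
    groups = _group_indices(meta, tab.sample_ids, [plan.group_by])
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups of {plan.group_by!r}")
    m = _resolve_size(plan, groups)
    alpha = alpha_diversity(tab).to_numpy()
    col = {name: j for j, name in enumerate(ALPHA_INDICES)}

    rng = np.random.default_rng(plan.seed)
    p_mat = np.empty((plan.n_iterations, len(ALPHA_INDICES)))
    for it in range(plan.n_iterations):
        draws = [rng.choice(idx, size=m, replace=False)
                 for idx in groups.values()]
        assert all(len(dr) == m for dr in draws)  # balanced by construction
        for name, j in col.items():
            samples = [alpha[dr, j] for dr in draws]
            if len(samples) == 2:
                _, p = _rank_sum_p(samples[0], samples[1])
            else:
                p = _kruskal_p(samples)
            p_mat[it, j] = p
    return {name: BootstrapSummary.from_p_values(
                p_mat[:, j], m, plan.seed, plan.significance)
            for name, j in col.items()}


def bootstrap_beta(tab: AbundanceTable, meta: SampleMetadata,
                   plan: BootstrapPlan) -> BootstrapSummary:
    """Subsampled Bray-Curtis + PERMANOVA robustness check.

    Groups are ``group_by`` cells, crossed with ``cross_with`` when set
    (breed-within-farm); every cell is subsampled to the smallest cell
    size.  Each iteration computes Bray-Curtis on the balanced subsample
    and a one-term PERMANOVA on ``group_by`` with ``inner_permutations``
    permutations; the collected p-values summarise robustness of the
    community-level difference to sample-size imbalance.
    """
    if len(meta.sample_ids) < len(tab.sample_ids):
        tab = tab.select_samples(meta.sample_ids)
    columns = [plan.group_by] + ([plan.cross_with] if plan.cross_with else [])
    groups = _group_indices(meta, tab.sample_ids, columns)
    mf = meta.align_to(tab.sample_ids).frame
    if mf[plan.group_by].nunique() < 2:
        raise ValueError(f"need >= 2 levels of {plan.group_by!r}")
    m = _resolve_size(plan, groups)
    ids = np.asarray(tab.sample_ids)

    rng = np.random.default_rng(plan.seed)
    p_values = np.empty(plan.n_iterations)
    for it in range(plan.n_iterations):
        draws = [rng.choice(idx, size=m, replace=False)
                 for idx in groups.values()]
        assert all(len(dr) == m for dr in draws)  # balanced by construction
        chosen = np.concatenate(draws)
        sub = tab.select_samples(ids[chosen])
        d = bray_curtis(sub)
        inner_seed = int(rng.integers(0, 2**31 - 1))
        res = permanova(d, meta, [plan.group_by],
                        n_permutations=plan.inner_permutations,
                        seed=inner_seed)
        p_values[it] = res.p_value(plan.group_by)
    return BootstrapSummary.from_p_values(p_values, m, plan.seed,
                                          plan.significance)


def summaries_to_frame(summaries: dict[str, BootstrapSummary]) -> pd.DataFrame:
    """Flatten named summaries into a one-row-per-summary table."""
    rows = []
    for name, s in summaries.items():
        rows.append((name, s.subsample_size, len(s.p_values),
                     s.stability_fraction, s.median_p,
                     s.p_interval[0], s.p_interval[1]))
    return pd.DataFrame(rows, columns=["comparison", "subsample_size",
                                       "n_iterations", "stability_fraction",
                                       "median_p", "p_lo", "p_hi"])
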