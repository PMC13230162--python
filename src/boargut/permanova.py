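"""Distance-based multivariate variance partitioning (PERMANOVA).

Implements multi-term models on a dissimilarity matrix: sequential
(order-dependent, by-terms) and marginal sums of squares, pseudo-F
statistics, and permutation p-values under free permutation of sample
labels.  The machinery is the standard one: Gower-centre the squared
distances into an inner-product matrix G, project onto nested column
spaces of the dummy-coded design, and read sums of squares off traces.

For Euclidean distances on a one-dimensional response the sequential
decomposition coincides with classical ANOVA sums of squares, which is the
module's primary correctness oracle (exercised in the test suite).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth
from skbio.stats.distance import DistanceMatrix

from .containers import SampleMetadata

__all__ = ["gower_center", "permanova", "parse_formula", "PermanovaResult",
           "variance_partition_by_stratum", "StratifiedPermanova"]


def _as_square(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return d.data.astype(float), list(d.ids)
    arr = np.asarray(d, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def gower_center(d) -> np.ndarray:
    """Gower-centred inner-product matrix G = -1/2 J (D∘D) J.

    J is the centering projector I - 11'/n.  Rows and columns of G sum to
    zero and trace(G) equals the total sum of squares sum(d^2)/n.
    """
    D, _ = _as_square(d)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    A = -0.5 * D * D
    row_means = A.mean(axis=1, keepdims=True)
    grand = A.mean()
    return A - row_means - row_means.T + grand


def parse_formula(formula: str) -> list[str]:
    """Extract ordered term names from e.g. ``"d ~ breed + age_stage + batch"``."""
    rhs = formula.split("~", 1)[1] if "~" in formula else formula
    terms = [t.strip() for t in re.split(r"\+", rhs) if t.strip()]
    if not terms:
        raise ValueError(f"no terms in formula {formula!r}")
    return terms


@dataclass
class PermanovaResult:
    """ANOVA-style table plus the permutation settings that produced it.

    ``table`` has one row per model term plus ``Residual`` and ``Total``,
    with columns df, sum_sq, r_squared, pseudo_f, p_value.  In sequential
    mode the term and residual sums of squares add up to the total.
    """

    table: pd.DataFrame
    mode: str
    n_permutations: int
    seed: int
    flags: dict[str, str] = field(default_factory=dict)

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "r_squared"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space, rank-revealing."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    return orth(X, rcond=1e-9)


def _dummy_block(series: pd.Series, term: str) -> np.ndarray:
    levels = pd.unique(series.astype(str))
    if len(levels) < 2:
        raise ValueError(f"term {term!r} has fewer than 2 observed levels")
    dummies = pd.get_dummies(series.astype(str), drop_first=True, dtype=float)
    return dummies.to_numpy()


def permanova(d, meta: SampleMetadata, terms, n_permutations: int = 999,
              mode: str = "sequential", seed: int = 0) -> PermanovaResult:
    """Multi-term PERMANOVA on a distance matrix.

    Parameters
    ----------
    d : skbio.DistanceMatrix or square array
        Pairwise dissimilarities between samples.
    meta : SampleMetadata
        Must cover every sample id in ``d``; rows are aligned to its order.
    terms : list of str or formula string
        Categorical factor columns of the metadata, fitted in the given
        order.  Sequential sums of squares are order-dependent.
    mode : "sequential" or "marginal"
        Sequential conditions each term on the preceding terms; marginal
        conditions each term on all other terms (SS(full) - SS(full minus
        term)).
    n_permutations : int
        Free permutations of sample labels; p = (1 + #{F* >= F}) / (1 + N).

    A term whose design columns are entirely confounded with earlier terms
    gets df 0 and is flagged; its F and p are NaN.
    """
    if isinstance(terms, str):
        terms = parse_formula(terms)
    terms = list(terms)
    if len(terms) == 0:
        raise ValueError("at least one model term is required")
    if len(set(terms)) != len(terms):
        raise ValueError("duplicated model terms")
    if mode not in ("sequential", "marginal"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")

    D, ids = _as_square(d)
    n = len(ids)
    mf = meta.align_to(ids).frame
    G = gower_center(D)
    total_ss = float(np.trace(G))

    blocks = [_dummy_block(mf[t], t) for t in terms]
    intercept = np.ones((n, 1))

    # nested orthonormal bases for the cumulative designs
    bases = [_orthobasis(intercept)]
    for k in range(len(blocks)):
        bases.append(_orthobasis(np.hstack([intercept] + blocks[:k + 1])))
    ranks = [b.shape[1] for b in bases]
    full_rank = ranks[-1]
    if n < full_rank + 2:
        raise ValueError(
            f"too few samples (n={n}) for a design of rank {full_rank}")

    hats = [b @ b.T for b in bases]
    H_full = hats[-1]
    flags: dict[str, str] = {}

    # per-term "difference projectors": trace(M_t G) is the term SS
    projectors: list[np.ndarray] = []
    dfs: list[int] = []
    if mode == "sequential":
        for k in range(len(terms)):
            projectors.append(hats[k + 1] - hats[k])
            dfs.append(ranks[k + 1] - ranks[k])
    else:
        for k in range(len(terms)):
            others = [blocks[j] for j in range(len(blocks)) if j != k]
            B = _orthobasis(np.hstack([intercept] + others))
            projectors.append(H_full - B @ B.T)
            dfs.append(full_rank - B.shape[1])

    M_res = np.eye(n) - H_full
    df_res = n - full_rank
    ss_res = float(np.sum(M_res * G))

    ss_terms = [float(np.sum(M * G)) for M in projectors]
    f_obs = np.full(len(terms), np.nan)
    for k, t in enumerate(terms):
        if dfs[k] == 0:
            flags[t] = "confounded"
            continue
        f_obs[k] = (ss_terms[k] / dfs[k]) / (ss_res / df_res)

    # permutation test: permuting metadata rows is equivalent to conjugating
    # G by the permutation, which is what is done here
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    testable = [k for k in range(len(terms)) if dfs[k] > 0]
    for _ in range(n_permutations):
        p = rng.permutation(n)
        Gp = G[np.ix_(p, p)]
        ss_res_p = np.sum(M_res * Gp)
        for k in testable:
            f_p = (np.sum(projectors[k] * Gp) / dfs[k]) / (ss_res_p / df_res)
            if f_p >= f_obs[k] - 1e-12:
                exceed[k] += 1

    rows = []
    for k, t in enumerate(terms):
        p_val = (1.0 + exceed[k]) / (1.0 + n_permutations) \
            if dfs[k] > 0 else np.nan
        rows.append((t, dfs[k], ss_terms[k],
                     ss_terms[k] / total_ss if total_ss > 0 else 0.0,
                     f_obs[k], p_val))
    rows.append(("Residual", df_res, ss_res,
                 ss_res / total_ss if total_ss > 0 else 0.0, np.nan, np.nan))
    rows.append(("Total", n - 1, total_ss, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "sum_sq", "r_squared",
                                        "pseudo_f", "p_value"]).set_index("term")
    return PermanovaResult(table=table, mode=mode,
                           n_permutations=n_permutations, seed=seed,
                           flags=flags)


# ---------------------------------------------------------------------------
# Stratified fits with small-group exclusion
# ---------------------------------------------------------------------------

@dataclass
class StratifiedPermanova:
    """Per-stratum PERMANOVA results with an audit trail.

    ``skipped`` maps a stratum to the reason it could not be fitted;
    ``excluded`` records primary-factor levels dropped for small size and
    the samples removed with them; ``dropped_terms`` records non-primary
    terms that collapsed to a single level within a stratum.
    """

    results: dict[str, PermanovaResult]
    skipped: dict[str, str] = field(default_factory=dict)
    excluded: dict[str, dict[str, int]] = field(default_factory=dict)
    dropped_terms: dict[str, list[str]] = field(default_factory=dict)


def variance_partition_by_stratum(d, meta: SampleMetadata, terms,
                                  stratify_by: str,
                                  min_group_size: int = 10,
                                  primary: str | None = None,
                                  n_permutations: int = 999,
                                  mode: str = "sequential",
                                  seed: int = 0) -> StratifiedPermanova:
    """Fit the model separately within each level of ``stratify_by``.

    Within each stratum, levels of the primary factor (the first model term
    unless ``primary`` says otherwise) with fewer than ``min_group_size``
    samples are excluded before fitting — e.g. a breed represented by only
    8 animals in one farm.  Non-primary terms left with a single level in
    the stratum are dropped from that stratum's formula.  Strata whose
    remaining design is degenerate are skipped with a recorded reason.
    """
    if isinstance(terms, str):
        terms = parse_formula(terms)
    terms = list(terms)
    primary = primary or terms[0]
    if primary not in terms:
        raise ValueError(f"primary term {primary!r} not in model terms")
    D, ids = _as_square(d)
    dm = d if isinstance(d, DistanceMatrix) else DistanceMatrix(D, ids)
    mf = meta.align_to(ids).frame

    out = StratifiedPermanova(results={})
    strata = sorted(mf[stratify_by].unique())
    for si, stratum in enumerate(strata):
        in_stratum = mf.index[mf[stratify_by] == stratum]
        sub = mf.loc[in_stratum]
        counts = sub[primary].value_counts()
        small = counts[counts < min_group_size]
        if len(small):
            out.excluded[stratum] = {lvl: int(nn) for lvl, nn in small.items()}
            sub = sub[~sub[primary].isin(small.index)]
        if sub[primary].nunique() < 2:
            out.skipped[stratum] = (
                f"fewer than 2 levels of {primary!r} with "
                f">= {min_group_size} samples")
            continue
        kept_terms = []
        for t in terms:
            if sub[t].nunique() >= 2:
                kept_terms.append(t)
            else:
                out.dropped_terms.setdefault(stratum, []).append(t)
        sub_ids = list(sub.index)
        sub_d = dm.filter(sub_ids)
        try:
            res = permanova(sub_d, meta, kept_terms,
                            n_permutations=n_permutations, mode=mode,
                            seed=seed + si)
        except ValueError as exc:
            out.skipped[stratum] = str(exc)
            continue
        out.results[stratum] = res
    return out
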