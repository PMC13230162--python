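"""Alpha diversity, Bray-Curtis dissimilarity, PCoA and group comparisons.

Conventions follow the vegan defaults: Shannon uses the natural log,
Simpson is reported as 1 - sum(p^2), and Bray-Curtis is computed on
per-sample proportions.  Group comparisons use the Wilcoxon rank-sum test
(exact for small untied samples, normal approximation with tie correction
otherwise) with Benjamini-Hochberg adjustment within each index family.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceTable
from .permanova import gower_center

__all__ = ["alpha_diversity", "bray_curtis", "pcoa", "PcoaResult",
           "compare_groups_alpha", "AlphaComparison", "bh_adjust"]

ALPHA_INDICES = ("observed_richness", "shannon", "simpson")


def alpha_diversity(tab: AbundanceTable) -> pd.DataFrame:
    """Per-sample observed richness, Shannon and Simpson indices.

    Richness counts taxa with abundance > 0; Shannon is -sum(p ln p) over
    positive proportions; Simpson is 1 - sum(p^2).
    """
    rel = tab.relative_abundance().to_numpy()  # rejects all-zero samples
    richness = (rel > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (rel ** 2).sum(axis=1)
    return pd.DataFrame({"observed_richness": richness.astype(int),
                         "shannon": shannon, "simpson": simpson},
                        index=tab.data.index)


def bray_curtis(tab: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d(i,j) = sum |x_i - x_j| / sum (x_i + x_j); for TPM-normalised rows this
    equals the proportion-based definition.  Samples must be normalised so
    no row is all-zero.
    """
    tab.require_normalized()
    rel = tab.relative_abundance().to_numpy()
    condensed = pdist(rel, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=tab.sample_ids)


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``eigenvalues`` holds the full descending spectrum of the Gower-centred
    matrix (negative eigenvalues included, for the record);
    ``proportion_explained`` is per returned axis, over the positive part of
    the spectrum only.  ``truncated`` is set when fewer axes than requested
    were available.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    truncated: bool = False


def pcoa(d, n_axes: int = 2) -> PcoaResult:
    """Classical scaling: eigendecompose the Gower-centred matrix.

    Coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues.  Axis signs are fixed so the largest-magnitude
    loading on each axis is positive, making the embedding reproducible.
    No correction for negative eigenvalues is applied.
    """
    if n_axes < 2:
        raise ValueError("n_axes must be >= 2")
    if isinstance(d, DistanceMatrix):
        ids = list(d.ids)
    else:
        ids = [str(i) for i in range(np.asarray(d).shape[0])]
    G = gower_center(d)
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = max(np.abs(w).max(), 1.0) * 1e-10
    n_pos = int((w > tol).sum())
    k = min(n_axes, n_pos)
    truncated = k < n_axes
    if truncated:
        warnings.warn(f"only {n_pos} positive eigenvalues; returning {k} axes",
                      RuntimeWarning, stacklevel=2)
    coords = v[:, :k] * np.sqrt(w[:k])
    for j in range(k):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = w[w > tol].sum()
    prop = (w[:k] / pos_sum) if pos_sum > 0 else np.zeros(k)
    frame = pd.DataFrame(coords, index=pd.Index(ids, name="sample_id"),
                         columns=[f"PCo{j + 1}" for j in range(k)])
    return PcoaResult(coordinates=frame, eigenvalues=w,
                      proportion_explained=prop, truncated=truncated)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # every observation identical: no evidence
        return len(x) * len(y) / 2.0, 1.0
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def _kruskal_p(samples: list[np.ndarray]) -> float:
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return 1.0
    return float(kruskal(*samples).pvalue)


@dataclass
class AlphaComparison:
    """Pairwise rank-sum tests per index plus (for >= 3 groups) omnibus tests.

    ``pairwise`` columns: index, group1, group2, n1, n2, statistic, p, q
    with q adjusted within each index family.  ``omnibus`` columns:
    index, p (Kruskal-Wallis), empty for two groups.
    """

    pairwise: pd.DataFrame
    omnibus: pd.DataFrame


def compare_groups_alpha(alpha: pd.DataFrame, groups: pd.Series) -> AlphaComparison:
    """Compare alpha-diversity indices between sample groups.

    Parameters
    ----------
    alpha : DataFrame
        Output of :func:`alpha_diversity` (samples x indices).
    groups : Series
        Group label per sample, aligned by sample id.
    """
    groups = groups.reindex(alpha.index)
    if groups.isna().any():
        missing = alpha.index[groups.isna()].tolist()[:5]
        raise ValueError(f"group labels missing for samples: {missing}")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 samples: "
                         f"{dict(small.astype(int))}")

    rows = []
    for index_name in alpha.columns:
        values = alpha[index_name]
        for g1, g2 in combinations(levels, 2):
            x = values[groups == g1].to_numpy(float)
            y = values[groups == g2].to_numpy(float)
            stat, p = _rank_sum_p(x, y)
            rows.append((index_name, g1, g2, len(x), len(y), stat, p))
    pairwise = pd.DataFrame(rows, columns=["index", "group1", "group2",
                                           "n1", "n2", "statistic", "p"])
    pairwise["q"] = np.nan
    for index_name in alpha.columns:
        mask = pairwise["index"] == index_name
        pairwise.loc[mask, "q"] = bh_adjust(pairwise.loc[mask, "p"].to_numpy())

    omnibus_rows = []
    if len(levels) >= 3:
        for index_name in alpha.columns:
            values = alpha[index_name]
            samples = [values[groups == g].to_numpy(float) for g in levels]
            omnibus_rows.append((index_name, _kruskal_p(samples)))
    omnibus = pd.DataFrame(omnibus_rows, columns=["index", "p"])
    return AlphaComparison(pairwise=pairwise, omnibus=omnibus)


# ---------------------------------------------------------------------------
# Simple TSV export helpers used by the CLI and pipeline
# ---------------------------------------------------------------------------

def write_distance(d: DistanceMatrix, path) -> None:
    """Condensed distance vector with an id header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(d.ids) + "\n")
        fh.write("\t".join(repr(float(x)) for x in d.condensed_form()) + "\n")


def read_distance(path) -> DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        vec = np.array(fh.readline().split("\t"), dtype=float)
    return DistanceMatrix(squareform(vec), ids=ids)
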