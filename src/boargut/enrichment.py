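"""Per-taxon multivariable linear models and the consistency classifier.

For each taxon the response is log(relative abundance + pseudocount), the
pseudocount being half the taxon's smallest nonzero relative abundance.
Each pairwise model regresses the response on an indicator of the contrast
level of the primary factor (breed or age stage) plus dummy-coded
covariates (company, farm, batch — and breed, for age models), restricted
to the samples of the two levels.  Benjamini-Hochberg q-values are
computed within each pairwise model across taxa.

A taxon is labelled enriched in level L only when both pairwise models
involving L favour L in sign and both reach q < 0.05 — the
cross-comparison consistency rule.  Because the two models must agree in
direction, a taxon can carry at most one label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import enrichment_input_filter
from .containers import AbundanceTable, SampleMetadata, TPM_TOTAL
from .diversity import bh_adjust

__all__ = ["PairwiseModelSpec", "EnrichmentResult", "transform_abundance",
           "fit_pairwise", "classify_consistent", "run_enrichment",
           "evaluate_recovery"]

DEFAULT_COVARIATES = ("company", "farm", "batch")

#: response variance below this is treated as degenerate (no information)
_DEGENERATE_VAR = 1e-24


@dataclass(frozen=True)
class PairwiseModelSpec:
    """One pairwise comparison of the primary factor, with covariates."""

    primary: str
    reference: str
    contrast: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self):
        if self.reference == self.contrast:
            raise ValueError("reference and contrast levels must differ")
        if self.primary in self.covariates:
            raise ValueError("primary factor cannot also be a covariate")

    @property
    def name(self) -> str:
        return f"{self.reference}_vs_{self.contrast}"


def transform_abundance(tab: AbundanceTable) -> tuple[pd.DataFrame, pd.Series]:
    """Log-transform relative abundances with per-taxon pseudocounts.

    Returns (responses, pseudocounts).  The pseudocount is half the minimum
    nonzero relative abundance of the taxon, recorded for audit.  Expects a
    table already passed through :func:`enrichment_input_filter`, so no
    taxon is all-zero.
    """
    rel = tab.values / TPM_TOTAL
    pseudo = np.empty(tab.n_taxa)
    for j in range(tab.n_taxa):
        col = rel[:, j]
        positive = col[col > 0]
        assert positive.size > 0, "all-zero taxon should have been filtered"
        pseudo[j] = positive.min() / 2.0
    responses = pd.DataFrame(np.log(rel + pseudo[None, :]),
                             index=tab.data.index, columns=tab.data.columns)
    return responses, pd.Series(pseudo, index=tab.data.columns,
                                name="pseudocount")


def _independent_columns(X: np.ndarray, protected: int) -> list[int]:
    """Greedy rank-preserving column selection.

    The first ``protected`` columns (intercept + primary indicator) are
    always kept; later columns are added only when they increase the rank.
    """
    keep = list(range(protected))
    rank = np.linalg.matrix_rank(X[:, keep])
    for j in range(protected, X.shape[1]):
        trial = keep + [j]
        r = np.linalg.matrix_rank(X[:, trial])
        if r > rank:
            keep = trial
            rank = r
    return keep


def _build_design(spec: PairwiseModelSpec, mf: pd.DataFrame
                  ) -> tuple[np.ndarray, list[str], list[str]]:
    n = len(mf)
    cols = [np.ones(n), (mf[spec.primary] == spec.contrast).to_numpy(float)]
    names = ["intercept", f"{spec.primary}[{spec.contrast}]"]
    for cov in spec.covariates:
        dummies = pd.get_dummies(mf[cov].astype(str), prefix=cov,
                                 drop_first=True, dtype=float)
        for c in dummies.columns:
            v = dummies[c].to_numpy()
            if v.std() > 0:  # levels absent within the pair drop out here
                cols.append(v)
                names.append(c)
    X = np.column_stack(cols)
    keep = _independent_columns(X, protected=2)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    return X[:, keep], [names[j] for j in keep], dropped


def fit_pairwise(spec: PairwiseModelSpec, responses: pd.DataFrame,
                 meta: SampleMetadata) -> pd.DataFrame:
    """OLS of every taxon's response on the pairwise design.

    Restricted to samples of the two primary levels; returns a per-taxon
    frame with columns coefficient (log-scale shift of contrast vs
    reference), p (two-sided t-test on that coefficient) and flag.
    Covariate columns that are collinear within the pair are dropped and
    recorded in ``frame.attrs["dropped_columns"]``.
    """
    mf = meta.align_to(responses.index).frame
    in_pair = mf[spec.primary].isin([spec.reference, spec.contrast])
    mf = mf[in_pair]
    for level in (spec.reference, spec.contrast):
        n_level = int((mf[spec.primary] == level).sum())
        if n_level < 3:
            raise ValueError(f"level {level!r} has only {n_level} samples "
                             "in the pair (need >= 3)")
    Y = responses.loc[mf.index].to_numpy()
    X, names, dropped = _build_design(spec, mf)
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples in the pair")

    # mass-univariate OLS: one shared design, all taxa at once
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)                    # p x T
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * XtX_inv[1, 1])
    coef = beta[1]

    var_y = Y.var(axis=0)
    degenerate = var_y < _DEGENERATE_VAR
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvals = np.where(se > 0, pvals, 1.0)
    coef = np.where(degenerate, 0.0, coef)
    pvals = np.where(degenerate, 1.0, pvals)

    out = pd.DataFrame({"coefficient": coef, "p": pvals,
                        "flag": np.where(degenerate, "degenerate", "")},
                       index=responses.columns)
    out.attrs["design_columns"] = names
    out.attrs["dropped_columns"] = dropped
    out.attrs["n_samples"] = n
    return out


def classify_consistent(records: pd.DataFrame, levels: list[str],
                        q_threshold: float = 0.05) -> pd.Series:
    """Label each taxon by the cross-comparison consistency rule.

    ``records`` is the long table with columns taxon, reference, contrast,
    coefficient, q.  A taxon gets label L iff both models involving L have
    q strictly below ``q_threshold`` and their coefficients favour L
    (positive when L is the contrast, negative when L is the reference).
    Taxa with a missing model for a level are labelled ``none``.
    """
    labels = {}
    by_taxon = records.groupby("taxon", sort=False)
    for taxon, sub in by_taxon:
        label = "none"
        for level in levels:
            inv = sub[(sub["reference"] == level) | (sub["contrast"] == level)]
            if len(inv) != 2:
                continue  # incomplete model set for this level
            favors = ((inv["contrast"] == level) & (inv["coefficient"] > 0)) | \
                     ((inv["reference"] == level) & (inv["coefficient"] < 0))
            if favors.all() and (inv["q"] < q_threshold).all():
                label = level
                break  # sign concordance makes labels mutually exclusive
        labels[taxon] = label
    return pd.Series(labels, name="label")


@dataclass
class EnrichmentResult:
    """Pairwise-model coefficients, q-values and consistency labels."""

    records: pd.DataFrame            # taxon, model, reference, contrast, ...
    labels: pd.Series                # taxon -> level or "none"
    pseudocounts: pd.Series
    q_threshold: float
    primary: str
    covariates: tuple[str, ...]
    dropped_columns: dict[str, list[str]] = field(default_factory=dict)

    def enriched(self, level: str) -> list[str]:
        return list(self.labels.index[self.labels == level])


def run_enrichment(tab: AbundanceTable, meta: SampleMetadata,
                   primary: str = "breed",
                   covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                   q_threshold: float = 0.05,
                   min_prev: float = 0.05,
                   min_mean_relabund: float = 1e-5,
                   prefiltered: bool = False) -> EnrichmentResult:
    """Full enrichment screen for a 3-level primary factor.

    Applies the rare-taxon filter, the log transform, the three pairwise
    fits with BH adjustment within each model across taxa, and the
    consistency classifier.  Deterministic given its inputs; invariant to
    the ordering of samples.
    """
    mf = meta.align_to(tab.sample_ids).frame
    levels = sorted(mf[primary].astype(str).unique())
    if len(levels) != 3:
        raise ValueError(f"primary factor {primary!r} must have exactly 3 "
                         f"levels, found {levels}")
    filtered = tab if prefiltered else enrichment_input_filter(
        tab, min_prev, min_mean_relabund)
    responses, pseudo = transform_abundance(filtered)

    frames = []
    dropped: dict[str, list[str]] = {}
    for ref, contrast in combinations(levels, 2):
        spec = PairwiseModelSpec(primary=primary, reference=ref,
                                 contrast=contrast, covariates=covariates)
        fit = fit_pairwise(spec, responses, meta)
        frame = fit.reset_index(names="taxon")
        frame.insert(1, "model", spec.name)
        frame.insert(2, "reference", ref)
        frame.insert(3, "contrast", contrast)
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        frames.append(frame)
        if fit.attrs["dropped_columns"]:
            dropped[spec.name] = fit.attrs["dropped_columns"]
    records = pd.concat(frames, ignore_index=True)
    labels = classify_consistent(records, levels, q_threshold)
    labels = labels.reindex(filtered.taxon_ids).fillna("none")
    return EnrichmentResult(records=records, labels=labels,
                            pseudocounts=pseudo, q_threshold=q_threshold,
                            primary=primary, covariates=tuple(covariates),
                            dropped_columns=dropped)


def evaluate_recovery(result: EnrichmentResult, truth: pd.DataFrame,
                      factor: str = "breed") -> dict:
    """Score labels against a planted-truth table.

    ``truth`` has columns taxon, factor, level, sign; only '+' records of
    the given factor are treated as planted enrichment.  Returns per-level
    recovery plus the false-label tally: a false label is any labelled
    taxon whose planted level (or absence of one) disagrees.
    """
    planted = truth[(truth["factor"] == factor) & (truth["sign"] == "+")]
    truth_map = dict(zip(planted["taxon"], planted["level"]))
    labelled = result.labels[result.labels != "none"]

    per_level = {}
    for level in sorted(planted["level"].unique()):
        taxa = [t for t, lv in truth_map.items() if lv == level]
        tested = [t for t in taxa if t in result.labels.index]
        hit = [t for t in tested if result.labels.get(t) == level]
        per_level[level] = {"planted": len(taxa), "tested": len(tested),
                            "recovered": len(hit)}
    false_labels = [t for t, lv in labelled.items()
                    if truth_map.get(t) != lv]
    n_null_tested = int((~result.labels.index.isin(truth_map)).sum())
    return {
        "per_level": per_level,
        "n_labelled": int(len(labelled)),
        "n_false_labels": len(false_labels),
        "false_label_proportion": (len(false_labels) / len(labelled)
                                   if len(labelled) else 0.0),
        "n_null_tested": n_null_tested,
    }
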