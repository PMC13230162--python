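"""Loading, normalisation, presence calling and filtering of abundance data.

Two distinct presence rules exist and are applied at different pipeline
stages: a coverage gate (effective coverage strictly above 1x) used when the
abundance table is constructed, and a relative-abundance rule (strictly above
1e-5) used for shared-taxa set analysis.  Prevalence cuts are inclusive
(>=), matching how the filters are stated.
"""
from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    AbundanceTable,
    CoverageStats,
    PresenceMatrix,
    SampleMetadata,
    DEFAULT_READ_LENGTH,
    TPM_TOTAL,
)

# ---------------------------------------------------------------------------
# TSV io (first column sample_id, remaining columns taxon ids; '.' decimal)
# ---------------------------------------------------------------------------

def read_abundance(path: str | os.PathLike,
                   taxonomy_path: str | os.PathLike | None = None) -> AbundanceTable:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    taxonomy = None
    if taxonomy_path is not None:
        tx = pd.read_csv(taxonomy_path, sep="\t", index_col="taxon")
        taxonomy = tx["lineage"]
    return AbundanceTable(frame, taxonomy)


def write_abundance(tab: AbundanceTable, path: str | os.PathLike) -> None:
    frame = tab.data.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_coverage(path: str | os.PathLike,
                  read_length: int = DEFAULT_READ_LENGTH) -> CoverageStats:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return CoverageStats(frame, read_length)


def write_coverage(cov: CoverageStats, path: str | os.PathLike) -> None:
    frame = cov.data.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"batch": str})
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    meta.frame.to_csv(path, sep="\t")


def write_taxonomy(taxonomy: pd.Series, path: str | os.PathLike) -> None:
    frame = taxonomy.rename("lineage").to_frame()
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Normalisation and presence calling
# ---------------------------------------------------------------------------

def normalize_tpm(raw) -> AbundanceTable:
    """Scale every sample (row) to sum to 1e6 (TPM convention).

    Zero entries stay exactly zero; the operation is idempotent and invariant
    to per-row rescaling.  Samples with no positive entry are rejected.
    """
    if isinstance(raw, AbundanceTable):
        tab = raw
    else:
        tab = AbundanceTable(raw)
    values = tab.values
    sums = values.sum(axis=1)
    if (sums == 0).any():
        bad = [s for s, t in zip(tab.sample_ids, sums) if t == 0]
        raise ValueError(f"cannot normalise all-zero samples: {bad[:5]}")
    scaled = values * (TPM_TOTAL / sums)[:, None]
    return AbundanceTable(
        pd.DataFrame(scaled, index=tab.data.index, columns=tab.data.columns),
        tab.taxonomy)


def effective_coverage(cov: CoverageStats) -> pd.DataFrame:
    """Fold coverage per (sample, taxon): reads-per-base x read length."""
    return cov.data * float(cov.read_length)


def call_presence_by_coverage(cov: CoverageStats,
                              threshold: float = 1.0) -> PresenceMatrix:
    """Presence when effective coverage strictly exceeds ``threshold`` (1x)."""
    if threshold < 0:
        raise ValueError("coverage threshold must be nonnegative")
    ec = effective_coverage(cov)
    return PresenceMatrix(ec > threshold,
                          provenance={"rule": "coverage",
                                      "coverage_threshold": threshold,
                                      "read_length": cov.read_length})


def call_presence_by_abundance(tab: AbundanceTable,
                               threshold: float = 1e-5) -> PresenceMatrix:
    """Presence when relative abundance (TPM / 1e6) strictly exceeds ``threshold``."""
    if not (0 < threshold < 1):
        raise ValueError("abundance threshold must lie in (0, 1)")
    rel = tab.values / TPM_TOTAL
    frame = pd.DataFrame(rel > threshold, index=tab.data.index,
                         columns=tab.data.columns)
    return PresenceMatrix(frame, provenance={"rule": "abundance",
                                             "abundance_threshold": threshold})


def coverage_gate(tab: AbundanceTable, cov: CoverageStats,
                  threshold: float = 1.0,
                  renormalize: bool = True) -> AbundanceTable:
    """Zero out entries whose effective coverage does not exceed ``threshold``.

    This is the table-construction step: taxa are retained in a sample only
    when their genome coverage exceeds 1x.  By default the gated rows are
    rescaled back to the TPM total.
    """
    cov.check_axes_match(tab)
    pres = call_presence_by_coverage(cov, threshold)
    gated = tab.values * pres.values
    sums = gated.sum(axis=1)
    if (sums == 0).any():
        bad = [s for s, t in zip(tab.sample_ids, sums) if t == 0]
        raise ValueError(f"coverage gate removed every taxon in samples: {bad[:5]}")
    frame = pd.DataFrame(gated, index=tab.data.index, columns=tab.data.columns)
    out = AbundanceTable(frame, tab.taxonomy)
    return normalize_tpm(out) if renormalize else out


# ---------------------------------------------------------------------------
# Prevalence-based filters
# ---------------------------------------------------------------------------

def prevalence_filter(pres: PresenceMatrix, group: Sequence[str],
                      min_prevalence: float) -> list[str]:
    """Taxa present in at least ``min_prevalence`` of the ``group`` samples.

    The cut is inclusive: a taxon present in exactly 10% of samples passes a
    0.10 threshold.
    """
    group = [str(s) for s in group]
    if len(group) == 0:
        raise ValueError("prevalence_filter requires a non-empty sample group")
    if not (0 <= min_prevalence <= 1):
        raise ValueError("min_prevalence must lie in [0, 1]")
    sub = pres.data.loc[group]
    prev = sub.to_numpy().mean(axis=0)
    keep = prev >= min_prevalence
    return [t for t, k in zip(pres.taxon_ids, keep) if k]


def enrichment_input_filter(tab: AbundanceTable,
                            min_prev: float = 0.05,
                            min_mean_relabund: float = 1e-5) -> AbundanceTable:
    """Drop rare taxa before per-taxon modelling.

    A taxon is kept when it is detected (abundance > 0) in at least
    ``min_prev`` of all samples AND its mean relative abundance over all
    samples is at least ``min_mean_relabund``.  Both boundaries are kept
    (inclusive), i.e. only taxa strictly below a cut are excluded.
    """
    if not (0 <= min_prev <= 1):
        raise ValueError("min_prev must lie in [0, 1]")
    if min_mean_relabund < 0:
        raise ValueError("min_mean_relabund must be nonnegative")
    values = tab.values
    detected = (values > 0).mean(axis=0)
    mean_rel = (values / TPM_TOTAL).mean(axis=0)
    # inclusive boundary, robust to summation rounding in the mean
    keep = (detected >= min_prev) & \
        (mean_rel >= min_mean_relabund * (1.0 - 1e-12))
    if not keep.any():
        raise ValueError(
            f"filter removed all {tab.n_taxa} taxa "
            f"(prevalence>={min_prev}, mean relative abundance>={min_mean_relabund})")
    taxa = [t for t, k in zip(tab.taxon_ids, keep) if k]
    return tab.select_taxa(taxa)
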