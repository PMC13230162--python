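"""Shared and group-specific taxon sets with UpSet-style intersections.

A taxon belongs to a group's set when it passes the abundance-based
presence rule in at least ``min_prevalence`` of the group's samples.
Species in every breed's set within one farm are cross-breed shared taxa;
species in every farm's set within one breed are cross-farm shared taxa.
Intersection counts are exclusive (UpSet convention: each taxon counted in
exactly the subset of groups that contain it); inclusive pairwise overlaps
are reported alongside since both readings occur in practice.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import pandas as pd

from .abundance import prevalence_filter
from .containers import PresenceMatrix, SampleMetadata

__all__ = ["TaxonSetFamily", "IntersectionReport", "build_group_sets",
           "intersect_report"]

MAX_GROUPS = 20  # 2^k - 1 exclusive cells; guard against combinatorial blowup


@dataclass(frozen=True)
class TaxonSetFamily:
    """Named taxon sets (one per group) plus the thresholds that built them."""

    sets: Mapping[str, frozenset]
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "sets",
                           {str(k): frozenset(v) for k, v in self.sets.items()})
        object.__setattr__(self, "provenance", dict(self.provenance))

    @property
    def group_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def build_group_sets(pres: PresenceMatrix, meta: SampleMetadata,
                     group_by: str,
                     within: tuple[str, str] | None = None,
                     min_prevalence: float = 0.10) -> TaxonSetFamily:
    """Per-group taxon sets from a presence matrix.

    Parameters
    ----------
    pres : PresenceMatrix
        Presence calls (typically the relative-abundance rule applied to the
        coverage-gated table).
    group_by : str
        Metadata factor whose levels define the groups (breed or farm).
    within : (factor, level), optional
        Restrict to one stratum first, e.g. ``("farm", "A1")`` for the
        cross-breed sets of a single farm.
    min_prevalence : float
        Inclusive prevalence cut applied within each group (default 10%).
    """
    mf = meta.align_to(pres.sample_ids).frame
    if within is not None:
        factor, level = within
        mf = mf[mf[factor].astype(str) == str(level)]
        if len(mf) == 0:
            raise ValueError(f"empty stratum: {factor}={level}")
    sets = {}
    for group, sub in mf.groupby(mf[group_by].astype(str), sort=True):
        taxa = prevalence_filter(pres, list(sub.index), min_prevalence)
        sets[group] = frozenset(taxa)
    provenance = dict(pres.provenance)
    provenance.update({"group_by": group_by, "within": within,
                       "min_prevalence": min_prevalence})
    return TaxonSetFamily(sets=sets, provenance=provenance)


@dataclass
class IntersectionReport:
    """Exclusive intersection counts over all non-empty group subsets.

    ``exclusive`` maps a frozenset of group names to the number of taxa
    present in exactly those groups; the counts partition the union.
    ``inclusive_pairwise`` gives plain |A ∩ B| for every pair.
    """

    exclusive: dict[frozenset, int]
    set_sizes: dict[str, int]
    shared_by_all: int
    unique_per_group: dict[str, int]
    inclusive_pairwise: dict[frozenset, int]
    union_size: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (groups joined by '&', exclusive count)."""
        rows = [("&".join(sorted(k)), len(k), v)
                for k, v in sorted(self.exclusive.items(),
                                   key=lambda kv: (len(kv[0]), sorted(kv[0])))]
        return pd.DataFrame(rows, columns=["groups", "degree", "count"])


def intersect_report(family: TaxonSetFamily) -> IntersectionReport:
    """Tally each taxon's membership pattern across the family's sets."""
    names = family.group_names
    if len(names) < 2:
        raise ValueError("need at least 2 groups to intersect")
    if len(names) > MAX_GROUPS:
        raise ValueError(f"refusing to intersect more than {MAX_GROUPS} groups")

    union = set().union(*family.sets.values())
    exclusive: dict[frozenset, int] = {}
    for taxon in union:
        pattern = frozenset(g for g in names if taxon in family.sets[g])
        exclusive[pattern] = exclusive.get(pattern, 0) + 1

    set_sizes = {g: len(family.sets[g]) for g in names}
    shared_by_all = exclusive.get(frozenset(names), 0)
    unique = {g: exclusive.get(frozenset([g]), 0) for g in names}
    pairwise = {frozenset([a, b]): len(family.sets[a] & family.sets[b])
                for a, b in combinations(names, 2)}

    report = IntersectionReport(exclusive=exclusive, set_sizes=set_sizes,
                                shared_by_all=shared_by_all,
                                unique_per_group=unique,
                                inclusive_pairwise=pairwise,
                                union_size=len(union))
    # partition identity: exclusive cells tile the union exactly
    assert sum(exclusive.values()) == len(union)
    return report
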