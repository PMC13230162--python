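"""Synthetic boar-cohort generator.

Emulates the statistical structure the downstream analyses assume: a
breed x farm x age x batch design with highly imbalanced group sizes,
compositional abundance with planted additive effects on the log scale, and
per-taxon coverage statistics tied to abundance so the 1x presence gate is
exercised on both sides of the threshold.

The model is log-normal: per sample, log taxon intensity equals a per-taxon
baseline plus sparse breed / farm / age-stage / batch shifts plus Gaussian
noise; intensities are exponentiated and closed to the TPM total.  The
planted shifts constitute the ground truth that recovery tests score
against.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import abundance as _abund
from .containers import (
    AGE_STAGES,
    AbundanceTable,
    CoverageStats,
    SampleMetadata,
    TPM_TOTAL,
    assign_age_stage,
)

__all__ = [
    "CohortDesign", "EffectModel", "SyntheticCohort", "simulate_cohort",
    "assign_age_stage", "write_cohort", "read_cohort", "study_design",
    "study_effect_model", "planted_breed_model", "STUDY_GROUPS",
]

#: the nine breed-within-station group sizes of the source cohort
STUDY_GROUPS = (
    ("Duroc", "A1", 34), ("Landrace", "A1", 113), ("LargeWhite", "A1", 338),
    ("Duroc", "A2", 8), ("Landrace", "A2", 108), ("LargeWhite", "A2", 301),
    ("Duroc", "B1", 498), ("Landrace", "B1", 166), ("LargeWhite", "B1", 85),
)

#: phylum composition of the simulated community; two phyla dominate, as in
#: commercial pig gut metagenomes
DEFAULT_PHYLUM_WEIGHTS = {
    "Firmicutes": 0.34, "Bacteroidota": 0.26, "Firmicutes_A": 0.16,
    "Proteobacteria": 0.09, "Spirochaetota": 0.07, "Actinobacteriota": 0.05,
    "Verrucomicrobiota": 0.03,
}


@dataclass(frozen=True)
class CohortDesign:
    """Group structure of a simulated cohort.

    ``groups`` lists (breed, farm, n_samples) triples; each (breed, farm)
    pair may appear once.  Ages are drawn uniformly from
    ``age_range_days`` and each farm is split into ``n_batches`` sampling
    batches.  Company defaults to the first character of the farm label
    unless ``company_map`` overrides it.
    """

    groups: tuple[tuple[str, str, int], ...]
    age_range_days: tuple[int, int] = (257, 1906)
    n_batches: int = 4
    seed: int = 0
    company_map: Mapping[str, str] | None = None

    def __post_init__(self):
        groups = tuple((str(b), str(f), int(n)) for b, f, n in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) == 0:
            raise ValueError("design needs at least one group")
        if any(n < 1 for _, _, n in groups):
            raise ValueError("all group sizes must be >= 1")
        pairs = [(b, f) for b, f, _ in groups]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (breed, farm) pair in design")
        lo, hi = self.age_range_days
        if not (1 <= lo <= hi <= 4000):
            raise ValueError("age range must lie within [1, 4000]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")

    @property
    def breeds(self) -> tuple[str, ...]:
        return tuple(sorted({b for b, _, _ in self.groups}))

    @property
    def farms(self) -> tuple[str, ...]:
        return tuple(sorted({f for _, f, _ in self.groups}))

    @property
    def n_samples(self) -> int:
        return sum(n for _, _, n in self.groups)

    def company_of(self, farm: str) -> str:
        if self.company_map is not None:
            return str(self.company_map[farm])
        return farm[0]

    def batch_labels(self, farm: str) -> list[str]:
        return [f"{farm}.b{j + 1}" for j in range(self.n_batches)]


@dataclass
class EffectModel:
    """Per-taxon baselines plus sparse additive log-scale effects.

    Effect tables map a factor level to ``{taxon_index: log_shift}``; taxon
    indices are 0-based positions in the simulated taxon list.  The planted
    truth (taxon, factor, level, sign) is derived from the tables, so it can
    never disagree with them.
    """

    n_taxa: int
    base_logmean: np.ndarray | None = None
    breed_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    farm_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    stage_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    batch_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    dispersion: float = 1.0
    taxonomy: pd.Series | None = None

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.base_logmean is None:
            self.base_logmean = np.zeros(self.n_taxa)
        self.base_logmean = np.asarray(self.base_logmean, dtype=float)
        if self.base_logmean.shape != (self.n_taxa,):
            raise ValueError("base_logmean must have length n_taxa")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        for factor in ("breed", "farm", "stage", "batch"):
            for level, shifts in self._table(factor).items():
                for taxon in shifts:
                    if not (0 <= int(taxon) < self.n_taxa):
                        raise ValueError(
                            f"effect for unknown taxon index {taxon} "
                            f"(factor {factor!r}, level {level!r})")

    def _table(self, factor: str) -> dict[str, dict[int, float]]:
        return getattr(self, f"{factor}_effects")

    def add_effect(self, factor: str, level: str, taxa, shift: float) -> "EffectModel":
        """Plant a uniform log-shift for ``taxa`` at one factor level."""
        table = self._table(factor)
        entry = table.setdefault(str(level), {})
        for t in np.atleast_1d(taxa):
            t = int(t)
            if not (0 <= t < self.n_taxa):
                raise ValueError(f"taxon index {t} out of range")
            entry[t] = float(shift)
        return self

    def taxon_ids(self) -> list[str]:
        return [f"t{i + 1:04d}" for i in range(self.n_taxa)]

    @property
    def planted_truth(self) -> pd.DataFrame:
        """Long table (taxon, factor, level, sign) derived from the effects."""
        ids = self.taxon_ids()
        rows = []
        for factor in ("breed", "farm", "stage", "batch"):
            for level, shifts in sorted(self._table(factor).items()):
                for taxon, shift in sorted(shifts.items()):
                    if shift == 0:
                        continue
                    rows.append((ids[taxon], factor, level,
                                 "+" if shift > 0 else "-"))
        return pd.DataFrame(rows, columns=["taxon", "factor", "level", "sign"])

    @classmethod
    def community(cls, n_taxa: int = 300, dispersion: float = 1.0,
                  seed: int = 0, base_sd: float = 2.0,
                  phylum_weights: Mapping[str, float] | None = None) -> "EffectModel":
        """Draw a baseline community with lognormal-ish abundance spread.

        Baselines are N(0, base_sd) on the log scale, which yields the
        heavy-tailed rank-abundance curves typical of gut metagenomes.
        Taxa are assigned to phyla with ``phylum_weights`` probabilities, so
        the two dominant phyla also dominate total abundance by taxon count.
        """
        rng = np.random.default_rng(seed)
        base = rng.normal(0.0, base_sd, n_taxa)
        weights = dict(phylum_weights or DEFAULT_PHYLUM_WEIGHTS)
        phyla = list(weights)
        probs = np.array([weights[p] for p in phyla], dtype=float)
        probs = probs / probs.sum()
        assign = rng.choice(len(phyla), size=n_taxa, p=probs)
        lineages = []
        for i, k in enumerate(assign):
            p = phyla[k]
            lineages.append(
                f"d__Bacteria;p__{p};c__{p}_c;o__{p}_o;f__{p}_f;"
                f"g__{p}_g{i % 40:02d};s__species_{i + 1:04d}")
        model = cls(n_taxa=n_taxa, base_logmean=base, dispersion=dispersion)
        model.taxonomy = pd.Series(lineages, index=model.taxon_ids())
        return model


@dataclass
class SyntheticCohort:
    """A simulated cohort: abundance, coverage, metadata and planted truth."""

    abundance: AbundanceTable
    coverage: CoverageStats
    metadata: SampleMetadata
    truth: pd.DataFrame

    def __post_init__(self):
        ids = self.abundance.sample_ids
        if self.coverage.sample_ids != ids or self.metadata.sample_ids != ids:
            raise ValueError("sample ids differ across cohort tables")
        if self.coverage.taxon_ids != self.abundance.taxon_ids:
            raise ValueError("taxon ids differ between abundance and coverage")
        sums = self.abundance.values.sum(axis=1)
        if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
            raise ValueError("abundance rows must sum to the TPM total")


def _validate_levels(design: CohortDesign, model: EffectModel) -> None:
    known = {
        "breed": set(design.breeds),
        "farm": set(design.farms),
        "stage": set(AGE_STAGES),
        "batch": {b for f in design.farms for b in design.batch_labels(f)},
    }
    for factor, levels in known.items():
        for level, shifts in model._table(factor).items():
            if level not in levels:
                offending = sorted(shifts)[:3]
                raise ValueError(
                    f"effect references unknown {factor} level {level!r} "
                    f"(taxa {offending})")


def simulate_cohort(design: CohortDesign, model: EffectModel,
                    depth_factor: float = 5.0,
                    coverage_jitter_sd: float = 0.5) -> SyntheticCohort:
    """Draw a cohort from the log-normal additive-effects model.

    Per sample: log intensity = base + breed + farm + stage + batch shifts
    + N(0, dispersion) noise, exponentiated and closed to 1e6 (TPM).
    Reads-per-base is ``depth_factor`` x relative abundance x a per-sample
    lognormal jitter, so with the default depth a typical taxon sits a few
    fold above the 1x gate and rare taxa fall below it.

    Identical (design, model) with the same ``design.seed`` reproduce the
    cohort bit for bit: one seed sequence is spawned into per-sample
    substreams, independent of iteration order.
    """
    _validate_levels(design, model)
    if depth_factor <= 0:
        raise ValueError("depth_factor must be positive")

    n_total = design.n_samples
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(n_total + 1)
    meta_rng = np.random.default_rng(children[0])

    taxon_ids = model.taxon_ids()
    lo, hi = design.age_range_days

    records = []
    sample_seeds = []
    counter = 0
    for breed, farm, n in design.groups:
        batches = design.batch_labels(farm)
        for _ in range(n):
            age = int(meta_rng.integers(lo, hi + 1))
            batch = batches[int(meta_rng.integers(len(batches)))]
            records.append({
                "sample_id": f"s{counter + 1:05d}",
                "breed": breed, "farm": farm,
                "company": design.company_of(farm),
                "batch": batch, "age_days": age,
            })
            sample_seeds.append(children[counter + 1])
            counter += 1

    meta_frame = pd.DataFrame.from_records(records).set_index("sample_id")
    stages = assign_age_stage(meta_frame["age_days"].to_numpy())

    # dense per-level shift vectors for fast lookup
    def _dense(table):
        return {level: _shift_vector(model.n_taxa, shifts)
                for level, shifts in table.items()}

    breed_shift = _dense(model.breed_effects)
    farm_shift = _dense(model.farm_effects)
    stage_shift = _dense(model.stage_effects)
    batch_shift = _dense(model.batch_effects)
    zero = np.zeros(model.n_taxa)

    abund = np.empty((n_total, model.n_taxa))
    rpb = np.empty((n_total, model.n_taxa))
    for i, (sid, row) in enumerate(meta_frame.iterrows()):
        rng = np.random.default_rng(sample_seeds[i])
        logmu = (model.base_logmean
                 + breed_shift.get(row["breed"], zero)
                 + farm_shift.get(row["farm"], zero)
                 + stage_shift.get(stages[i], zero)
                 + batch_shift.get(row["batch"], zero))
        noise = rng.normal(0.0, model.dispersion, model.n_taxa) \
            if model.dispersion > 0 else 0.0
        intensity = np.exp(logmu + noise)
        abund[i] = intensity / intensity.sum() * TPM_TOTAL
        jitter = rng.lognormal(0.0, coverage_jitter_sd) \
            if coverage_jitter_sd > 0 else 1.0
        rpb[i] = depth_factor * (abund[i] / TPM_TOTAL) * jitter

    index = meta_frame.index
    tab = AbundanceTable(pd.DataFrame(abund, index=index, columns=taxon_ids),
                         model.taxonomy)
    cov = CoverageStats(pd.DataFrame(rpb, index=index, columns=taxon_ids))
    meta = SampleMetadata(meta_frame)
    return SyntheticCohort(tab, cov, meta, model.planted_truth)


def _shift_vector(n_taxa: int, shifts: Mapping[int, float]) -> np.ndarray:
    v = np.zeros(n_taxa)
    for taxon, shift in shifts.items():
        v[int(taxon)] = float(shift)
    return v


# ---------------------------------------------------------------------------
# Study-shaped defaults
# ---------------------------------------------------------------------------

def study_design(seed: int = 0, scale: float = 1.0,
                 age_range_days: tuple[int, int] = (257, 1906),
                 n_batches: int = 4) -> CohortDesign:
    """The three-breed x three-farm design with the cohort's group sizes.

    ``scale`` shrinks every group proportionally (minimum 2 samples per
    group) for desk-scale runs; at scale 1 the nine groups hold
    34/113/338, 8/108/301 and 498/166/85 animals.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    groups = tuple((b, f, max(2, round(n * scale)) if scale != 1.0 else n)
                   for b, f, n in STUDY_GROUPS)
    return CohortDesign(groups=groups, age_range_days=age_range_days,
                        n_batches=n_batches, seed=seed)


def study_effect_model(n_taxa: int = 300, seed: int = 0,
                       breed_shift: float = 1.2, farm_shift: float = 1.2,
                       stage_shift: float = 0.9, batch_shift: float = 0.4,
                       taxa_per_breed: int = 10, taxa_per_farm: int = 12,
                       taxa_per_stage: int = 8, taxa_per_batch: int = 4,
                       dispersion: float = 1.5) -> EffectModel:
    """A community with planted breed, farm, stage and batch structure.

    Shift magnitudes are fixed design constants chosen so that, at the
    study's group sizes, breed explains a single-digit percentage of
    Bray-Curtis variation with farm comparable and batch a nuisance-sized
    remainder — the qualitative regime the analyses are built for.
    Disjoint taxon blocks are planted per level so the truth table is
    unambiguous.
    """
    model = EffectModel.community(n_taxa=n_taxa, dispersion=dispersion,
                                  seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 915)))
    need = (3 * taxa_per_breed + 3 * taxa_per_farm + 3 * taxa_per_stage
            + 12 * taxa_per_batch)
    if need > n_taxa:
        raise ValueError(f"n_taxa={n_taxa} too small for planted blocks ({need})")
    pool = list(rng.permutation(n_taxa))

    def take(k):
        return [pool.pop() for _ in range(k)]

    for breed in ("Duroc", "Landrace", "LargeWhite"):
        model.add_effect("breed", breed, take(taxa_per_breed), breed_shift)
    for farm in ("A1", "A2", "B1"):
        model.add_effect("farm", farm, take(taxa_per_farm), farm_shift)
    for stage in AGE_STAGES:
        model.add_effect("stage", stage, take(taxa_per_stage), stage_shift)
    for farm in ("A1", "A2", "B1"):
        for j in range(4):
            model.add_effect("batch", f"{farm}.b{j + 1}",
                             take(taxa_per_batch), batch_shift)
    return model


def planted_breed_model(n_taxa: int = 530, taxa_per_breed: int = 10,
                        shift: float = 2.0, dispersion: float = 1.0,
                        seed: int = 0,
                        baseline_rank_range: tuple[int, int] = (40, 200),
                        breeds: tuple[str, ...] = ("Duroc", "Landrace",
                                                   "LargeWhite")) -> EffectModel:
    """Community with strong breed-enriched taxon blocks and known truth.

    Planted taxa are drawn from the mid-high baseline ranks
    (``baseline_rank_range`` in descending base_logmean order): abundant
    enough that the log response is not pinned at the pseudocount floor,
    but not so dominant that boosting them displaces the rest of the
    composition and manufactures spurious depletion signals elsewhere.
    All remaining taxa are effect-free nulls.
    """
    model = EffectModel.community(n_taxa=n_taxa, dispersion=dispersion,
                                  seed=seed)
    lo, hi = baseline_rank_range
    if hi - lo < len(breeds) * taxa_per_breed:
        raise ValueError("baseline_rank_range too narrow for planted blocks")
    order = np.argsort(model.base_logmean)[::-1]
    candidates = [int(i) for i in order[lo:hi]]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 417)))
    rng.shuffle(candidates)
    for i, breed in enumerate(breeds):
        block = candidates[i * taxa_per_breed:(i + 1) * taxa_per_breed]
        model.add_effect("breed", breed, block, shift)
    return model


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, directory: str | os.PathLike) -> dict:
    """Write abundance/coverage/metadata/truth TSVs; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # id consistency is enforced by SyntheticCohort, re-checked before writing
    if cohort.coverage.sample_ids != cohort.abundance.sample_ids:
        raise ValueError("sample ids differ across cohort tables")
    paths = {
        "abundance": directory / "abundance.tsv",
        "coverage": directory / "coverage.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.tsv",
    }
    _abund.write_abundance(cohort.abundance, paths["abundance"])
    _abund.write_coverage(cohort.coverage, paths["coverage"])
    _abund.write_metadata(cohort.metadata, paths["metadata"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    if cohort.abundance.taxonomy is not None:
        paths["taxonomy"] = directory / "taxonomy.tsv"
        _abund.write_taxonomy(cohort.abundance.taxonomy, paths["taxonomy"])
    return {k: str(v) for k, v in paths.items()}


def read_cohort(directory: str | os.PathLike) -> SyntheticCohort:
    directory = Path(directory)
    taxonomy_path = directory / "taxonomy.tsv"
    tab = _abund.read_abundance(
        directory / "abundance.tsv",
        taxonomy_path if taxonomy_path.exists() else None)
    cov = _abund.read_coverage(directory / "coverage.tsv")
    meta = _abund.read_metadata(directory / "metadata.tsv")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t",
                        dtype=str).reindex(columns=["taxon", "factor",
                                                    "level", "sign"])
    return SyntheticCohort(tab, cov, meta, truth)
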