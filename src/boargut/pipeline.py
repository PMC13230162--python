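"""End-to-end orchestration: load/simulate -> gate -> diversity ->
variance partitioning -> bootstrap -> shared taxa -> enrichment.

A single :class:`RunConfig` holds every threshold the analysis uses, each
defaulting to the study's value (coverage gate 1x, abundance rule 1e-5,
prevalence 10% for set analysis and 5% for enrichment, 999 permutations,
1000 bootstrap iterations, stage boundaries 365/1095 days), so deviations
are explicit and auditable.  ``run_all`` writes every stage's TSV output
plus a JSON manifest with a config hash; a rerun with the same config and
seed reproduces the TSVs byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import abundance as ab
from . import diversity as dv
from . import enrichment as en
from . import resampling as rs
from .permanova import variance_partition_by_stratum
from . import shared_taxa as st
from . import synthetic_data as sd
from .containers import AGE_STAGES

logger = logging.getLogger("boargut.pipeline")

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of a full run, defaulting to the study's constants."""

    output_dir: str = "results"
    seed: int = 0
    input_dir: str | None = None          # cohort TSVs; simulate when None
    coverage_threshold: float = 1.0
    abundance_threshold: float = 1e-5
    set_prevalence: float = 0.10
    enrichment_prevalence: float = 0.05
    enrichment_min_mean: float = 1e-5
    permutations: int = 999
    bootstrap_iterations: int = 1000
    inner_permutations: int = 999
    q_threshold: float = 0.05
    min_group_size: int = 10
    young_max_days: int = 365
    mid_max_days: int = 1095
    stability_cutoff: float = 0.95
    # simulation settings used only when input_dir is None
    sim_scale: float = 0.1
    sim_n_taxa: int = 200

    def __post_init__(self):
        for name in ("set_prevalence", "enrichment_prevalence",
                     "abundance_threshold", "enrichment_min_mean",
                     "q_threshold", "stability_cutoff"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.coverage_threshold < 0:
            raise ValueError("coverage_threshold must be nonnegative")
        if self.permutations < 99 or self.inner_permutations < 99:
            raise ValueError("permutation counts must be >= 99")
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")
        if not (0 < self.young_max_days < self.mid_max_days):
            raise ValueError("stage boundaries must satisfy 0 < young < mid")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> sd.SyntheticCohort:
    if config.input_dir is not None:
        cohort = sd.read_cohort(config.input_dir)
        return cohort
    design = sd.study_design(seed=config.seed, scale=config.sim_scale)
    model = sd.study_effect_model(n_taxa=config.sim_n_taxa, seed=config.seed)
    return sd.simulate_cohort(design, model)


def run_all(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "config": asdict(config), "config_hash": config.config_hash(),
        "seed": config.seed, "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                counts = fn() or {}
            except Exception as exc:  # abort with stage name and cause
                raise PipelineError(name, exc) from exc
            elapsed = time.perf_counter() - t0
            manifest["stages"][name] = {"elapsed_s": round(elapsed, 3),
                                        **counts}
            logger.info("stage=%s elapsed=%.2fs %s", name, elapsed, counts)
        return wrap

    state: dict = {}

    @stage("load")
    def _load():
        cohort = _load_inputs(config)
        # ids were cross-checked by SyntheticCohort before any computation
        boundaries = (config.young_max_days, config.mid_max_days)
        if cohort.metadata.stage_boundaries != boundaries:
            frame = cohort.metadata.frame.drop(columns=["age_stage"])
            from .containers import SampleMetadata
            cohort = sd.SyntheticCohort(
                cohort.abundance, cohort.coverage,
                SampleMetadata(frame, boundaries), cohort.truth)
        state["cohort"] = cohort
        return {"n_samples": cohort.abundance.n_samples,
                "n_taxa": cohort.abundance.n_taxa}

    @stage("gate")
    def _gate():
        cohort = state["cohort"]
        tab = ab.normalize_tpm(cohort.abundance)
        gated = ab.coverage_gate(tab, cohort.coverage,
                                 config.coverage_threshold)
        state["gated"] = gated
        ab.write_abundance(gated, outdir / "abundance_gated.tsv")
        return {"n_taxa": gated.n_taxa}

    @stage("diversity")
    def _diversity():
        gated = state["gated"]
        meta = state["cohort"].metadata
        alpha = dv.alpha_diversity(gated)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        mf = meta.align_to(gated.sample_ids).frame
        rows = []
        for farm, sub in mf.groupby("farm"):
            sizes = sub["breed"].value_counts()
            if (sizes >= 2).sum() < 2:
                continue
            keep = sub[sub["breed"].isin(sizes.index[sizes >= 2])]
            cmp_res = dv.compare_groups_alpha(alpha.loc[keep.index],
                                              keep["breed"])
            pw = cmp_res.pairwise.copy()
            pw.insert(0, "farm", farm)
            rows.append(pw)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                outdir / "alpha_comparisons.tsv", sep="\t", index=False)
        d = dv.bray_curtis(gated)
        state["distance"] = d
        ordination = dv.pcoa(d, n_axes=3)
        ordination.coordinates.to_csv(outdir / "pcoa.tsv", sep="\t")
        return {"n_pairs": len(d.condensed_form())}

    @stage("permanova")
    def _permanova():
        meta = state["cohort"].metadata
        d = state["distance"]
        tables = []
        for mode in ("sequential", "marginal"):
            by_farm = variance_partition_by_stratum(
                d, meta, ["breed", "age_stage", "batch"], "farm",
                min_group_size=config.min_group_size,
                n_permutations=config.permutations, mode=mode,
                seed=config.seed)
            for farm, res in by_farm.results.items():
                t = res.table.reset_index()
                t.insert(0, "stratum", farm)
                t.insert(0, "stratify_by", "farm")
                t.insert(0, "mode", mode)
                tables.append(t)
            by_stage = variance_partition_by_stratum(
                d, meta, ["farm", "breed", "batch"], "age_stage",
                min_group_size=config.min_group_size,
                n_permutations=config.permutations, mode=mode,
                seed=config.seed + 1)
            for stg, res in by_stage.results.items():
                t = res.table.reset_index()
                t.insert(0, "stratum", stg)
                t.insert(0, "stratify_by", "age_stage")
                t.insert(0, "mode", mode)
                tables.append(t)
        out = pd.concat(tables, ignore_index=True)
        out.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
        return {"n_fits": int(out["stratum"].nunique())}

    @stage("bootstrap")
    def _bootstrap():
        gated = state["gated"]
        meta = state["cohort"].metadata
        mf = meta.align_to(gated.sample_ids).frame
        summaries = {}
        for farm, sub in mf.groupby("farm"):
            plan = rs.BootstrapPlan(group_by="breed",
                                    n_iterations=config.bootstrap_iterations,
                                    seed=config.seed)
            sub_meta = meta.align_to(list(sub.index))
            sub_tab = gated.select_samples(list(sub.index))
            try:
                per_index = rs.bootstrap_alpha(sub_tab, sub_meta, plan)
            except ValueError:
                continue  # a breed too small to equalise within this farm
            for index_name, summary in per_index.items():
                summaries[f"alpha:{farm}:{index_name}"] = summary
        beta_plan = rs.BootstrapPlan(group_by="breed", cross_with="farm",
                                     n_iterations=config.bootstrap_iterations,
                                     inner_permutations=config.inner_permutations,
                                     seed=config.seed)
        summaries["beta:all:breed"] = rs.bootstrap_beta(gated, meta, beta_plan)
        frame = rs.summaries_to_frame(summaries)
        frame.to_csv(outdir / "bootstrap.tsv", sep="\t", index=False)
        return {"n_summaries": len(frame)}

    @stage("shared_taxa")
    def _shared():
        gated = state["gated"]
        meta = state["cohort"].metadata
        pres = ab.call_presence_by_abundance(gated,
                                             config.abundance_threshold)
        mf = meta.align_to(gated.sample_ids).frame
        frames = []
        for farm in sorted(mf["farm"].unique()):
            fam = st.build_group_sets(pres, meta, "breed",
                                      within=("farm", farm),
                                      min_prevalence=config.set_prevalence)
            rep = st.intersect_report(fam).to_frame()
            rep.insert(0, "scope", f"farm:{farm}")
            frames.append(rep)
        for breed in sorted(mf["breed"].unique()):
            fam = st.build_group_sets(pres, meta, "farm",
                                      within=("breed", breed),
                                      min_prevalence=config.set_prevalence)
            rep = st.intersect_report(fam).to_frame()
            rep.insert(0, "scope", f"breed:{breed}")
            frames.append(rep)
        out = pd.concat(frames, ignore_index=True)
        out.to_csv(outdir / "shared_taxa.tsv", sep="\t", index=False)
        return {"n_rows": len(out)}

    @stage("enrichment")
    def _enrichment():
        gated = state["gated"]
        meta = state["cohort"].metadata
        counts = {}
        runs = {
            "breed": ("breed", ("company", "farm", "batch")),
            "age_stage": ("age_stage", ("company", "farm", "breed", "batch")),
        }
        for label, (primary, covariates) in runs.items():
            res = en.run_enrichment(
                gated, meta, primary=primary, covariates=covariates,
                q_threshold=config.q_threshold,
                min_prev=config.enrichment_prevalence,
                min_mean_relabund=config.enrichment_min_mean)
            records = res.records.copy()
            records["label"] = res.labels.reindex(records["taxon"]).to_numpy()
            records.to_csv(outdir / f"enrichment_{label}.tsv", sep="\t",
                           index=False)
            counts[f"{label}_labelled"] = int((res.labels != "none").sum())
        return counts

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
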