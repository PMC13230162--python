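"""Variance partitioning: algebraic identities and independent oracles.

The strongest checks are external: classical ANOVA sums of squares on
Euclidean 1-D responses (statsmodels), exhaustive permutation enumeration
at n=6, and vegan's adonis2 run through Rscript on a fixed cohort.
"""
import itertools
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from statsmodels.formula.api import ols

import boargut as bg
from boargut import diversity as dv
from boargut.permanova import (gower_center, parse_formula,
                               variance_partition_by_stratum)
from boargut.permanova import permanova as fit_permanova


def _meta(frame):
    frame = frame.copy()
    defaults = {"breed": "D", "farm": "F1", "company": "A", "batch": "b1",
                "age_days": 500}
    for col, val in defaults.items():
        if col not in frame:
            frame[col] = val
    frame.index = [f"s{i}" for i in range(len(frame))]
    frame.index.name = "sample_id"
    return bg.SampleMetadata(frame)


def _euclid_dm(y):
    y = np.asarray(y, dtype=float)[:, None]
    ids = [f"s{i}" for i in range(len(y))]
    return DistanceMatrix(squareform(pdist(y)), ids=ids)


class TestGowerCenter:
    def test_two_points_trace_is_half_squared_distance(self):
        G = gower_center(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.trace(G) == pytest.approx(0.5, abs=1e-12)

    def test_zero_distances_zero_matrix(self):
        G = gower_center(np.zeros((4, 4)))
        assert np.allclose(G, 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 3))
        G = gower_center(squareform(pdist(pts)))
        assert np.allclose(G.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(G, G.T)

    def test_rejects_asymmetric(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            gower_center(D)


class TestSequentialEqualsClassicalAnova:
    """On |y_i - y_j| distances, term SS must equal ANOVA type-I SS."""

    def test_two_factor_unbalanced_model(self):
        rng = np.random.default_rng(5)
        n = 40
        frame = pd.DataFrame({
            "breed": rng.choice(["D", "L", "W"], n),
            "batch": rng.choice(["b1", "b2"], n),
        })
        y = rng.normal(size=n) + (frame["breed"] == "D") * 1.0
        res = fit_permanova(_euclid_dm(y), _meta(frame), ["breed", "batch"],
                           n_permutations=99, seed=0)
        data = frame.assign(y=y)
        fit = ols("y ~ C(breed) + C(batch)", data=data).fit()
        anova = sm.stats.anova_lm(fit, typ=1)
        assert res.table.loc["breed", "sum_sq"] == \
            pytest.approx(anova.loc["C(breed)", "sum_sq"], abs=1e-8)
        assert res.table.loc["batch", "sum_sq"] == \
            pytest.approx(anova.loc["C(batch)", "sum_sq"], abs=1e-8)
        assert res.table.loc["Residual", "sum_sq"] == \
            pytest.approx(anova.loc["Residual", "sum_sq"], abs=1e-8)
        assert res.table.loc["breed", "pseudo_f"] == \
            pytest.approx(anova.loc["C(breed)", "F"], abs=1e-8)

    def test_decomposition_exact(self, balanced_cohort):
        d = dv.bray_curtis(balanced_cohort.abundance)
        res = fit_permanova(d, balanced_cohort.metadata,
                           ["breed", "age_stage", "batch"],
                           n_permutations=99, seed=1)
        terms = res.table.drop(index=["Total"])["sum_sq"].sum()
        assert terms == pytest.approx(res.table.loc["Total", "sum_sq"],
                                      rel=1e-8)
        r2 = res.table.drop(index=["Total"])["r_squared"]
        assert ((r2 >= -1e-12) & (r2 <= 1 + 1e-12)).all()


class TestPermutationPvalue:
    def test_matches_exhaustive_enumeration_two_groups_n6(self):
        """999 free permutations vs all C(6,3)=20 label assignments."""
        y = np.array([0.1, 0.3, 0.2, 1.4, 1.7, 1.5])
        labels = ["A", "A", "A", "B", "B", "B"]
        d = _euclid_dm(y)
        res = fit_permanova(d, _meta(pd.DataFrame({"breed": labels})),
                           ["breed"], n_permutations=999, seed=3)

        # oracle: enumerate all distinct 3/3 splits, compute F directly
        def f_stat(assign):
            groups = {}
            for v, a in zip(y, assign):
                groups.setdefault(a, []).append(v)
            gm = y.mean()
            ss_b = sum(len(g) * (np.mean(g) - gm) ** 2
                       for g in groups.values())
            ss_w = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                       for g in groups.values())
            return (ss_b / 1) / (ss_w / 4)

        f_obs = f_stat(labels)
        fs = [f_stat(["A" if i in comb else "B" for i in range(6)])
              for comb in itertools.combinations(range(6), 3)]
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.p_value("breed") == pytest.approx(exact_p, abs=0.05)

    def test_reproducible_given_seed_and_stable_across_seeds(self,
                                                             balanced_cohort):
        d = dv.bray_curtis(balanced_cohort.abundance)
        meta = balanced_cohort.metadata
        a = fit_permanova(d, meta, ["breed"], n_permutations=999, seed=10)
        b = fit_permanova(d, meta, ["breed"], n_permutations=999, seed=10)
        assert a.p_value("breed") == b.p_value("breed")
        c = fit_permanova(d, meta, ["breed"], n_permutations=999, seed=11)
        p = a.p_value("breed")
        se = np.sqrt(max(p * (1 - p), 1e-6) / 999)
        assert abs(c.p_value("breed") - p) <= max(2 * se, 2 / 999)

    def test_equal_distances_give_uniform_split(self):
        """Exchangeable degenerate case: R2 = df/(n-1), pseudo-F ~ 1."""
        n = 12
        d = DistanceMatrix(1 - np.eye(n), ids=[f"s{i}" for i in range(n)])
        frame = pd.DataFrame({"breed": ["D", "L", "W"] * 4,
                              "batch": ["b1", "b2"] * 6})
        res = fit_permanova(d, _meta(frame), ["breed", "batch"],
                           n_permutations=99, seed=0)
        for term in ("breed", "batch"):
            df = res.table.loc[term, "df"]
            assert res.table.loc[term, "r_squared"] == \
                pytest.approx(df / (n - 1), abs=1e-8)
            assert res.table.loc[term, "pseudo_f"] == pytest.approx(1.0,
                                                                    abs=1e-8)


class TestModes:
    def test_marginal_equals_sequential_for_orthogonal_balanced_design(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({
            "breed": np.repeat(["D", "L"], 8),
            "batch": np.tile(["b1", "b2"], 8),  # fully crossed, balanced
        })
        y = rng.normal(size=16)
        d = _euclid_dm(y)
        meta = _meta(frame)
        seq = fit_permanova(d, meta, ["breed", "batch"], 99, "sequential", 0)
        marg = fit_permanova(d, meta, ["breed", "batch"], 99, "marginal", 0)
        for term in ("breed", "batch"):
            assert seq.table.loc[term, "sum_sq"] == \
                pytest.approx(marg.table.loc[term, "sum_sq"], abs=1e-8)

    def test_confounded_term_flagged_df_zero(self):
        frame = pd.DataFrame({"breed": ["D", "D", "L", "L", "W", "W"],
                              "farm": ["F1", "F1", "F2", "F2", "F3", "F3"]})
        y = [0.0, 0.2, 1.0, 1.1, 2.0, 2.2]
        res = fit_permanova(_euclid_dm(y), _meta(frame), ["breed", "farm"],
                           n_permutations=99, seed=0)
        assert res.table.loc["farm", "df"] == 0
        assert res.flags["farm"] == "confounded"
        assert np.isnan(res.table.loc["farm", "p_value"])

    def test_too_few_samples_rejected(self):
        frame = pd.DataFrame({"breed": ["D", "L", "W", "D", "L", "W"],
                              "batch": ["b1", "b2", "b3", "b4", "b5", "b6"]})
        with pytest.raises(ValueError, match="too few samples"):
            fit_permanova(_euclid_dm([1, 2, 3, 4, 5, 6]), _meta(frame),
                         ["breed", "batch"], n_permutations=99, seed=0)


class TestAgainstVegan:
    def test_matches_adonis2_sums_of_squares(self, tmp_path, balanced_cohort):
        """Independent oracle: vegan::adonis2 on the same distances."""
        d = dv.bray_curtis(balanced_cohort.abundance)
        meta = balanced_cohort.metadata
        ours = {mode: fit_permanova(d, meta, ["breed", "age_stage", "batch"],
                                   n_permutations=99, mode=mode, seed=0)
                for mode in ("sequential", "marginal")}
        np.savetxt(tmp_path / "D.tsv", d.data, delimiter="\t")
        meta.frame.to_csv(tmp_path / "meta.tsv", sep="\t")
        script = tmp_path / "adonis.R"
        script.write_text(
            "suppressMessages(library(vegan))\n"
            "D <- as.dist(as.matrix(read.table('D.tsv')))\n"
            "meta <- read.table('meta.tsv', header=TRUE, sep='\\t')\n"
            "for (by in c('terms','margin')) {\n"
            "  r <- adonis2(D ~ breed + age_stage + batch, data=meta,\n"
            "               permutations=99, by=by)\n"
            "  write.csv(r, paste0('adonis_', by, '.csv'))\n"
            "}\n")
        subprocess.run(["Rscript", script.name], cwd=tmp_path, check=True,
                       capture_output=True)
        for mode, by in (("sequential", "terms"), ("marginal", "margin")):
            ref = pd.read_csv(tmp_path / f"adonis_{by}.csv", index_col=0)
            for term in ("breed", "age_stage", "batch"):
                assert ours[mode].table.loc[term, "sum_sq"] == \
                    pytest.approx(ref.loc[term, "SumOfSqs"], rel=1e-6)
                assert ours[mode].table.loc[term, "r_squared"] == \
                    pytest.approx(ref.loc[term, "R2"], rel=1e-6)


class TestStratified:
    def _cohort(self):
        groups = [("Duroc", "A2", 8), ("Landrace", "A2", 25),
                  ("LargeWhite", "A2", 30), ("Duroc", "B1", 25),
                  ("Landrace", "B1", 15), ("LargeWhite", "B1", 12)]
        design = bg.CohortDesign(groups=groups, seed=21, n_batches=2)
        model = bg.EffectModel.community(n_taxa=60, dispersion=1.0, seed=21)
        model.add_effect("breed", "Duroc", [0, 1, 2], 1.5)
        return bg.simulate_cohort(design, model)

    def test_small_breed_group_excluded_before_fit(self):
        cohort = self._cohort()
        d = dv.bray_curtis(cohort.abundance)
        fit = variance_partition_by_stratum(
            d, cohort.metadata, ["breed", "age_stage", "batch"], "farm",
            min_group_size=10, n_permutations=99, seed=0)
        assert fit.excluded["A2"] == {"Duroc": 8}
        # the A2 fit ran on the remaining two breeds only
        a2 = fit.results["A2"].table
        assert a2.loc["Total", "df"] == 25 + 30 - 1

    def test_degenerate_stratum_skipped_with_reason(self):
        cohort = self._cohort()
        d = dv.bray_curtis(cohort.abundance)
        fit = variance_partition_by_stratum(
            d, cohort.metadata, ["breed"], "farm",
            min_group_size=26, n_permutations=99, seed=0)
        assert "A2" in fit.skipped and "B1" in fit.skipped
        assert fit.results == {}

    def test_planted_breed_effect_beats_batch(self):
        """Breed R2 exceeds batch R2 in nearly all replicates."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            design = bg.CohortDesign(
                groups=[("Duroc", "B1", 25), ("Landrace", "B1", 15),
                        ("LargeWhite", "B1", 12)], seed=seed, n_batches=2)
            model = bg.EffectModel.community(n_taxa=60, dispersion=1.0,
                                             seed=seed)
            for j, b in enumerate(["Duroc", "Landrace", "LargeWhite"]):
                model.add_effect("breed", b, [3 * j, 3 * j + 1, 3 * j + 2],
                                 1.5)
            cohort = bg.simulate_cohort(design, model)
            d = dv.bray_curtis(cohort.abundance)
            fit = variance_partition_by_stratum(
                d, cohort.metadata, ["breed", "batch"], "farm",
                min_group_size=10, n_permutations=99, seed=seed)
            table = fit.results["B1"].table
            if table.loc["breed", "r_squared"] > table.loc["batch",
                                                           "r_squared"]:
                wins += 1
        assert wins >= int(0.9 * n_rep)


def test_parse_formula():
    assert parse_formula("d ~ breed + age_stage + batch") == \
        ["breed", "age_stage", "batch"]
    assert parse_formula("breed+batch") == ["breed", "batch"]
    with pytest.raises(ValueError):
        parse_formula("d ~ ")
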