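"""Size factors, NB-Wald fitting, BH adjustment and contrast orchestration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tyhybrid.detest import (
    Contrast,
    DesignSpec,
    bh_adjust,
    design_matrix,
    dispersion_moments,
    nb_wald_fit,
    run_contrasts,
    size_factors,
    summarize_contrasts,
)
from tyhybrid.simulate import nb_counts, rng_for


def _two_group_sheet(n_per_group, levels=("parent", "hybrid")):
    ids = [f"{lvl}_r{i}" for lvl in levels for i in range(n_per_group)]
    sheet = pd.DataFrame({
        "sample_id": ids,
        "species": [lvl for lvl in levels for _ in range(n_per_group)],
    }).set_index("sample_id", drop=False)
    sheet.index.name = None
    return sheet


class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_closed_form(self):
        counts = pd.DataFrame({"a": [10, 25, 40], "b": [20, 50, 80]})
        s = size_factors(counts)
        assert s["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert s["b"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 500, (40, 5)))
        shuffled = counts.sample(frac=1, random_state=1)
        pd.testing.assert_series_equal(size_factors(counts),
                                       size_factors(shuffled))

    def test_scaling_one_sample_scales_relative_factors(self):
        # multiplying one sample by c multiplies its size factor relative to
        # every other sample by c (geometric means rescale uniformly, so the
        # absolute factors shift by c^(1/n) but all ratios behave linearly)
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 500, (60, 4)),
                              columns=list("abcd"))
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 5
        s0, s1 = size_factors(counts), size_factors(scaled)
        for other in "abd":
            assert s1["c"] / s1[other] == pytest.approx(
                5 * s0["c"] / s0[other]
            )
            assert s1[other] / s1["a"] == pytest.approx(s0[other] / s0["a"])

    def test_no_all_positive_feature_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="all-positive"):
            size_factors(counts)


class TestDesignMatrix:
    def test_treatment_coding_with_reference(self):
        sheet = _two_group_sheet(2)
        spec = DesignSpec(terms=["species"],
                          contrast="species_hybrid_vs_parent",
                          reference={"species": "parent"})
        X = design_matrix(sheet, spec)
        assert list(X.columns) == ["Intercept", "species_hybrid_vs_parent"]
        assert X.loc["hybrid_r0", "species_hybrid_vs_parent"] == 1.0
        assert X.loc["parent_r0", "species_hybrid_vs_parent"] == 0.0

    def test_interaction_columns(self):
        sheet = _two_group_sheet(2)
        sheet["temperature"] = ["30", "12"] * 2
        spec = DesignSpec(
            terms=["temperature", "species", ("species", "temperature")],
            contrast="species_hybrid_vs_parent:temperature_30_vs_12",
            reference={"species": "parent", "temperature": "12"},
        )
        X = design_matrix(sheet, spec)
        inter = X["species_hybrid_vs_parent:temperature_30_vs_12"]
        for sid in sheet.index:
            expect = float(sheet.loc[sid, "species"] == "hybrid"
                           and sheet.loc[sid, "temperature"] == "30")
            assert inter[sid] == expect

    def test_rank_deficient_design_rejected(self):
        sheet = _two_group_sheet(2)
        sheet["copy"] = sheet["species"]
        spec = DesignSpec(terms=["species", "copy"],
                          contrast="species_hybrid_vs_hybrid")
        with pytest.raises(ValueError, match="full rank"):
            design_matrix(sheet, spec)


class TestNbWald:
    def test_identical_groups_give_null_result(self):
        col = [100, 220, 310, 47, 500]
        counts = pd.DataFrame({f"s{i}": col for i in range(6)})
        sheet = _two_group_sheet(3)
        counts.columns = sheet.index
        sf = size_factors(counts)
        spec = DesignSpec(terms=["species"],
                          contrast="species_hybrid_vs_parent",
                          reference={"species": "parent"})
        res = nb_wald_fit(counts, sf, spec, samples=sheet)
        assert np.allclose(res["log2FoldChange"], 0.0, atol=1e-6)
        assert (res["pvalue"] > 0.999).all()

    def test_all_zero_feature_missing_p(self):
        counts = pd.DataFrame(
            {"s0": [0, 10], "s1": [0, 12], "s2": [0, 9], "s3": [0, 11]},
            index=["zero", "ok"],
        )
        sheet = _two_group_sheet(2)
        counts.columns = sheet.index
        sf = pd.Series(1.0, index=counts.columns)
        spec = DesignSpec(terms=["species"],
                          contrast="species_hybrid_vs_parent",
                          reference={"species": "parent"})
        res = nb_wald_fit(counts, sf, spec, samples=sheet)
        assert np.isnan(res.loc["zero", "pvalue"])
        assert np.isfinite(res.loc["ok", "pvalue"])

    def test_fold_change_recovery(self):
        """Median estimated log2FC near the planted value at fold 4."""
        rng = rng_for(42, "recovery")
        n = 8
        mu = np.concatenate([np.full(n, 500.0), np.full(n, 2000.0)])
        counts = pd.DataFrame(
            nb_counts(np.tile(mu, (50, 1)), 0.05, rng),
        )
        sheet = _two_group_sheet(n)
        counts.columns = sheet.index
        sf = pd.Series(1.0, index=counts.columns)
        spec = DesignSpec(terms=["species"],
                          contrast="species_hybrid_vs_parent",
                          reference={"species": "parent"})
        res = nb_wald_fit(counts, sf, spec, samples=sheet, dispersion=0.05)
        med = res["log2FoldChange"].median()
        assert 1.8 <= med <= 2.2

    def test_agreement_with_statsmodels_oracle(self):
        """log2FC and p match an independent NB-GLM fit per feature."""
        import statsmodels.api as sm

        rng = rng_for(7, "oracle")
        means = np.exp(rng.normal(np.log(300), 1, 20))
        fc = np.exp(rng.normal(0, 0.5, 20))
        mu = np.concatenate(
            [np.tile(means[:, None], 3), np.tile((means * fc)[:, None], 3)],
            axis=1,
        )
        counts = pd.DataFrame(nb_counts(mu, 0.05, rng))
        sheet = _two_group_sheet(3)
        counts.columns = sheet.index
        sf = size_factors(counts)
        spec = DesignSpec(terms=["species"],
                          contrast="species_hybrid_vs_parent",
                          reference={"species": "parent"})
        X = design_matrix(sheet, spec).to_numpy()
        alphas = dispersion_moments(counts, sf, X)
        res = nb_wald_fit(counts, sf, spec, samples=sheet, dispersion=alphas)
        for fid in counts.index:
            y = counts.loc[fid].to_numpy(float)
            fit = sm.GLM(
                y, X,
                family=sm.families.NegativeBinomial(
                    alpha=max(float(alphas[fid]), 1e-8)
                ),
                offset=np.log(sf.to_numpy()),
            ).fit()
            assert abs(res.loc[fid, "log2FoldChange"]
                       - fit.params[1] / np.log(2)) <= 0.05
            p_o, p_m = fit.pvalues[1], res.loc[fid, "pvalue"]
            assert p_o / 2 <= p_m <= p_o * 2 or p_o < 1e-12

    def test_null_pvalues_uniform(self):
        """Wald p under the global null with known dispersion is ~U(0,1)."""
        rng = rng_for(3, "uniform")
        mu = np.full((1000, 12), 300.0)
        counts = pd.DataFrame(nb_counts(mu, 0.05, rng))
        sheet = _two_group_sheet(6)
        counts.columns = sheet.index
        sf = pd.Series(1.0, index=counts.columns)
        spec = DesignSpec(terms=["species"],
                          contrast="species_hybrid_vs_parent",
                          reference={"species": "parent"})
        res = nb_wald_fit(counts, sf, spec, samples=sheet, dispersion=0.05)
        _, p = stats.kstest(res["pvalue"].dropna(), "uniform")
        assert p > 0.01


class TestBh:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_missing_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m = 2, rank 1
        assert adj[2] == pytest.approx(0.04)

    def test_padj_at_least_p_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestRunContrasts:
    @staticmethod
    def _study(seed, fold_change=1.0, n_rep=6, n_genes=60):
        rng = rng_for(seed, "study")
        sheet = pd.DataFrame({
            "sample_id": [f"{g}_r{i}" for g in ("p1", "hybrid")
                          for i in range(n_rep)],
            "species": ["p1"] * n_rep + ["hybrid"] * n_rep,
        }).set_index("sample_id", drop=False)
        sheet.index.name = None
        means = np.exp(rng.normal(np.log(300), 0.8, n_genes + 1))
        mu = np.tile(means[:, None], 2 * n_rep)
        mu[0, n_rep:] *= fold_change  # feature 0 is the Ty family
        idx = ["Ty1_p1"] + [f"g{i:03d}_p1" for i in range(n_genes)]
        counts = pd.DataFrame(nb_counts(mu, 0.05, rng), index=idx,
                              columns=sheet.index)
        subgenome = pd.Series("p1", index=idx)
        return counts, sheet, subgenome

    def test_planted_up_family_detected(self):
        hits = 0
        for seed in range(10):
            counts, sheet, sub = self._study(seed, fold_change=2.0, n_rep=12)
            res = run_contrasts(
                counts, sheet, sub,
                [Contrast(name="hvp", focal_parent="p1")],
            )["hvp"]
            if res.loc["Ty1_p1", "significant"] and (
                res.loc["Ty1_p1", "log2FoldChange"] > 0
            ):
                hits += 1
        assert hits >= 9

    def test_non_focal_features_never_tested(self, ds2_run):
        counts = ds2_run.sim_counts.counts
        sheet = ds2_run.samples
        sub = pd.Series(
            {f: ("p1" if f.endswith("_p1") else "p2") for f in counts.index}
        )
        results = run_contrasts(
            counts, sheet, sub,
            [Contrast(name="hv1", focal_parent="p1"),
             Contrast(name="hv2", focal_parent="p2")],
        )
        assert not any(f.endswith("_p2") for f in results["hv1"].index)
        assert not any(f.endswith("_p1") for f in results["hv2"].index)

    def test_too_few_replicates_error(self):
        counts, sheet, sub = self._study(0, n_rep=6)
        single = sheet.iloc[[0] + list(range(6, 12))]
        with pytest.raises(ValueError, match="replicate"):
            run_contrasts(counts[single.index], single, sub,
                          [Contrast(name="x", focal_parent="p1")])

    def test_summary_counts_significant_families(self):
        counts, sheet, sub = self._study(1, fold_change=4.0, n_rep=12)
        results = run_contrasts(counts, sheet, sub,
                                [Contrast(name="hvp", focal_parent="p1")])
        summary = summarize_contrasts(results, ty_features=["Ty1_p1"])
        assert summary.loc["hvp", "ty_up"] == 1
        assert summary.loc["hvp", "n_tested"] == len(counts)


class TestNormalizedExchangeability:
    def test_equal_expression_is_exchangeable_after_normalization(self):
        """Kruskal-Wallis across samples on equal-expression features is
        non-significant for the vast majority of seeds."""
        n_reject = 0
        for seed in range(20):
            rng = rng_for(seed, "exch")
            depth = np.array([0.5, 0.8, 1.0, 1.2, 2.0, 3.0])
            mu = np.outer(np.full(80, 200.0), depth)
            counts = pd.DataFrame(nb_counts(mu, 0.02, rng))
            sf = size_factors(counts)
            norm = counts.div(sf, axis=1)
            _, p = stats.kruskal(*[norm[c] for c in norm.columns])
            if p < 0.01:
                n_reject += 1
        assert n_reject <= 1
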