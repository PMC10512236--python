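"""Windowed identity, cross-mapping rate estimation and count correction."""

import numpy as np
import pandas as pd
import pytest

from tyhybrid.annotations import make_feature
from tyhybrid.crossmap import (
    correct_counts,
    estimate_crossmap_rates,
    flag_excluded_families,
    mask_region_for_family,
    windowed_identity,
)


class TestWindowedIdentity:
    def test_identical_sequences_full_identity(self):
        msa = [("cer", "ACGT" * 50), ("par", "ACGT" * 50)]
        prof = windowed_identity(msa, window=100)
        assert len(prof) == 2
        assert (prof["identity"] == 100.0).all()

    def test_ten_substitutions_per_window_is_ninety(self):
        a = "A" * 200
        b = "C" * 10 + "A" * 90 + "C" * 10 + "A" * 90
        prof = windowed_identity([("cer", a), ("par", b)], window=100)
        assert list(prof["identity"]) == [90.0, 90.0]

    def test_indel_columns_ignored(self):
        # 10 gap columns + 90 matches: identity over 90 compared positions
        a = "-" * 10 + "A" * 90
        b = "C" * 10 + "A" * 90
        prof = windowed_identity([("cer", a), ("par", b)], window=100)
        assert prof["identity"].iloc[0] == pytest.approx(100.0)

    def test_fully_gapped_window_missing(self):
        a = "-" * 100 + "A" * 100
        b = "C" * 100 + "A" * 100
        prof = windowed_identity([("cer", a), ("par", b)], window=100)
        assert np.isnan(prof["identity"].iloc[0])
        assert prof["identity"].iloc[1] == 100.0

    def test_symmetric_in_species_order(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 250))
        b = "".join(rng.choice(list("ACGT"), 250))
        p1 = windowed_identity([("cer", a), ("par", b)])
        p2 = windowed_identity([("par", b), ("cer", a)])
        pd.testing.assert_frame_equal(p1, p2)

    def test_intraspecific_pairs_excluded(self):
        msa = [("cer", "AAAA"), ("cer", "TTTT"), ("par", "AAAA")]
        prof = windowed_identity(msa, window=4)
        # only cer-par pairs count: identities 100 and 0 -> mean 50
        assert prof["identity"].iloc[0] == pytest.approx(50.0)

    def test_matches_planted_divergence(self, genomes, sim_config):
        a = genomes.planted[("p1", "Ty1")].internal
        b = genomes.planted[("p2", "Ty1")].internal
        prof = windowed_identity([("p1", a), ("p2", b)], window=100)
        mean_identity = prof["identity"].mean()
        assert mean_identity == pytest.approx(100 * (1 - sim_config.divergence),
                                              abs=1.5)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError, match="2 species"):
            windowed_identity([("cer", "ACGT"), ("cer", "ACGT")])


class TestRateEstimation:
    def test_zero_cognate_gives_zero(self):
        counts = pd.DataFrame({"s1": {"Ty1_cer": 100, "Ty1_par": 0}})
        rates = estimate_crossmap_rates(counts, [("Ty1_cer", "Ty1_par")])
        assert rates.get("Ty1_cer", "Ty1_par") == 0.0

    def test_twelve_percent_arithmetic(self):
        counts = pd.DataFrame({"s1": {"Ty1_cer": 88, "Ty1_par": 12}})
        rates = estimate_crossmap_rates(counts, [("Ty1_cer", "Ty1_par")])
        assert rates.get("Ty1_cer", "Ty1_par") == pytest.approx(0.12)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"s1": {"A": 400, "B": 100}})
        scaled = counts * 7
        r1 = estimate_crossmap_rates(counts, [("A", "B")])
        r2 = estimate_crossmap_rates(scaled, [("A", "B")])
        assert r1.get("A", "B") == pytest.approx(r2.get("A", "B"))

    def test_replicates_pooled_by_summing(self):
        counts = pd.DataFrame(
            {"r1": {"A": 90, "B": 10}, "r2": {"A": 10, "B": 90}}
        )
        rates = estimate_crossmap_rates(counts, [("A", "B")])
        assert rates.get("A", "B") == pytest.approx(0.5)

    def test_zero_total_is_missing(self):
        counts = pd.DataFrame({"s1": {"A": 0, "B": 0}})
        rates = estimate_crossmap_rates(counts, [("A", "B")])
        assert np.isnan(rates.get("A", "B"))

    def test_recovery_from_simulated_reads(self, sim_config, genomes,
                                           separate_ref, tmp_path):
        """Rate estimated from a parental library on own + cognate refs."""
        from tyhybrid.quantify import CountOptions, build_count_matrix
        from tyhybrid.simulate import SimConfig, simulate_reads

        true_rate = 0.08
        n_reads = 20000
        cfg = SimConfig(**{**sim_config.__dict__, "crossmap_rate": true_rate})
        counts_in = pd.DataFrame({"p1_r1": {"Ty1_p1": n_reads}})
        reads = simulate_reads(cfg, separate_ref, counts_in, genomes, tmp_path,
                               dialect="separate")
        observed = build_count_matrix(
            reads.sam_paths, separate_ref.features,
            CountOptions(stranded="reverse"),
        )
        rates = estimate_crossmap_rates(observed, [("Ty1_p1", "Ty1_p2")])
        est = rates.get("Ty1_p1", "Ty1_p2")
        sigma = np.sqrt(true_rate * (1 - true_rate) / n_reads)
        assert abs(est - true_rate) <= 3 * sigma


class TestCorrection:
    def test_twelve_percent_inflation(self):
        counts = pd.DataFrame({"s1": {"Ty1_cer": 100.0, "g1": 50.0}})
        rates = estimate_crossmap_rates(
            pd.DataFrame({"p": {"Ty1_cer": 88, "Ty1_par": 12}}),
            [("Ty1_cer", "Ty1_par")],
        )
        out = correct_counts(counts, rates, "Ty1_cer", "Ty1_par")
        assert out.loc["Ty1_cer", "s1"] == pytest.approx(112.0)
        assert out.loc["g1", "s1"] == 50.0

    def test_zero_rate_identity(self):
        counts = pd.DataFrame({"s1": {"A": 100.0}})
        rates = estimate_crossmap_rates(
            pd.DataFrame({"p": {"A": 10, "B": 0}}), [("A", "B")]
        )
        pd.testing.assert_frame_equal(correct_counts(counts, rates, "A", "B"),
                                      counts)

    def test_missing_rate_errors(self):
        from tyhybrid.crossmap import CrossmapRates

        counts = pd.DataFrame({"s1": {"A": 1.0}})
        with pytest.raises(KeyError):
            correct_counts(counts, CrossmapRates({}), "A", "B")

    def test_linear_and_order_independent(self):
        from tyhybrid.crossmap import CrossmapRates

        rates = CrossmapRates({("A", "B"): 0.1, ("C", "D"): 0.2})
        counts = pd.DataFrame({"s1": {"A": 10.0, "C": 20.0},
                               "s2": {"A": 5.0, "C": 2.0}})
        ab_first = correct_counts(correct_counts(counts, rates, "A", "B"),
                                  rates, "C", "D")
        cd_first = correct_counts(correct_counts(counts, rates, "C", "D"),
                                  rates, "A", "B")
        pd.testing.assert_frame_equal(ab_first, cd_first)

    def test_correction_restores_truth(self, sim_config, genomes,
                                       separate_ref, tmp_path):
        from tyhybrid.quantify import CountOptions, build_count_matrix
        from tyhybrid.simulate import SimConfig, simulate_reads

        true_rate = 0.08
        n_reads = 20000
        cfg = SimConfig(**{**sim_config.__dict__, "crossmap_rate": true_rate})
        counts_in = pd.DataFrame({"p1_r1": {"Ty1_p1": n_reads}})
        reads = simulate_reads(cfg, separate_ref, counts_in, genomes, tmp_path,
                               dialect="separate")
        observed = build_count_matrix(
            reads.sam_paths, separate_ref.features,
            CountOptions(stranded="reverse"),
        )
        rates = estimate_crossmap_rates(observed, [("Ty1_p1", "Ty1_p2")])
        r = rates.get("Ty1_p1", "Ty1_p2")
        corrected = correct_counts(observed, rates, "Ty1_p1", "Ty1_p2")
        # the linear inflation restores n*(1 - r^2): exact up to the
        # second-order term the scalar correction rule leaves behind
        assert corrected.loc["Ty1_p1", "p1_r1"] == pytest.approx(
            n_reads * (1 - r**2), rel=1e-9
        )
        # relative restoration error is bounded by r^2
        rel_err = abs(corrected.loc["Ty1_p1", "p1_r1"] - n_reads) / n_reads
        assert rel_err <= true_rate**2 * 1.5


class TestExclusionFlag:
    def test_swamped_low_expression_family_flagged(self):
        from tyhybrid.crossmap import CrossmapRates

        counts = pd.DataFrame({"s": {"Ty1_cer": 1000.0, "Ty1_par": 100.0}})
        rates = CrossmapRates({("Ty1_cer", "Ty1_par"): 0.12})
        assert flag_excluded_families(counts, rates) == ["Ty1_par"]

    def test_balanced_pair_not_flagged(self):
        from tyhybrid.crossmap import CrossmapRates

        counts = pd.DataFrame({"s": {"Ty1_cer": 300.0, "Ty1_par": 250.0}})
        rates = CrossmapRates({("Ty1_cer", "Ty1_par"): 0.12})
        assert flag_excluded_families(counts, rates) == []

    def test_low_rate_not_flagged(self):
        from tyhybrid.crossmap import CrossmapRates

        counts = pd.DataFrame({"s": {"Ty1_cer": 1000.0, "Ty1_par": 100.0}})
        rates = CrossmapRates({("Ty1_cer", "Ty1_par"): 0.02})
        assert flag_excluded_families(counts, rates) == []


class TestRegionMask:
    def test_gag_exclusion_leaves_pol_remainder(self):
        feats = [make_feature("Ty1", 0, 5000, "+", "transcript",
                              transcript_id="Ty1")]
        out = mask_region_for_family(feats, "Ty1", (0, 1600))
        spans = [(f.start, f.end) for f in out]
        assert spans == [(1600, 5000)]

    def test_interior_region_splits_feature(self):
        feats = [make_feature("Ty1", 0, 5000, "+", "transcript",
                              transcript_id="Ty1")]
        out = mask_region_for_family(feats, "Ty1", (1000, 1600))
        assert [(f.start, f.end) for f in out] == [(0, 1000), (1600, 5000)]

    def test_empty_region_unchanged(self):
        feats = [make_feature("Ty1", 0, 5000, "+", "transcript",
                              transcript_id="Ty1")]
        assert mask_region_for_family(feats, "Ty1", (100, 100)) == feats

    def test_region_outside_feature_raises(self):
        feats = [make_feature("Ty1", 0, 5000, "+", "transcript",
                              transcript_id="Ty1")]
        with pytest.raises(ValueError, match="outside"):
            mask_region_for_family(feats, "Ty1", (4000, 6000))

    def test_counts_drop_by_excluded_region_reads(self, ds2_run, separate_ref):
        """Counting on the GAG-masked feature loses exactly the fragments
        confined to the excluded region."""
        from tyhybrid.quantify import CountOptions, count_features

        pf = ds2_run.genomes.planted[("p1", "Ty1")]
        ltr = len(pf.ltr)
        # GAG interval on the separate-dialect internal-only contig
        gag = (max(0, pf.gag.start - ltr), pf.gag.end - ltr)
        feats = [f for f in separate_ref.features
                 if f.attr("transcript_id") == "Ty1_p1"]
        masked = mask_region_for_family(feats, "Ty1_p1", gag)
        sample, path = next(iter(ds2_run.reads.sam_paths.items()))
        opts = CountOptions(stranded="reverse")
        full = count_features(path, feats, opts)["Ty1_p1"]
        restricted = count_features(path, masked, opts)["Ty1_p1"]
        # fragments overlapping only the GAG region are lost
        truth = ds2_run.reads.truth
        t = truth[(truth["sample"] == sample)
                  & (truth.placed_contig == "Ty1_p1_I")]
        lost = ((t.true_pos + t.fragment_len <= gag[1])
                & (t.true_pos >= gag[0])).sum()
        assert full - restricted == lost
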