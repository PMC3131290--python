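"""Expression preprocessing, the genotype+litter model, FDR, permutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import nullchip as nc
from nullchip.expression import (DesignMatrixError, ExpressionStudy,
                                 count_litter_permutations)


def make_study(values, genotypes, litters, genes=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame({"genotype": genotypes, "litter": litters}, index=samples)
    det = pd.DataFrame(0.99, index=genes, columns=samples)
    return ExpressionStudy(expr=expr, meta=meta, detection=det)


class TestBackgroundCorrect:
    def test_zero_controls_are_identity(self, rng):
        raw = pd.DataFrame(rng.uniform(100, 500, size=(10, 3)), columns=list("abc"))
        out = nc.background_correct(raw, pd.Series(0.0, index=list("abc")))
        pd.testing.assert_frame_equal(out, raw)

    def test_per_array_offsets_subtracted_columnwise(self):
        raw = pd.DataFrame({"a": [150.0, 250.0], "b": [300.0, 400.0]})
        out = nc.background_correct(raw, pd.Series({"a": 50.0, "b": 100.0}))
        assert out["a"].tolist() == [100.0, 200.0]
        assert out["b"].tolist() == [200.0, 300.0]

    def test_missing_control_summary_errors(self):
        raw = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="negative-control"):
            nc.background_correct(raw, pd.Series({"a": 0.0}))


class TestVst:
    def test_glog_asymptotically_log2(self):
        x = np.array([1e4, 1e6])
        np.testing.assert_allclose(nc.glog2(x, 1.0), np.log2(x), rtol=1e-6)

    def test_glog_closed_form_at_zero(self):
        assert nc.glog2(0.0, 8.0) == pytest.approx(np.log2(4.0))

    def test_glog_monotone_and_defined_for_negatives(self):
        x = np.linspace(-50, 50, 201)
        y = nc.glog2(x, 10.0)
        assert np.all(np.diff(y) > 0)
        assert np.isfinite(y).all()

    def test_flattens_mean_variance_dependence(self, rng):
        # multiplicative noise: sd grows with the mean on the raw scale
        mu = np.exp(rng.uniform(np.log(20), np.log(5000), 400))
        raw = mu[:, None] * np.exp(rng.normal(0, 0.25, size=(400, 20))) \
            + rng.normal(0, 10.0, size=(400, 20))
        df = pd.DataFrame(raw)
        slope_raw = stats.linregress(raw.mean(axis=1), raw.std(axis=1)).slope
        out = nc.vst(df).to_numpy()
        slope_vst = stats.linregress(out.mean(axis=1), out.std(axis=1)).slope
        assert abs(slope_vst) < abs(slope_raw) / 5.0

    def test_constant_array_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="degenerate"):
            nc.vst(df)


class TestDetectionFilter:
    def test_kept_iff_detected_somewhere(self, rng):
        study = make_study(rng.normal(size=(3, 4)),
                           ["wt", "wt", "mut", "mut"], ["L1", "L1", "L1", "L1"])
        study.detection.iloc[0] = [0.96, 0.10, 0.10, 0.10]   # kept: one sample
        study.detection.iloc[1] = [0.94, 0.94, 0.94, 0.94]   # removed: never
        study.detection.iloc[2] = [0.95, 0.95, 0.95, 0.95]   # kept: boundary
        out = nc.detection_filter(study)
        assert list(out.expr.index) == ["g0", "g2"]

    def test_idempotent(self, rng):
        study = make_study(rng.normal(size=(20, 4)),
                           ["wt", "wt", "mut", "mut"], ["L1"] * 4)
        study.detection.iloc[:5] = 0.5
        once = nc.detection_filter(study)
        twice = nc.detection_filter(once)
        pd.testing.assert_frame_equal(once.expr, twice.expr)


class TestQcOutliers:
    def test_homogeneous_cohort_unflagged(self, rng):
        signal = rng.normal(8, 1.5, 300)
        values = signal[:, None] + rng.normal(0, 0.3, size=(300, 8))
        study = make_study(values, ["wt"] * 4 + ["mut"] * 4, ["L1"] * 8)
        assert not nc.qc_outliers(study).any()

    def test_planted_outlier_flagged_exactly(self, rng):
        signal = rng.normal(8, 1.5, 300)
        values = signal[:, None] + rng.normal(0, 0.3, size=(300, 8))
        values[:, 5] = rng.normal(8, 1.5, 300)  # independent noise, no shared signal
        study = make_study(values, ["wt"] * 4 + ["mut"] * 4, ["L1"] * 8)
        flags = nc.qc_outliers(study)
        assert flags.sum() == 1 and flags.iloc[5]

    def test_too_many_flags_abort(self, rng):
        signal = rng.normal(8, 1.5, 200)
        values = signal[:, None] + rng.normal(0, 0.2, size=(200, 6))
        values[:, :2] = rng.normal(8, 1.5, size=(200, 2))  # 2 of 6 unrelated
        study = make_study(values, ["wt"] * 3 + ["mut"] * 3, ["L1"] * 6)
        with pytest.raises(ValueError, match="flagged"):
            nc.qc_outliers(study)


class TestFitDe:
    def test_reduces_to_two_sample_t_without_litter(self, rng):
        values = rng.normal(size=(50, 10))
        study = make_study(values, ["wt"] * 5 + ["mut"] * 5, ["L1"] * 10)
        res = nc.fit_de(study, moderate=False)
        t, p = stats.ttest_ind(values[:, 5:], values[:, :5], axis=1)
        np.testing.assert_allclose(res["t"].to_numpy(), t, rtol=1e-8)
        np.testing.assert_allclose(res["p"].to_numpy(), p, rtol=1e-8)

    def test_noiseless_planted_effect_recovered(self, rng):
        base = np.repeat(rng.normal(8, 1, (5, 1)), 8, axis=1)
        values = base.copy()
        values[0, 4:] += 1.0  # gene 0 up in mutants
        values += rng.normal(0, 1e-9, values.shape)
        study = make_study(values, ["wt"] * 4 + ["mut"] * 4,
                           ["L1", "L1", "L2", "L2"] * 2)
        res = nc.fit_de(study, moderate=False)
        assert res.iloc[0]["effect"] == pytest.approx(1.0, abs=1e-6)
        assert res.iloc[0]["p"] < 1e-12
        assert res.iloc[0]["direction"] == "up"

    def test_confounded_design_rejected(self, rng):
        values = rng.normal(size=(10, 6))
        study = make_study(values, ["wt", "wt", "wt", "mut", "mut", "mut"],
                           ["L1", "L1", "L1", "L2", "L2", "L2"])
        with pytest.raises(DesignMatrixError, match="confounded"):
            nc.fit_de(study)

    def test_directions_partition_significant_genes(self, rng):
        cfg = nc.SimConfig(n_genes=500, de_fraction=0.1, seed=41)
        study, _ = nc.gen_expression(cfg)
        res = nc.fit_de(study)
        sig = res[res["p"] < 0.01]
        assert set(sig["direction"]) <= {"up", "down"}
        assert ((sig["effect"] < 0) == (sig["direction"] == "down")).all()

    def test_effect_rmse_decreases_with_noise(self):
        rmses = []
        for noise in (1.0, 0.5, 0.1):
            cfg = nc.SimConfig(n_genes=800, de_fraction=0.1, effect_size_log2=1.5,
                               expr_noise_sd=noise, seed=42)
            study, truth = nc.gen_expression(cfg)
            res = nc.fit_de(study)
            est = res.loc[truth.de_genes["gene_id"], "effect"].to_numpy()
            rmses.append(float(np.sqrt(np.mean((est - truth.de_genes["effect"].to_numpy()) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]


class TestBhFdr:
    def test_single_p_is_its_own_q(self):
        assert nc.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_example_step_up(self):
        np.testing.assert_allclose(nc.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 51)))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(nc.bh_fdr(p), q_ref, atol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=100)
        q = nc.bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            nc.bh_fdr([0.5, 1.2])


class TestPermutation:
    def test_combinatorial_count_by_hand(self, rng):
        # litters (2WT/2M) and (1WT/1M): C(4,2) * C(2,1) = 12
        values = rng.normal(size=(30, 6))
        study = make_study(values, ["wt", "wt", "mut", "mut", "wt", "mut"],
                           ["L1", "L1", "L1", "L1", "L2", "L2"])
        assert count_litter_permutations(study.meta) == 12
        report = nc.litter_permutation_test(study, alpha=0.01)
        assert report.total == 12
        assert len(report.tallies) == 12

    def test_default_litter_composition_yields_108(self):
        cfg = nc.SimConfig(n_genes=10, seed=43)
        study, _ = nc.gen_expression(cfg)
        assert count_litter_permutations(study.meta) == 108

    def test_identity_assignment_always_qualifies(self, rng):
        values = rng.normal(size=(40, 6))
        study = make_study(values, ["wt", "wt", "mut", "mut", "wt", "mut"],
                           ["L1", "L1", "L1", "L1", "L2", "L2"])
        report = nc.litter_permutation_test(study, alpha=0.05)
        assert report.count_ge_observed >= 1
        assert report.empirical_p >= 1.0 / report.total

    def test_planted_signal_is_permutation_extreme(self):
        cfg = nc.SimConfig(n_genes=1500, de_fraction=0.05, effect_size_log2=1.5,
                           expr_noise_sd=0.4, seed=44)
        study, _ = nc.gen_expression(cfg)
        report = nc.litter_permutation_test(study, alpha=0.01)
        assert report.empirical_p <= 5.0 / report.total

    def test_sampling_fallback_records_seed(self, rng):
        values = rng.normal(size=(20, 6))
        study = make_study(values, ["wt", "wt", "mut", "mut", "wt", "mut"],
                           ["L1", "L1", "L1", "L1", "L2", "L2"])
        report = nc.litter_permutation_test(study, alpha=0.05, max_enumerate=5,
                                            n_sample=20, seed=99)
        assert report.sampled and report.seed == 99
        assert report.total == 20
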