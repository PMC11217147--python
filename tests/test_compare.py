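"""Comparative statistics: knockdown response, DMRs, bias curve, evenness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ubscall as u
from ubscall.compare import background_fold_change


def _sites(rows):
    recs = [
        (ref, pos, "+", "C", k, cov - k, cov, k / cov)
        for ref, pos, k, cov in rows
    ]
    return pd.DataFrame(
        recs,
        columns=["ref", "pos", "strand", "context", "n_unconverted",
                 "n_converted", "coverage", "ratio"],
    )


class TestKnockdownResponse:
    @pytest.mark.parametrize(
        "f_ctrl,f_kd,expected",
        [
            (0.30, 0.05, "decreased"),   # 0.05 <= 0.10
            (0.10, 0.35, "increased"),   # 0.35 >= 0.30
            (0.20, 0.15, "unchanged"),
            (0.30, 0.10, "decreased"),   # boundary: exactly one third
            (0.10, 0.30, "increased"),   # boundary: exactly threefold
        ],
    )
    def test_classification_rules(self, f_ctrl, f_kd, expected):
        ctrl = _sites([("t", 5, int(f_ctrl * 100), 100)])
        kd = _sites([("t", 5, int(f_kd * 100), 100)])
        out = u.knockdown_response(ctrl, kd, min_cov=20)
        assert out["response"].iloc[0] == expected

    def test_both_zero_is_unchanged_and_no_overlap_errors(self):
        ctrl = _sites([("t", 5, 0, 100)])
        kd = _sites([("t", 5, 0, 100)])
        assert u.knockdown_response(ctrl, kd)["response"].iloc[0] == "unchanged"
        with pytest.raises(ValueError):
            u.knockdown_response(ctrl, _sites([("t", 9, 1, 100)]))

    @given(c=st.floats(0.05, 3.0), f=st.floats(0.01, 0.3), g=st.floats(0.01, 0.3))
    @settings(max_examples=60, deadline=None)
    def test_scale_consistency(self, c, f, g):
        """Multiplying both fractions by c > 0 leaves the class unchanged."""
        def classify(a, b):
            if a == 0 and b == 0:
                return "unchanged"
            if b <= a / 3:
                return "decreased"
            if b >= 3 * a:
                return "increased"
            return "unchanged"

        assert classify(f, g) == classify(c * f, c * g)


class TestDMR:
    def test_identical_groups_yield_no_dmrs(self):
        samples, _ = u.simulate_cfdna_cohort(seed=1, n_case=2, n_control=2,
                                             n_windows=5)
        df = samples["ctrl1"]
        res = u.DifferentialMethylationModel([df, df], [df, df]).fit()
        assert len(res.dmrs) == 0

    def test_planted_window_recovered_exactly(self):
        samples, _ = u.simulate_cfdna_cohort(
            seed=2, n_case=6, n_control=6, n_windows=25,
            planted_dmrs=[(7000, 0.30)],
        )
        case = {k: v for k, v in samples.items() if k.startswith("case")}
        ctrl = {k: v for k, v in samples.items() if k.startswith("ctrl")}
        res = u.DifferentialMethylationModel(case, ctrl).fit()
        dmrs = res.dmrs
        assert len(dmrs) == 1
        assert (dmrs["start"].iloc[0], dmrs["end"].iloc[0]) == (7000, 8000)
        assert dmrs["diff"].iloc[0] == pytest.approx(0.30, abs=0.08)
        assert "DMRs reported" in res.summary()

    def test_low_cpg_windows_never_reported(self):
        """Windows with <=20 CpG are excluded regardless of the difference."""
        rng = np.random.default_rng(3)
        def grp(p):
            return [
                _sites([("w", i * 50, int(rng.binomial(100, p)), 100)
                        for i in range(15)])  # 15 CpG in one window
                for _ in range(3)
            ]
        case, ctrl = grp(0.9), grp(0.1)
        for df in case + ctrl:
            df["context"] = "CpG"
        res = u.DifferentialMethylationModel(case, ctrl).fit()
        assert len(res.windows) == 0 and len(res.dmrs) == 0

    def test_group_size_validation(self):
        samples, _ = u.simulate_cfdna_cohort(seed=4, n_case=2, n_control=2,
                                             n_windows=3)
        with pytest.raises(ValueError):
            u.DifferentialMethylationModel([samples["case1"]],
                                           [samples["ctrl1"], samples["ctrl2"]])

    def test_zscore_matrix_is_row_standardized(self):
        samples, _ = u.simulate_cfdna_cohort(seed=5, n_case=3, n_control=3,
                                             n_windows=8)
        case = {k: v for k, v in samples.items() if k.startswith("case")}
        ctrl = {k: v for k, v in samples.items() if k.startswith("ctrl")}
        res = u.DifferentialMethylationModel(case, ctrl).fit()
        z = res.zscore_matrix.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)


class TestDegradationBias:
    def test_endpoints_and_identity(self):
        assert u.degradation_bias_curve(0.0, 0.5) == 0.0
        assert u.degradation_bias_curve(1.0, 0.5) == 1.0
        x = np.linspace(0, 1, 11)
        assert np.allclose(u.degradation_bias_curve(x, 1.0), x)

    def test_closed_form_value(self):
        assert u.degradation_bias_curve(0.5, 0.5) == pytest.approx(2 / 3)

    def test_strictly_increasing_in_x_decreasing_in_s(self):
        x = np.linspace(0.05, 0.95, 19)
        y = u.degradation_bias_curve(x, 0.6)
        assert np.all(np.diff(y) > 0)
        s = np.linspace(0.1, 1.0, 10)
        y = u.degradation_bias_curve(0.4, s)
        assert np.all(np.diff(y) < 0)
        assert np.all(u.degradation_bias_curve(x, 0.6) > x)  # over-estimation

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            u.degradation_bias_curve(1.2, 0.5)
        with pytest.raises(ValueError):
            u.degradation_bias_curve(0.5, 0.0)


class TestCoverageEvenness:
    def test_constant_depth_gives_zero_iqr(self):
        out = u.coverage_evenness([10.0] * 50)
        assert out["iqr_z"] == 0.0 and out["n_outliers"] == 0

    def test_standard_normal_iqr(self):
        rng = np.random.default_rng(6)
        out = u.coverage_evenness(rng.normal(100, 10, size=20000))
        assert out["iqr_z"] == pytest.approx(1.349, abs=0.05)

    def test_scale_invariance_of_z(self):
        rng = np.random.default_rng(7)
        d = rng.gamma(5, 10, size=500)
        a, b = u.coverage_evenness(d), u.coverage_evenness(2 * d)
        assert a["iqr_z"] == pytest.approx(b["iqr_z"], rel=1e-12)
        assert a["n_outliers"] == b["n_outliers"]
        assert b["iqr_raw"] == pytest.approx(2 * a["iqr_raw"], rel=1e-12)


class TestSpikeInFP:
    def test_all_converted_spike_gives_zero(self):
        df = _sites([("spike", i, 0, 100) for i in range(20)])
        out = u.spike_in_fp_rate(df, ratio_cutoff=0.05)
        assert out["fp_rate"] == 0.0 and out["pooled_rate"] == 0.0

    def test_cutoff_zero_counts_any_unconverted(self):
        df = _sites([("s", 0, 0, 10), ("s", 1, 1, 10), ("s", 2, 3, 10)])
        out = u.spike_in_fp_rate(df, ratio_cutoff=1e-9)
        assert out["fp_rate"] == pytest.approx(2 / 3)

    def test_null_simulation_matches_binomial_tail(self):
        rng = np.random.default_rng(8)
        p0, cov, cutoff = 0.01, 100, 0.05
        k = rng.binomial(cov, p0, size=5000)
        df = _sites([("s", i, int(ki), cov) for i, ki in enumerate(k)])
        out = u.spike_in_fp_rate(df, ratio_cutoff=cutoff)
        expected = u.binomial_pvalue(5, cov, p0)  # Pr(X >= 5) = Pr(ratio >= 0.05)
        se = np.sqrt(expected * (1 - expected) / 5000)
        assert out["fp_rate"] == pytest.approx(expected, abs=4 * se)

    def test_fold_change_between_libraries(self):
        a = _sites([("s", i, 2, 100) for i in range(10)])
        b = _sites([("s", i, 1, 100) for i in range(10)])
        assert background_fold_change(a, b) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            u.spike_in_fp_rate(_sites([("s", 0, 0, 3)]), min_cov=10)


class TestDistributionSummary:
    def _annotation(self):
        return pd.DataFrame(
            [
                ("t1", 0, 100, "g1", "5UTR"),
                ("t1", 100, 700, "g1", "CDS"),
                ("t1", 700, 1000, "g1", "3UTR"),
            ],
            columns=["ref", "start", "end", "gene", "region"],
        )

    def test_empty_table_all_zero(self):
        out = u.distribution_summary(_sites([]).iloc[0:0], annotation=self._annotation())
        assert out["n_sites"] == 0
        assert all(v == 0 for v in out["threshold_counts"].values())
        assert out["metaprofile"].sum() == 0

    def test_threshold_counts_monotone(self):
        rng = np.random.default_rng(9)
        k = rng.integers(0, 101, size=200)
        df = _sites([("t1", i, int(ki), 100) for i, ki in enumerate(k)])
        out = u.distribution_summary(df)
        counts = [out["threshold_counts"][t] for t in (0.05, 0.20, 0.33)]
        assert counts == sorted(counts, reverse=True)

    def test_region_assignment_and_metaprofile(self):
        df = _sites([("t1", 50, 30, 100), ("t1", 400, 30, 100),
                     ("t1", 800, 30, 100), ("t2", 10, 30, 100)])
        out = u.distribution_summary(df, annotation=self._annotation())
        assert out["region_counts"] == {"5UTR": 1, "CDS": 1, "3UTR": 1,
                                        "unannotated": 1}
        assert out["sites_per_gene"] == {"g1": 3}
        prof = out["metaprofile"]
        assert len(prof) == 300
        assert prof.sum() == pytest.approx(1.0)
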