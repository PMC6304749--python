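import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devsnn.analysis import (
    DEFAULT_STAGE_REFERENCES,
    anova_factorial,
    band_label,
    classify_modulation,
    gaussian_pdf_filter,
    mean_spike_frequency,
    modulation_table,
    percent_change,
    spike_distance_matrix,
    stage_map,
    van_rossum_distance,
)
from devsnn.records import SpikeRecord
from devsnn.synthetic_data import EffectSpec, SyntheticSpec, gen_msf_table, gen_spike_record


class TestMeanSpikeFrequency:
    def test_empty_record(self):
        rec = SpikeRecord(times=np.empty(0), ids=np.empty(0, dtype=np.int64),
                          n_neurons=10, duration=100.0)
        assert mean_spike_frequency(rec, 50.0) == 0.0

    def test_regular_train(self):
        # one neuron, a spike every 0.1 s over (50, 2000]: 10 Hz
        times = 50.1 + 0.1 * np.arange(19500)
        rec = SpikeRecord(times=times, ids=np.zeros(times.size, dtype=np.int64),
                          n_neurons=1, duration=2000.2)
        assert mean_spike_frequency(rec, 50.0) == pytest.approx(10.0, rel=1e-3)

    def test_poisson_ground_truth(self):
        rec = gen_spike_record(SyntheticSpec(n_neurons=100, T=100.0,
                                             rate_profile=10.0, seed=4))
        msf = mean_spike_frequency(rec, 0.0)
        se = math.sqrt(10.0 / (100 * 100.0))
        assert abs(msf - 10.0) < 3 * se

    def test_invalid_burn_in(self):
        rec = SpikeRecord(times=np.empty(0), ids=np.empty(0, dtype=np.int64),
                          n_neurons=10, duration=10.0)
        with pytest.raises(ValueError):
            mean_spike_frequency(rec, 10.0)


class TestPercentChange:
    @pytest.mark.parametrize("before,after,expected,direction", [
        (25.8, 6.0, 76.7, "reduction"),
        (65.0, 78.2, 20.3, "increase"),
        (133.8, 15.2, 88.6, "reduction"),
    ])
    def test_worked_examples(self, before, after, expected, direction):
        change = percent_change(before, after)
        assert change.rounded(1) == expected
        assert change.direction == direction

    def test_no_change(self):
        change = percent_change(40.0, 40.0)
        assert change.percent == 0.0
        assert change.direction == "none"

    def test_deadband(self):
        assert percent_change(100.0, 99.5).direction == "none"
        assert percent_change(100.0, 98.5).direction == "reduction"

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)

    @settings(max_examples=100, deadline=None)
    @given(before=st.floats(1.0, 1e3), p=st.floats(-99.0, 99.0))
    def test_round_trip_identity(self, before, p):
        after = before * (1.0 - p / 100.0)
        assert percent_change(before, after).percent == pytest.approx(p, abs=1e-9)


class TestClassifyModulation:
    @pytest.mark.parametrize("stp,direction,expected", [
        ("STD1", "reduction", "predicted"),
        ("STD1", "increase", "unpredicted"),
        ("STD2", "reduction", "predicted"),
        ("STD2", "increase", "unpredicted"),
        ("STF1", "increase", "predicted"),
        ("STF1", "reduction", "unpredicted"),
        ("STF2", "increase", "predicted"),
        ("STF2", "reduction", "unpredicted"),
    ])
    def test_truth_table(self, stp, direction, expected):
        assert classify_modulation(stp, direction) == expected

    def test_none_direction(self):
        assert classify_modulation("STF2", "none") == "none"

    def test_control_rejected(self):
        with pytest.raises(ValueError):
            classify_modulation("control", "reduction")

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            classify_modulation("STD9", "reduction")
        with pytest.raises(ValueError):
            classify_modulation("STD1", "sideways")


class TestBandLabel:
    @pytest.mark.parametrize("if_hz,band", [
        (5, "theta"), (10, "alpha"), (15, "beta"), (30, "beta"),
        (35, "low-gamma"), (50, "low-gamma"), (55, "high-gamma"),
        (80, "high-gamma"), (85, "epsilon"), (100, "epsilon"), (250, "epsilon"),
    ])
    def test_grid(self, if_hz, band):
        assert band_label(if_hz) == band

    @pytest.mark.parametrize("bad", [0.0, -5.0, 251.0, 2.0])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            band_label(bad)


class TestGaussianPdfFilter:
    def test_normal_sample_kept(self):
        rng = np.random.default_rng(5)
        y = 50.0 + 5.0 * rng.standard_normal(12)
        assert gaussian_pdf_filter(y).keep

    def test_bimodal_sample_excluded(self):
        rng = np.random.default_rng(5)
        comp = rng.integers(0, 2, 12)
        y = np.where(comp, 20.0, 80.0) + rng.standard_normal(12) * 5.0  # 6 SD apart
        assert not gaussian_pdf_filter(y).keep

    def test_constant_sample_excluded_with_diagnostic(self):
        res = gaussian_pdf_filter(np.full(12, 7.0))
        assert not res.keep
        assert "degenerate" in res.reason

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            gaussian_pdf_filter([1.0, 2.0])


class TestVanRossum:
    def test_identical_trains_zero(self):
        a = np.array([0.1, 0.5, 0.9])
        assert van_rossum_distance(a, a, 0.02) == pytest.approx(0.0, abs=1e-9)

    def test_two_spike_closed_form(self):
        # single spikes offset by d: D = sqrt(1 - exp(-d/tau))
        tau, d = 0.02, 0.013
        got = van_rossum_distance([0.5], [0.5 + d], tau)
        assert got == pytest.approx(math.sqrt(1 - math.exp(-d / tau)), abs=1e-12)

    def test_quadrature_oracle(self):
        # numerical integral of the squared kernel difference
        tau = 0.02
        a = np.array([0.10, 0.35])
        b = np.array([0.12, 0.60])
        t = np.linspace(0.0, 1.5, 3_000_001)

        def filtered(train):
            f = np.zeros_like(t)
            for s in train:
                m = t >= s
                f[m] += np.exp(-(t[m] - s) / tau)
            return f

        d2 = np.trapezoid((filtered(a) - filtered(b)) ** 2, t) / tau
        assert van_rossum_distance(a, b, tau) == pytest.approx(math.sqrt(d2), abs=1e-4)

    def test_brute_force_pair_sums(self, rng):
        # independent O(n^2) evaluation of the kernel-sum formula
        tau = 0.05
        a = np.sort(rng.uniform(0, 2, 40))
        b = np.sort(rng.uniform(0, 2, 55))

        def cross(x, y):
            return np.sum(np.exp(-np.abs(x[:, None] - y[None, :]) / tau))

        d2 = 0.5 * (cross(a, a) + cross(b, b) - 2 * cross(a, b))
        assert van_rossum_distance(a, b, tau) == pytest.approx(
            math.sqrt(max(d2, 0)), abs=1e-9
        )

    def test_matrix_symmetry_and_diagonal(self):
        rec = gen_spike_record(SyntheticSpec(n_neurons=12, T=5.0,
                                             rate_profile=8.0, seed=9))
        mat, ids = spike_distance_matrix(rec, subsample=8, kernel_tau=20.0)
        assert mat.shape == (8, 8)
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0.0)
        assert np.all(mat[~np.eye(8, dtype=bool)] > 0)

    def test_matrix_needs_two_neurons(self):
        rec = SpikeRecord(times=np.empty(0), ids=np.empty(0, dtype=np.int64),
                          n_neurons=1, duration=1.0)
        with pytest.raises(ValueError):
            spike_distance_matrix(rec)


class TestStageMap:
    def test_pre_shift_window(self):
        # 7.86 +/- 2*1.30 -> [5.26, 10.46]
        assert stage_map(6.0) == "pre-shift 5-10 DIV"

    def test_shift_window_center(self):
        assert stage_map(54.27) == "shift 11-17 DIV"

    def test_outside(self):
        assert stage_map(133.8) == "outside"
        assert stage_map(0.0) == "outside"

    def test_tie_goes_to_nearer_mean(self):
        from devsnn.analysis import StageReference
        refs = (StageReference("a", 10.0, 5.0), StageReference("b", 20.0, 5.0))
        assert stage_map(14.0, refs) == "a"
        assert stage_map(16.0, refs) == "b"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stage_map(-1.0)

    def test_reference_values(self):
        assert DEFAULT_STAGE_REFERENCES[0].mean == 7.86
        assert DEFAULT_STAGE_REFERENCES[0].sd == 1.30
        assert DEFAULT_STAGE_REFERENCES[1].mean == 54.27
        assert DEFAULT_STAGE_REFERENCES[1].sd == 7.22


def one_way_anova_oracle(groups):
    """Textbook sums of squares for a one-way layout."""
    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = all_y.size - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return ss_between, ss_within, F


class TestAnova:
    def test_one_way_matches_textbook_oracle(self):
        groups = [
            [12.0, 14.0, 11.0, 13.0],
            [18.0, 17.0, 19.0, 21.0],
            [15.0, 15.5, 16.0, 14.5],
        ]
        rows = [
            {"g": name, "msf_hz": y}
            for name, ys in zip("abc", groups)
            for y in ys
        ]
        res = anova_factorial(pd.DataFrame(rows), ["g"])
        ss_b, ss_w, F = one_way_anova_oracle(groups)
        assert res.table.loc["g", "sum_sq"] == pytest.approx(ss_b, rel=1e-12)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(ss_w, rel=1e-12)
        assert res.table.loc["g", "F"] == pytest.approx(F, rel=1e-12)

    def test_matches_statsmodels_two_way(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(17)
        rows = []
        for a in "xyz":
            for b in "pq":
                for _ in range(4):
                    rows.append({"A": a, "B": b,
                                 "msf_hz": rng.normal(10 + (a == "x") * 3, 2.0)})
        df = pd.DataFrame(rows)
        mine = anova_factorial(df, ["A", "B"])
        model = ols("msf_hz ~ C(A) * C(B)", data=df).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        assert mine.table.loc["A", "sum_sq"] == pytest.approx(
            ref.loc["C(A)", "sum_sq"], rel=1e-9
        )
        assert mine.table.loc["A:B", "sum_sq"] == pytest.approx(
            ref.loc["C(A):C(B)", "sum_sq"], rel=1e-9
        )
        assert mine.p("A") == pytest.approx(ref.loc["C(A)", "PR(>F)"], rel=1e-9)

    def test_three_way_power(self):
        spec = EffectSpec(maturation_offsets={"mature": -30.0}, noise_sd=5.0, seed=2)
        res = anova_factorial(gen_msf_table(spec),
                              ["scenario", "maturation", "stp_class"])
        assert res.p("maturation") < 1e-6

    def test_sum_of_squares_conservation(self):
        table = gen_msf_table(EffectSpec(seed=8, noise_sd=4.0))
        res = anova_factorial(table, ["scenario", "maturation", "stp_class"])
        total = np.sum(
            (table["msf_hz"] - table["msf_hz"].mean()) ** 2
        )
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-10)
        assert res.table["df"].sum() == len(table) - 1

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"A": ["x"] * 6, "B": list("pq") * 3,
                           "msf_hz": np.arange(6.0)})
        with pytest.raises(ValueError):
            anova_factorial(df, ["A", "B"])

    def test_unbalanced_rejected(self):
        df = pd.DataFrame({"A": ["x", "x", "x", "y", "y"],
                           "msf_hz": [1.0, 2.0, 3.0, 4.0, 5.0]})
        with pytest.raises(ValueError):
            anova_factorial(df, ["A"])


class TestModulationTable:
    def test_end_to_end_worked_example(self):
        # zero-noise injected truth: control 25.8 Hz, STF2 cell 6.0 Hz
        spec = EffectSpec(
            grand_mean=25.8,
            stp_offsets={"STF2": -19.8},
            noise_sd=0.0,
            if_hz=5.0,
            seed=0,
        )
        table = gen_msf_table(spec)
        mod = modulation_table(table)
        row = mod[(mod["scenario"] == "B-2") & (mod["stp_class"] == "STF2")].iloc[0]
        assert row["percent_change"] == 76.7
        assert row["direction"] == "reduction"
        assert row["label"] == "unpredicted"  # STF that reduces is unpredicted
        assert row["band"] == "theta"
        # zero-variance cells fail the PDF filter by design
        assert not row["included"]

    def test_noisy_table_classification(self):
        spec = EffectSpec(
            grand_mean=50.0,
            stp_offsets={"STD1": -20.0, "STF1": 15.0},
            noise_sd=1.0,
            if_hz=20.0,
            seed=3,
        )
        mod = modulation_table(gen_msf_table(spec))
        std1 = mod[mod["stp_class"] == "STD1"]
        stf1 = mod[mod["stp_class"] == "STF1"]
        assert (std1["label"] == "predicted").all()
        assert (stf1["label"] == "predicted").all()
        assert std1["included"].all()
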