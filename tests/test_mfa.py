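import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from replidose.genome import Replicon
from replidose.mfa import (
    MFAProfile,
    WindowCounts,
    aggregate_windows,
    center_on_origin,
    detect_gaps,
    detect_slope_breaks,
    exclude_windows,
    fit_replication,
    normalize_mfa,
    rebin,
)
from replidose.simulate import GrowthParams, sim_copy_number

from .conftest import make_counts


def profile_from_dosage(dosage):
    """Noiseless MFAProfile directly from an expected-dosage table."""
    df = dosage.df.rename(columns={"dosage": "frequency"}).copy()
    df["ori_distance"] = np.nan
    df["included"] = df["frequency"] > 0
    df["reason"] = np.where(df["frequency"] > 0, "", "deletion")
    return MFAProfile(df, dosage.window_bp)


class TestAggregateWindows:
    def test_window_boundary_is_half_open(self, two_window_replicon):
        wc = aggregate_windows(
            {"r": np.array([0, 999, 1_000])}, [two_window_replicon], 1_000
        )
        assert list(wc.df["count"]) == [2, 1]

    def test_empty_input_gives_zero_windows(self, two_window_replicon):
        wc = aggregate_windows({}, [two_window_replicon], 1_000)
        assert list(wc.df["count"]) == [0, 0]

    def test_position_beyond_replicon_rejected(self, two_window_replicon):
        with pytest.raises(ValueError, match="outside"):
            aggregate_windows({"r": np.array([2_000])}, [two_window_replicon], 1_000)

    def test_coarse_aggregation_equals_sum_of_fine_windows(self):
        rep = Replicon("c", 100_000, True, ori_bp=0)
        rng = np.random.default_rng(42)
        starts = rng.integers(0, 100_000, size=50_000)
        fine = aggregate_windows({"c": starts}, [rep], 1_000)
        coarse = aggregate_windows({"c": starts}, [rep], 10_000)
        resummed = rebin(fine, 10_000)
        assert resummed.df.equals(coarse.df)


class TestNormalize:
    def test_uniform_counts_give_unit_frequency(self, two_window_replicon):
        prof = normalize_mfa(
            make_counts(two_window_replicon, [100, 100]),
            make_counts(two_window_replicon, [50, 50], phase="stationary"),
        )
        assert np.allclose(prof.df["frequency"], [1.0, 1.0], atol=1e-12)

    def test_uniform_stationary_passes_exponential_shape_through(
        self, two_window_replicon
    ):
        prof = normalize_mfa(
            make_counts(two_window_replicon, [200, 100]),
            make_counts(two_window_replicon, [100, 100], phase="stationary"),
        )
        assert np.allclose(prof.df["frequency"], [4 / 3, 2 / 3], atol=1e-12)

    def test_stationary_bias_fully_cancelled(self, two_window_replicon):
        prof = normalize_mfa(
            make_counts(two_window_replicon, [200, 100]),
            make_counts(two_window_replicon, [200, 100], phase="stationary"),
        )
        assert np.allclose(prof.df["frequency"], [1.0, 1.0], atol=1e-12)

    def test_zero_stationary_window_excluded(self, two_window_replicon):
        prof = normalize_mfa(
            make_counts(two_window_replicon, [100, 100]),
            make_counts(two_window_replicon, [100, 0], phase="stationary"),
        )
        assert list(prof.df["included"]) == [True, False]
        assert prof.df["reason"].iloc[1] == "zero-stationary"

    def test_mismatched_grids_rejected(self, two_window_replicon):
        other = Replicon("r", 3_000, True, ori_bp=0)
        with pytest.raises(ValueError, match="grid"):
            normalize_mfa(
                make_counts(two_window_replicon, [1, 1]),
                make_counts(other, [1, 1, 1], phase="stationary"),
            )

    def test_all_zero_stationary_rejected(self, two_window_replicon):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_mfa(
                make_counts(two_window_replicon, [1, 1]),
                make_counts(two_window_replicon, [0, 0], phase="stationary"),
            )

    @given(
        scale=st.floats(min_value=0.1, max_value=100.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_scale_invariance(self, scale, seed):
        """Multiplying all exponential counts by a constant leaves the
        normalized profile unchanged."""
        rep = Replicon("r", 20_000, True, ori_bp=0)
        rng = np.random.default_rng(seed)
        e = rng.integers(50, 500, size=20)
        s = rng.integers(50, 500, size=20)
        base = normalize_mfa(
            make_counts(rep, e), make_counts(rep, s, phase="stationary")
        )
        scaled = normalize_mfa(
            make_counts(rep, e * scale), make_counts(rep, s, phase="stationary")
        )
        assert np.allclose(
            base.df["frequency"], scaled.df["frequency"], rtol=1e-12
        )

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_shared_window_bias_cancels(self, seed):
        """A per-window bias applied to both phases does not change the
        normalized profile."""
        rep = Replicon("r", 20_000, True, ori_bp=0)
        rng = np.random.default_rng(seed)
        e = rng.integers(100, 1_000, size=20).astype(float)
        s = rng.integers(100, 1_000, size=20).astype(float)
        bias = rng.uniform(0.25, 4.0, size=20)
        base = normalize_mfa(
            make_counts(rep, e), make_counts(rep, s, phase="stationary")
        )
        biased = normalize_mfa(
            make_counts(rep, e * bias), make_counts(rep, s * bias, phase="stationary")
        )
        assert np.allclose(base.df["frequency"], biased.df["frequency"], rtol=1e-9)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_renormalization_is_idempotent(self, seed):
        """Normalizing an already-normalized profile against a flat
        stationary reference returns it unchanged."""
        rep = Replicon("r", 20_000, True, ori_bp=0)
        rng = np.random.default_rng(seed)
        e = rng.integers(100, 1_000, size=20)
        prof = normalize_mfa(
            make_counts(rep, e), make_counts(rep, np.full(20, 100), phase="stationary")
        )
        again = normalize_mfa(
            make_counts(rep, prof.df["frequency"].to_numpy() * 1_000_000),
            make_counts(rep, np.full(20, 100), phase="stationary"),
        )
        assert np.allclose(
            prof.df["frequency"], again.df["frequency"], atol=1e-12
        )


class TestExcludeWindows:
    def test_fourfold_stationary_window_excluded(self):
        rep = Replicon("r", 10_000, True, ori_bp=0)
        s = np.full(10, 100)
        s[4] = 400
        prof = normalize_mfa(
            make_counts(rep, np.full(10, 100)), make_counts(rep, s, phase="stationary")
        )
        out = exclude_windows(prof, make_counts(rep, s, phase="stationary"), 1.0)
        assert not out.df["included"].iloc[4]
        assert out.df["reason"].iloc[4] == "repeat-like"

    def test_window_at_the_mean_kept(self):
        rep = Replicon("r", 10_000, True, ori_bp=0)
        s = np.full(10, 100)
        prof = normalize_mfa(
            make_counts(rep, np.full(10, 100)), make_counts(rep, s, phase="stationary")
        )
        out = exclude_windows(prof, make_counts(rep, s, phase="stationary"), 1.0)
        assert out.df["included"].all()

    def test_renormalization_restores_unit_mean(self):
        rep = Replicon("r", 10_000, True, ori_bp=0)
        rng = np.random.default_rng(0)
        s = rng.integers(80, 120, size=10)
        s[2] = 1_000
        prof = normalize_mfa(
            make_counts(rep, rng.integers(80, 120, size=10)),
            make_counts(rep, s, phase="stationary"),
        )
        out = exclude_windows(prof, make_counts(rep, s, phase="stationary"), 1.0)
        assert out.check_mean_one(1e-9)


class TestCenterOnOrigin:
    def test_window_at_ori_has_zero_distance(self):
        rep = Replicon("r", 10_000, True, ori_bp=2_500)
        prof = normalize_mfa(
            make_counts(rep, np.full(10, 10)),
            make_counts(rep, np.full(10, 10), phase="stationary"),
        )
        out = center_on_origin(prof, [rep])
        assert out.df["ori_distance"].iloc[2] == 0

    def test_distance_wraps_modulo_length(self):
        # window midpoints at 500, 1500; ori at 8000 on a 10 kb circle
        rep = Replicon("r", 10_000, True, ori_bp=8_000)
        prof = normalize_mfa(
            make_counts(rep, np.full(10, 10)),
            make_counts(rep, np.full(10, 10), phase="stationary"),
        )
        out = center_on_origin(prof, [rep])
        assert out.df["ori_distance"].iloc[0] == 2_500
        assert out.df["ori_distance"].iloc[3] == -4_500

    def test_missing_origin_rejected(self):
        rep = Replicon("r", 10_000, True)
        prof = normalize_mfa(
            make_counts(rep, np.full(10, 10)),
            make_counts(rep, np.full(10, 10), phase="stationary"),
        )
        with pytest.raises(ValueError, match="origin"):
            center_on_origin(prof, [rep])


class TestFitReplication:
    def test_noiseless_profile_recovers_origin_and_ratio(self):
        rep = Replicon("c", 200_000, True, ori_bp=60_000)
        dos = sim_copy_number([rep], GrowthParams(c_over_tau=1.0), 1_000)
        fit = fit_replication(profile_from_dosage(dos), [rep])
        f = fit.replicons["c"]
        assert abs(f.ori_hat_bp - 60_000) <= 500
        assert f.ori_ter_ratio == pytest.approx(2.0, abs=0.01)
        assert not f.no_gradient

    def test_flat_profile_sets_no_gradient_flag(self):
        rep = Replicon("c", 50_000, True, ori_bp=0)
        dos = sim_copy_number([rep], GrowthParams(c_over_tau=0.0), 1_000)
        fit = fit_replication(profile_from_dosage(dos), [rep])
        f = fit.replicons["c"]
        assert f.no_gradient and f.ori_ter_ratio == 1.0

    def test_initiation_delay_matches_co_termination_truth(
        self, small_two_chromosome
    ):
        dos = sim_copy_number(small_two_chromosome, GrowthParams(c_over_tau=1.0), 1_000)
        fit = fit_replication(
            profile_from_dosage(dos), small_two_chromosome, doubling_time=30.0
        )
        truth = 1.0 - 6_000 / 10_000
        assert fit.primary == "A" and fit.secondary == "B"
        assert fit.initiation_delay_log2 == pytest.approx(truth, rel=0.05)
        assert fit.initiation_delay_min == pytest.approx(truth * 30.0, rel=0.05)

    def test_too_few_windows_rejected(self):
        rep = Replicon("r", 8_000, True, ori_bp=0)
        prof = normalize_mfa(
            make_counts(rep, np.full(8, 10)),
            make_counts(rep, np.full(8, 10), phase="stationary"),
        )
        with pytest.raises(ValueError, match="usable windows"):
            fit_replication(prof, [rep])


class TestDetectGaps:
    def test_long_zero_run_reported_with_bounds(self):
        rep = Replicon("r", 500_000, True, ori_bp=0)
        e = np.full(500, 50)
        s = np.full(500, 50)
        e[100:225] = 0
        s[100:225] = 0
        calls = detect_gaps(
            make_counts(rep, e), make_counts(rep, s, phase="stationary"), min_run=5
        )
        assert len(calls) == 1
        c = calls[0]
        assert (c.start_bp, c.end_bp, c.n_windows) == (100_000, 225_000, 125)
        assert c.end_bp - c.start_bp == 125_000
        assert c.phases_affected == "both"

    def test_no_zero_windows_yields_no_calls(self):
        rep = Replicon("r", 20_000, True, ori_bp=0)
        assert (
            detect_gaps(make_counts(rep, np.full(20, 5)), min_run=5) == []
        )

    def test_short_runs_below_min_run_ignored(self):
        rep = Replicon("r", 20_000, True, ori_bp=0)
        e = np.full(20, 5)
        e[7] = 0
        assert detect_gaps(make_counts(rep, e), min_run=5) == []

    def test_exponential_only_gap_labelled_as_phase_artifact(self):
        rep = Replicon("r", 20_000, True, ori_bp=0)
        e = np.full(20, 5)
        e[3:9] = 0
        calls = detect_gaps(
            make_counts(rep, e),
            make_counts(rep, np.full(20, 5), phase="stationary"),
            min_run=5,
        )
        assert calls[0].phases_affected == "exponential"


class TestSlopeBreaks:
    def _noiseless_fit(self, rep, dos):
        prof = profile_from_dosage(dos)
        return prof, fit_replication(prof, [rep])

    def test_self_consistent_profile_has_no_breaks(self):
        # ori on a window midpoint so the fitted V reproduces the
        # profile exactly (the fit's apex grid is the midpoints)
        rep = Replicon("c", 400_000, True, ori_bp=100_500)
        dos = sim_copy_number([rep], GrowthParams(c_over_tau=1.0), 1_000)
        prof, fit = self._noiseless_fit(rep, dos)
        assert (
            detect_slope_breaks(prof, fit, [rep], window_span=30, severity_threshold=5.0)
            == []
        )

    def test_mirrored_segment_is_detected(self):
        """Mirroring the dosage of a large interior segment (an inversion
        relative to the reference) must produce at least one slope break
        inside it."""
        rep = Replicon("c", 2_000_000, True, ori_bp=500_000)
        dos = sim_copy_number([rep], GrowthParams(c_over_tau=1.0), 1_000)
        df = dos.df.copy()
        seg = (df.start >= 1_200_000) & (df.start < 1_700_000)  # 500 kb, one arm
        df.loc[seg, "dosage"] = df.loc[seg, "dosage"].to_numpy()[::-1]
        dos = type(dos)(df, dos.window_bp, dos.replicons)
        prof = profile_from_dosage(dos)
        fit = fit_replication(prof, [rep])
        breaks = detect_slope_breaks(
            prof, fit, [rep], window_span=50, severity_threshold=5.0
        )
        assert any(1_200_000 <= b.position_bp < 1_700_000 for b in breaks)

    def test_flat_profile_yields_no_breaks(self):
        rep = Replicon("c", 400_000, True, ori_bp=0)
        dos = sim_copy_number([rep], GrowthParams(c_over_tau=0.0), 1_000)
        prof, fit = self._noiseless_fit(rep, dos)
        assert detect_slope_breaks(prof, fit, [rep], window_span=30) == []

    def test_span_wider_than_arm_rejected(self):
        rep = Replicon("c", 40_000, True, ori_bp=10_000)
        dos = sim_copy_number([rep], GrowthParams(c_over_tau=1.0), 1_000)
        prof, fit = self._noiseless_fit(rep, dos)
        with pytest.raises(ValueError, match="too large"):
            detect_slope_breaks(prof, fit, [rep], window_span=100)
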