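"""Artifact detection, interpolation, resampling and filtering."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import isopupil as ip
from isopupil.preprocess import lowpass


def oracle_mask(t, v, limit=10.0, tol=1e-6):
    """Independent double-loop implementation of both artifact rules."""
    n = len(v)
    flags = np.zeros(n, bool)
    for i in range(n):
        if not np.isfinite(v[i]) or abs(v[i]) <= tol:
            flags[i] = True
    for i in range(n - 1):
        dv, dt = v[i + 1] - v[i], t[i + 1] - t[i]
        if np.isfinite(dv) and abs(dv / dt) > limit:
            flags[i] = flags[i + 1] = True
    return flags


class TestDetectArtifacts:
    def test_zero_sample_flags_itself_and_velocity_flags_neighbours(self):
        t = np.arange(4) / 90.0
        v = np.array([4.0, 4.0, 0.0, 4.0])
        mask = ip.detect_artifacts(t, v)
        assert list(mask.flags) == [False, True, True, True]
        assert mask.reason[2] == "zero"  # zero rule takes precedence
        assert mask.reason[1] == "velocity" and mask.reason[3] == "velocity"

    def test_constant_trace_unflagged(self):
        t = np.arange(100) / 90.0
        mask = ip.detect_artifacts(t, np.full(100, 4.5))
        assert not mask.flags.any()

    def test_missing_values_flagged_as_zero(self):
        t = np.arange(3) / 90.0
        mask = ip.detect_artifacts(t, np.array([4.0, np.nan, 4.0]))
        assert mask.reason[1] == "zero"

    def test_slow_drift_below_limit_unflagged(self):
        t = np.arange(200) / 90.0
        v = 4.0 + 0.05 * t  # 0.05 mm/s
        assert not ip.detect_artifacts(t, v).flags.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_equivalent_to_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 1000))
        t = np.cumsum(rng.uniform(0.005, 0.02, n))
        # smooth base so both flagged and unflagged pairs occur, plus spikes
        v = 4.0 + 0.5 * np.sin(t) + rng.normal(0, 0.01, n)
        v[rng.random(n) < 0.05] = 0.0
        v[rng.random(n) < 0.05] = np.nan
        v[rng.random(n) < 0.03] += rng.uniform(0.5, 2.0)
        mask = ip.detect_artifacts(t, v)
        np.testing.assert_array_equal(mask.flags, oracle_mask(t, v))

    def test_non_increasing_timestamps_rejected(self):
        with pytest.raises(ip.PreconditionError):
            ip.detect_artifacts([0.0, 0.0, 0.01], [4, 4, 4])


class TestDilateMask:
    def test_90hz_grid_widens_by_4_samples_each_side(self):
        # 50 ms / (1/90 s) = 4.5, so samples within +-50 ms are 4 on each side
        t = np.arange(181) / 90.0
        flags = np.zeros(181, bool)
        flags[90] = True  # t = 1.000 s
        mask = ip.ArtifactMask(flags, np.where(flags, "zero", "none"))
        out = ip.dilate_mask(mask, t, 0.050)
        assert list(np.flatnonzero(out.flags)) == list(range(86, 95))
        assert out.reason[90] == "zero"
        assert set(out.reason[86:90]) == {"dilation"}

    def test_zero_radius_is_identity(self):
        t = np.arange(50) / 90.0
        flags = np.zeros(50, bool)
        flags[[3, 20]] = True
        mask = ip.ArtifactMask(flags, np.where(flags, "zero", "none"))
        out = ip.dilate_mask(mask, t, 0.0)
        np.testing.assert_array_equal(out.flags, mask.flags)
        np.testing.assert_array_equal(out.reason, mask.reason)

    def test_negative_radius_rejected(self):
        mask = ip.ArtifactMask(np.zeros(3, bool), np.array(["none"] * 3))
        with pytest.raises(ip.ConfigError):
            ip.dilate_mask(mask, np.arange(3) / 90.0, -0.01)

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.1))
    def test_double_dilation_contained_in_single_double_radius(self, seed, r):
        rng = np.random.default_rng(seed)
        n = 120
        t = np.cumsum(rng.uniform(0.005, 0.02, n))
        flags = rng.random(n) < 0.05
        mask = ip.ArtifactMask(flags, np.where(flags, "zero", "none"))
        twice = ip.dilate_mask(ip.dilate_mask(mask, t, r), t, r)
        once = ip.dilate_mask(mask, t, 2 * r)
        assert not np.any(twice.flags & ~once.flags)


class TestInterpolateArtifacts:
    def test_midpoint_fill(self):
        t = np.array([0.0, 0.01, 0.02])
        mask = ip.ArtifactMask([False, True, False], ["none", "zero", "none"])
        out = ip.interpolate_artifacts(t, [4.0, 0.0, 5.0], mask)
        np.testing.assert_allclose(out, [4.0, 4.5, 5.0])

    def test_empty_mask_is_identity(self):
        t = np.arange(10) / 90.0
        v = np.linspace(4, 5, 10)
        mask = ip.ArtifactMask(np.zeros(10, bool), np.array(["none"] * 10))
        np.testing.assert_array_equal(ip.interpolate_artifacts(t, v, mask), v)

    def test_leading_run_filled_with_first_valid_value(self):
        t = np.arange(5) / 90.0
        flags = np.array([True, True, False, False, False])
        mask = ip.ArtifactMask(flags, np.where(flags, "zero", "none"))
        out = ip.interpolate_artifacts(t, [0.0, 0.0, 4.2, 4.3, 4.4], mask)
        np.testing.assert_allclose(out[:3], [4.2, 4.2, 4.2])

    def test_idempotent_and_unflagged_bit_identical(self):
        rng = np.random.default_rng(3)
        n = 300
        t = np.cumsum(rng.uniform(0.005, 0.02, n))
        v = rng.uniform(3, 6, n)
        flags = rng.random(n) < 0.2
        v[flags] = 0.0
        mask = ip.ArtifactMask(flags, np.where(flags, "zero", "none"))
        once = ip.interpolate_artifacts(t, v, mask)
        twice = ip.interpolate_artifacts(t, once, mask)
        np.testing.assert_array_equal(once, twice)
        np.testing.assert_array_equal(once[~flags], v[~flags])

    def test_all_flagged_unrecoverable(self):
        mask = ip.ArtifactMask(np.ones(3, bool), np.array(["zero"] * 3))
        with pytest.raises(ip.UnrecoverableTraceError):
            ip.interpolate_artifacts(np.arange(3) / 90.0, np.zeros(3), mask)


class TestDataLoss:
    @pytest.mark.parametrize(
        "n_flagged,total,frac,excluded",
        [(10, 100, 0.10, False), (16, 100, 0.16, True), (0, 50, 0.0, False),
         (15, 100, 0.15, False)],  # exclusion is strictly greater than 15%
    )
    def test_fraction_and_exclusion_rule(self, n_flagged, total, frac, excluded):
        flags = np.zeros(total, bool)
        flags[:n_flagged] = True
        mask = ip.ArtifactMask(flags, np.where(flags, "zero", "none"))
        loss = ip.data_loss_fraction(mask)
        assert loss == pytest.approx(frac)
        assert ip.is_excluded(loss) is excluded


class TestResampleUniform:
    def test_already_uniform_identity(self):
        t = np.arange(200) / 90.0
        v = np.sin(t)
        grid, out = ip.resample_uniform(t, v, 90.0)
        np.testing.assert_allclose(out, v, atol=1e-9)

    def test_affine_signal_exact(self):
        rng = np.random.default_rng(5)
        t = np.cumsum(rng.uniform(0.005, 0.02, 400))
        v = 4.0 + 0.3 * t
        grid, out = ip.resample_uniform(t, v, 90.0)
        np.testing.assert_allclose(out, 4.0 + 0.3 * grid, atol=1e-9)

    def test_jittered_grid_matches_dense_oracle(self):
        rng = np.random.default_rng(6)
        base = np.arange(500) / 90.0
        t = base + rng.uniform(-0.002, 0.002, 500)
        t = np.maximum.accumulate(t + np.arange(500) * 1e-9)
        v = 4 + 0.5 * t  # piecewise-linear interp of affine data is exact
        grid, out = ip.resample_uniform(t, v, 90.0)
        np.testing.assert_allclose(out, np.interp(grid, t, v), atol=1e-12)

    def test_bad_rate_rejected(self):
        with pytest.raises(ip.ConfigError):
            ip.resample_uniform(np.arange(5) / 90.0, np.zeros(5), 0.0)


class TestLowpass:
    def test_dc_gain_unity(self):
        t = np.arange(900) / 90.0
        out = lowpass(t, np.full(900, 4.5), 0.5, 90.0)
        np.testing.assert_allclose(out.value, 4.5, atol=1e-6)

    def test_10hz_sine_through_0p5hz_cutoff_heavily_attenuated(self):
        t = np.arange(1800) / 90.0
        x = np.sin(2 * np.pi * 10 * t)
        out = lowpass(t, x, 0.5, 90.0)
        mid = out.value[300:-300]  # avoid edge transients
        assert np.abs(mid).max() < 0.01

    def test_attenuation_monotone_above_cutoff(self):
        t = np.arange(3600) / 90.0
        amps = []
        for f in (0.75, 1.0, 1.5, 2.0, 3.0):  # above the noise floor
            out = lowpass(t, np.sin(2 * np.pi * f * t), 0.5, 90.0)
            amps.append(np.abs(out.value[600:-600]).max())
        assert all(a > b for a, b in zip(amps, amps[1:]))

    def test_plr_transient_slower_at_aggressive_cutoff(self):
        t = np.arange(0, 20, 1 / 90.0)
        x = 4.75 - 1.5 * np.where(t > 10, 1 - np.exp(-(t - 10) / 0.2), 0.0)
        v4 = np.gradient(lowpass(t, x, 4.0, 90.0).value, 1 / 90.0)
        v05 = np.gradient(lowpass(t, x, 0.5, 90.0).value, 1 / 90.0)
        assert np.abs(v05).max() < np.abs(v4).max()

    def test_cutoff_at_or_above_nyquist_rejected(self):
        t = np.arange(100) / 90.0
        with pytest.raises(ip.ConfigError):
            lowpass(t, np.zeros(100), 45.0, 90.0)

    def test_too_short_series_rejected(self):
        t = np.arange(10) / 90.0
        with pytest.raises(ip.PreconditionError):
            lowpass(t, np.zeros(10), 4.0, 90.0)


class TestFullChain:
    def test_cleaning_is_transparent_on_clean_trace(self, clean_session):
        """Detect -> dilate -> interpolate -> resample leaves an artifact-free
        physiological trace essentially unchanged (< 1% of dynamic range)."""
        trace, _ = clean_session
        d = ip.combine_eyes(trace)
        t = trace.t
        mask = ip.dilate_mask(ip.detect_artifacts(t, d), t)
        assert not mask.flags.any()
        clean = ip.interpolate_artifacts(t, d, mask)
        grid, uniform = ip.resample_uniform(t, clean, 90.0)
        ref = np.interp(grid, t, d)
        rng_span = d.max() - d.min()
        assert np.abs(uniform - ref).max() < 0.01 * rng_span

    def test_preprocess_reports_qc_and_both_pathways(self, default_session):
        trace, _ = default_session
        res = ip.preprocess(trace.t, ip.combine_eyes(trace))
        assert res.plr.cutoff_hz == 4.0 and res.cognitive.cutoff_hz == 0.5
        assert 0.0 < res.data_loss_fraction < 0.15 and not res.excluded
        qc = res.qc_report()
        assert set(qc["artifact_counts"]) == {"zero", "velocity", "dilation"}
        assert qc["n_samples"] == len(trace)
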