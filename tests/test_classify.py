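import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import myxospt as m
from conftest import brute_force_msd, random_track
from myxospt.io import Movie

track_strategy = st.integers(min_value=0, max_value=2**31 - 1)


def seeded_track(seed, n_min=4, n_max=12, scale=150.0):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    return rng.normal(0.0, scale, size=(n, 2))


class TestBoundingSpan:
    def test_identical_points_zero_span(self):
        xy = np.tile([500.0, 300.0], (6, 1))
        assert m.bounding_span(xy) == (0.0, 0.0)

    def test_two_point_span(self):
        xy = np.array([[0.0, 0.0], [450.0, 30.0]])
        assert m.bounding_span(xy) == (450.0, 30.0)

    @given(track_strategy)
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        xy = seeded_track(seed)
        sx, sy = m.bounding_span(xy)
        bx = max(p[0] for p in xy) - min(p[0] for p in xy)
        by = max(p[1] for p in xy) - min(p[1] for p in xy)
        assert sx == bx and sy == by

    @given(track_strategy)
    @settings(max_examples=50, deadline=None)
    def test_span_monotone_under_extension(self, seed):
        """Appending a point never shrinks either span."""
        rng = np.random.default_rng(seed)
        xy = rng.normal(0, 100, size=(5, 2))
        extra = rng.normal(0, 400, size=2)
        s0 = m.bounding_span(xy)
        s1 = m.bounding_span(np.vstack([xy, extra]))
        assert s1[0] >= s0[0] and s1[1] >= s0[1]


class TestImmotileRule:
    def test_stationary_noiseless_track_immotile(self):
        assert m.classify_immotile(np.tile([1000.0, 800.0], (8, 1)))

    def test_drifting_track_motile(self):
        # 50 nm/frame over 10 frames spans 450 nm > 160 nm
        xy = np.stack([50.0 * np.arange(10), np.zeros(10)], axis=1)
        assert not m.classify_immotile(xy)

    def test_true_stationary_rarely_misclassified_at_25nm_noise(self):
        """≤5% of noisy stationary tracks leave the one-pixel box (10⁴ MC)."""
        rng = np.random.default_rng(99)
        mis = 0
        n_mc = 10_000
        for _ in range(n_mc):
            n = int(rng.integers(4, 13))
            xy = rng.normal(0.0, 25.0, size=(n, 2))
            if not m.classify_immotile(xy):
                mis += 1
        assert mis / n_mc <= 0.05

    @given(track_strategy)
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_time_reversal_and_translation(self, seed):
        xy = seeded_track(seed)
        flag = m.classify_immotile(xy)
        assert m.classify_immotile(xy[::-1]) == flag
        assert m.classify_immotile(xy + np.array([12345.6, -987.3])) == flag


class TestMSD:
    def test_stationary_msd_zero(self):
        msd = m.compute_msd(np.tile([100.0, 50.0], (7, 1)))
        np.testing.assert_allclose(msd[:, 1], 0.0)

    def test_ballistic_closed_form(self):
        """100 nm steps: MSD(k) = (0.1·k)² µm²."""
        xy = np.stack([100.0 * np.arange(8), np.zeros(8)], axis=1)
        msd = m.compute_msd(xy)
        np.testing.assert_allclose(msd[:, 1], (0.1 * msd[:, 0]) ** 2, rtol=1e-12)

    @given(track_strategy)
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_pair_enumeration(self, seed):
        xy = seeded_track(seed)
        got = m.compute_msd(xy)
        oracle = brute_force_msd(xy)
        np.testing.assert_allclose(got, oracle, rtol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            m.compute_msd(np.zeros((1, 2)))


class TestEstimateD:
    def test_exact_line_recovers_slope(self):
        lags = np.arange(1, 6)
        msd = np.stack([lags, 4 * 0.02 * lags * 0.1], axis=1)
        d, b, clamped = m.estimate_D(msd, 0.1)
        assert d == pytest.approx(0.02, rel=1e-12)
        assert b == pytest.approx(0.0, abs=1e-15)
        assert not clamped

    def test_intercept_absorbs_localization_noise(self):
        lags = np.arange(1, 6)
        offset = 4 * 0.025**2
        msd = np.stack([lags, 4 * 0.02 * lags * 0.1 + offset], axis=1)
        d, b, _ = m.estimate_D(msd, 0.1)
        assert d == pytest.approx(0.02, rel=1e-12)
        assert b == pytest.approx(offset, rel=1e-9)

    def test_negative_slope_clamped_and_flagged(self):
        msd = np.stack([np.arange(1, 4), [3e-3, 2e-3, 1e-3]], axis=1)
        d, _, clamped = m.estimate_D(msd, 0.1)
        assert d == 0.0 and clamped

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            m.estimate_D(np.array([[1, 1e-3], [2, 2e-3]]), 0.1, fit_lags=3)

    @pytest.mark.parametrize("d_true", [0.005, 0.018, 0.029])
    def test_population_mean_recovery(self, d_true):
        """Mean per-track D̂ over 5,000 PALM-length tracks recovers D*."""
        tracks = m.simulate_diffusive_tracks(d_true, 5000, rng=int(d_true * 1e5))
        ds = []
        for tr in tracks:
            msd = m.compute_msd(tr)
            if len(msd) >= 3:
                d, _, _ = m.estimate_D(msd, 0.1)
                ds.append(d)
        assert np.mean(ds) == pytest.approx(d_true, rel=0.15)


class TestModeClassification:
    def test_stationary_noiseless(self):
        assert m.classify_mode(np.tile([0.0, 0.0], (6, 1)), 0.1) == "stationary"

    def test_ballistic_alpha_two_directed(self):
        xy = np.stack([100.0 * np.arange(8), np.zeros(8)], axis=1)
        assert m.classify_mode(xy, 0.1) == "directed"

    def test_short_nonstationary_ambiguous(self):
        xy = np.array([[0, 0], [200.0, 0], [400.0, 0], [600.0, 0]])
        assert m.classify_mode(xy, 0.1) == "ambiguous"

    def test_mixture_mode_accuracy(self):
        """≥80% confusion-matrix accuracy on a known mixture (render-free)."""
        cfg = m.SimulateConfig(n_tracks=900)
        sim = m.simulate_population(cfg, rng=8, render=False)
        obs = sim.observed
        correct = total = 0
        for pid, grp in obs.groupby("particle_id"):
            if not (4 <= len(grp) <= 12):
                continue
            xy = grp.sort_values("frame")[["x_nm", "y_nm"]].to_numpy()
            got = m.classify_mode(xy, 0.1)
            if got == "ambiguous":
                continue
            true = grp["mode"].iloc[0]
            total += 1
            correct += got == true
        assert total > 200
        assert correct / total >= 0.80


class TestPopulationSummary:
    def _motion(self, immotile_flags, d_vals=None):
        n = len(immotile_flags)
        return pd.DataFrame({
            "particle_id": range(n),
            "immotile": immotile_flags,
            "D_um2_s": d_vals if d_vals is not None else np.where(immotile_flags, np.nan, 0.02),
            "mode": ["stationary" if f else "diffusive" for f in immotile_flags],
        })

    def test_counting(self):
        s = m.summarize_population(self._motion([True] * 3 + [False] * 7))
        assert s.n_total == 10 and s.n_immotile == 3
        assert s.immotile_fraction == pytest.approx(0.30)

    def test_all_immotile_no_d_stats(self):
        s = m.summarize_population(self._motion([True] * 5))
        assert s.d_motile_mean is None and s.d_motile_sd is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.summarize_population(self._motion([]))


class TestCompositeProjection:
    def _movie(self, frames):
        return Movie(frames=frames, pixel_size_nm=160.0, frame_interval_s=0.1)

    def test_constant_movie_projection_is_any_frame(self):
        frames = np.full((120, 8, 8), 3.0)
        comp = m.composite_projection(self._movie(frames), 100)
        np.testing.assert_array_equal(comp, frames[0])

    def test_single_bright_pixel_survives_max(self):
        frames = np.zeros((120, 8, 8))
        frames[50, 3, 4] = 7.0
        comp = m.composite_projection(self._movie(frames), 100)
        assert comp[3, 4] == 7.0

    def test_max_dominates_mean_pixelwise(self, rng):
        frames = rng.uniform(0, 10, size=(110, 6, 6))
        movie = self._movie(frames)
        assert (m.composite_projection(movie, 100, "max")
                >= m.composite_projection(movie, 100, "mean")).all()

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            m.composite_projection(self._movie(np.zeros((10, 4, 4))), 100)


class TestAnalyzeTrajectories:
    def test_track_outside_duration_window_rejected(self):
        rows = [(0, t, 10.0 * t, 0.0, 1) for t in range(20)]
        df = pd.DataFrame(rows, columns=["particle_id", "frame", "x_nm", "y_nm", "cell_id"])
        with pytest.raises(ValueError, match="window"):
            m.analyze_trajectories(df, 0.1)

    def test_summary_columns_and_flags(self):
        rows = []
        for t in range(6):  # stationary
            rows.append((0, t, 100.0, 100.0, 1))
        for t in range(6):  # fast drift
            rows.append((1, t, 400.0 * t, 0.0, 1))
        df = pd.DataFrame(rows, columns=["particle_id", "frame", "x_nm", "y_nm", "cell_id"])
        motion = m.analyze_trajectories(df, 0.1)
        assert motion.loc[motion.particle_id == 0, "immotile"].item()
        assert not motion.loc[motion.particle_id == 1, "immotile"].item()
        assert np.isnan(motion.loc[motion.particle_id == 0, "D_um2_s"].item())
        assert motion.loc[motion.particle_id == 1, "D_um2_s"].item() > 0
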