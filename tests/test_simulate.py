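import numpy as np
import pandas as pd
import pytest

import myxospt as m
from myxospt.simulate import MODES, gliding_events_to_tables


class TestTrajectories:
    def test_stationary_positions_identical(self, straight_cell, rng):
        pos = m.simulate_trajectory(
            straight_cell, m.MotionParams("stationary"), 12, 0.1, rng
        )
        assert pos.shape == (12, 2)
        assert (pos == pos[0]).all()

    def test_brownian_step_variance_matches_2_D_dt(self):
        """Unconfined increments have per-axis variance 2·D·dt (D = 0.018)."""
        huge = m.make_cell(10_000.0, 5_000.0)
        pos = m.simulate_trajectory(
            huge, m.MotionParams("diffusive", D_um2_s=0.018), 100_001, 0.1, 7,
            start_um=np.zeros(2),
        )
        steps = np.diff(pos / 1000.0, axis=0)
        expected = 2 * 0.018 * 0.1  # 3.6e-3 µm²
        for axis in (0, 1):
            assert steps[:, axis].var() == pytest.approx(expected, rel=0.03)

    def test_directed_no_transverse_steps_are_v_dt(self, straight_cell):
        # start at the cell centre so 10 frames at 1 µm/s stay clear of the poles
        pos = m.simulate_trajectory(
            straight_cell,
            m.MotionParams("directed", v_um_s=1.0, amplitude_um=0.0),
            10, 0.1, 3, start_um=straight_cell.center,
        )
        d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        np.testing.assert_allclose(d, 100.0, atol=1e-9)  # 100 nm per frame

    def test_confinement_all_positions_inside_cell(self, straight_cell, rng):
        for mode, kw in [
            ("diffusive", {"D_um2_s": 0.06}),
            ("directed", {"v_um_s": 1.0, "amplitude_um": 0.28}),
            ("stationary", {}),
        ]:
            pos = m.simulate_trajectory(
                straight_cell, m.MotionParams(mode, **kw), 200, 0.1, rng
            )
            assert straight_cell.contains(pos / 1000.0).all(), mode

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            m.MotionParams("levitating")

    def test_bad_horizon_rejected(self, straight_cell):
        with pytest.raises(ValueError):
            m.simulate_trajectory(straight_cell, m.MotionParams("stationary"), 0, 0.1)


class TestPhotophysics:
    def test_geometric_mean_on_duration(self):
        sched = m.simulate_photophysics(100_000, 10**6, 6.0, 10**6, rng=1)
        dur = sched["bleach_frame"] - sched["activation_frame"] + 1
        assert dur.mean() == pytest.approx(6.0, rel=0.02)

    def test_single_active_particle_per_cell(self):
        cells = np.repeat(np.arange(40), 25)
        sched = m.simulate_photophysics(
            1000, 300, 5.0, max_active_per_cell=1, rng=3, cell_ids=cells
        )
        for cid, grp in sched.groupby("cell_id"):
            iv = grp.sort_values("activation_frame")
            # inclusive intervals must be disjoint within a cell
            assert (
                iv["activation_frame"].to_numpy()[1:]
                > iv["bleach_frame"].to_numpy()[:-1]
            ).all()

    def test_single_frame_horizon(self):
        # one particle per cell: no deferral, so everyone activates at frame 0
        sched = m.simulate_photophysics(50, 1, 3.0, 5, rng=9,
                                        cell_ids=np.arange(50))
        assert (sched["activation_frame"] == 0).all()
        assert (sched["bleach_frame"] >= 0).all()


class TestRendering:
    def _noiseless_cfg(self, **kw):
        base = dict(photons_per_frame=800.0, background_level=0.0,
                    read_noise_sd=0.0, image_shape=(32, 32))
        base.update(kw)
        return m.RenderConfig(**base)

    def test_photon_conservation_single_spot(self):
        """Signal integrates to photons_per_frame within PSF truncation."""
        from myxospt.simulate import _psf_window
        cfg = self._noiseless_cfg()
        sigma_px = cfg.psf_sigma_nm / cfg.pixel_size_nm
        r0, c0, patch = _psf_window(16.2, 15.7, sigma_px, cfg.photons_per_frame,
                                    cfg.image_shape, 6)
        assert patch.sum() == pytest.approx(cfg.photons_per_frame, rel=0.005)

    def test_background_only(self):
        cfg = m.RenderConfig(photons_per_frame=500, background_level=7,
                             read_noise_sd=0, image_shape=(16, 16))
        truth = pd.DataFrame(columns=["particle_id", "frame", "x_nm", "y_nm"])
        movie = m.render_movie(truth, cfg, rng=0, n_frames=3)
        # Poisson(7) everywhere: mean close to 7, integer-valued
        assert movie.frames.dtype == np.uint16
        assert movie.frames.mean() == pytest.approx(7.0, rel=0.1)

    def test_doubling_photons_doubles_mean_signal(self):
        n_rep = 60  # average out Poisson shot noise
        truth = pd.DataFrame({
            "particle_id": np.zeros(n_rep, dtype=int),
            "frame": np.arange(n_rep),
            "x_nm": np.full(n_rep, 16 * 160.0),
            "y_nm": np.full(n_rep, 16 * 160.0),
        })
        means = []
        for photons in (400.0, 800.0):
            cfg = self._noiseless_cfg(photons_per_frame=photons)
            movie = m.render_movie(truth, cfg, rng=11, n_frames=n_rep)
            means.append(movie.frames.astype(float).sum() / n_rep)
        assert means[1] == pytest.approx(2 * means[0], rel=0.03)

    def test_outside_positions_error_names_particles(self):
        cfg = self._noiseless_cfg()
        truth = pd.DataFrame(
            {"particle_id": [5], "frame": [0], "x_nm": [-50.0], "y_nm": [10.0]}
        )
        with pytest.raises(ValueError, match=r"\[5\]"):
            m.render_movie(truth, cfg, rng=0)


class TestPopulation:
    def test_degenerate_mixture_all_stationary(self):
        cfg = m.SimulateConfig(
            fractions={"stationary": 1.0, "directed": 0.0, "diffusive": 0.0},
            n_tracks=50,
        )
        sim = m.simulate_population(cfg, rng=2, render=False)
        assert set(sim.truth["mode"]) == {"stationary"}

    def test_mode_counts_within_multinomial_bounds(self):
        fr = {"stationary": 0.3, "directed": 0.2, "diffusive": 0.5}
        cfg = m.SimulateConfig(fractions=fr, n_tracks=10_000)
        cfg.cells.margin_um = 0.4
        sim = m.simulate_population(cfg, rng=4, render=False)
        modes = sim.truth.groupby("particle_id")["mode"].first()
        n = len(modes)
        for mode, p in fr.items():
            count = (modes == mode).sum()
            sd = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 3 * sd, mode

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            m.SimulateConfig(fractions={"stationary": 0.5, "directed": 0.4,
                                        "diffusive": 0.0})

    def test_same_seed_bit_identical(self):
        cfg = m.SimulateConfig(n_tracks=80)
        a = m.simulate_population(cfg, rng=123, render=True)
        b = m.simulate_population(cfg, rng=123, render=True)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.movie.frames, b.movie.frames)

    def test_truth_positions_inside_owning_cell(self):
        cfg = m.SimulateConfig(n_tracks=150)
        sim = m.simulate_population(cfg, rng=5, render=False)
        cells = {c.id: c for c in sim.cells}
        for cid, grp in sim.truth.groupby("cell_id"):
            pts = grp[["x_nm", "y_nm"]].to_numpy() / 1000.0
            assert cells[cid].contains(pts).all()

    def test_render_free_observation_noise(self):
        cfg = m.SimulateConfig(
            fractions={"stationary": 1.0, "directed": 0.0, "diffusive": 0.0},
            n_tracks=400,
        )
        sim = m.simulate_population(cfg, rng=6, render=False)
        resid = (sim.observed[["x_nm", "y_nm"]].to_numpy()
                 - sim.truth[["x_nm", "y_nm"]].to_numpy())
        assert resid.std() == pytest.approx(cfg.motion.loc_noise_sd_nm, rel=0.1)


class TestGlidingSimulator:
    def test_net_displacement_no_events(self):
        """2.30 µm/min for one minute gives 2.30 µm of travel."""
        track, events = m.simulate_gliding_track(2.30, 0, 0, n_steps=6, rng=0)
        assert len(events) == 0
        net = track["x_um"].iloc[-1] - track["x_um"].iloc[0]
        assert net == pytest.approx(2.30, abs=1e-12)

    def test_forced_reversal_alternates_direction(self):
        track, events = m.simulate_gliding_track(
            1.2, reversal_prob_per_step=1.0, n_steps=10, rng=1
        )
        dx = np.diff(track["x_um"].to_numpy())
        assert (np.sign(dx[1:]) == -np.sign(dx[:-1])).all()
        assert (events["kind"] == "reversal").all() and len(events) == 10

    def test_zero_speed_zero_runs(self):
        track, events = m.simulate_gliding_track(0.0, 0, 0, n_steps=12, rng=2)
        assert np.allclose(track[["x_um", "y_um"]].to_numpy(), 0.0)

    def test_event_tables_consistent_with_track(self):
        track, events = m.simulate_gliding_track(
            2.0, 0.05, 0.1, pause_mean_steps=3, n_steps=200, rng=3
        )
        pauses, reversals = gliding_events_to_tables(events, 200)
        dx = np.diff(track["x_um"].to_numpy())
        for _, ev in pauses.iterrows():
            assert np.allclose(dx[int(ev.start_step):int(ev.end_step) + 1], 0.0)


class TestGrowthCurves:
    @pytest.fixture
    def ref(self):
        t = np.arange(0.0, 25.0, 2.0)
        return pd.DataFrame({"time_h": t, "od600": 0.5 * np.exp(0.1 * t)})

    def test_identity_ratios_reproduce_reference(self, ref):
        curves = m.simulate_growth_curves(1.0, 1.0, ref, 0.0)
        for medium in ("liquid", "agarose"):
            mut = curves.query("strain == 'mutant' and medium == @medium")
            np.testing.assert_allclose(mut["od600"].to_numpy(), ref["od600"].to_numpy())

    def test_negative_reference_rejected(self, ref):
        bad = ref.copy()
        bad.loc[2, "od600"] = -0.1
        with pytest.raises(ValueError, match="≥ 0"):
            m.simulate_growth_curves(1.0, 1.0, bad, 0.0)

    def test_scaled_curve_yields_expected_grabs_score(self, ref):
        """Agarose ratio 0.94 with liquid ratio 1.00 gives a −0.06 score."""
        curves = m.simulate_growth_curves(0.94, 1.00, ref, 0.0)
        scores = m.grabs_timecourse(curves)
        assert scores["score"].iloc[-1] == pytest.approx(-0.06, abs=1e-9)
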