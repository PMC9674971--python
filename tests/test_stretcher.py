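import numpy as np
import pandas as pd
import pytest

import wormstretcher as ws
from wormstretcher.stretcher import (
    SlopeRatioCurve,
    tricube_weights,
)

from conftest import wide_stage_profile


def wls_derivative_oracle(t, y, grid, h_bw):
    """Independent brute-force oracle: per grid point, solve the weighted
    least-squares line fit with numpy.linalg.lstsq and read off the slope."""
    out_b0, out_b1 = [], []
    for g in grid:
        x = t - g
        w = tricube_weights(x, h_bw)
        sw = np.sqrt(w)
        A = np.column_stack([sw, sw * x])
        beta, *_ = np.linalg.lstsq(A, sw * y, rcond=None)
        out_b0.append(beta[0])
        out_b1.append(beta[1])
    return np.array(out_b0), np.array(out_b1)


def shape_obs(t_hours, L, W, n_wells=8, noise=0.0, seed=0):
    """Well-level observation frame replicating (t, L, W) across wells."""
    rng = np.random.default_rng(seed)
    frames = []
    for w in range(n_wells):
        frames.append(
            pd.DataFrame(
                {
                    "well": f"w{w}",
                    "hour": t_hours,
                    "median_length_um": L + rng.normal(0, noise, len(t_hours)),
                    "median_width_um": W + rng.normal(0, noise * 0.1, len(t_hours)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestWindows:
    def test_published_dpy1_l2_window(self, clean_summaries):
        _, su = clean_summaries
        sel = ws.select_window(su, ws.StageWindowConfig(), "dpy-1", "L2")
        assert sel["hour"].min() >= 19.0 and sel["hour"].max() <= 26.0

    def test_full_window_keeps_everything(self, clean_summaries):
        _, su = clean_summaries
        conf = ws.StageWindowConfig(windows={("N2", "L1"): (0.0, 43.0)})
        sel = ws.select_window(su, conf, "N2", "L1")
        assert len(sel) == (su["strain"] == "N2").sum()

    def test_l4_excluded_by_default(self, clean_summaries):
        _, su = clean_summaries
        with pytest.raises(KeyError, match="L4"):
            ws.select_window(su, ws.StageWindowConfig(), "N2", "L4")

    def test_empty_selection_names_window(self, clean_summaries):
        _, su = clean_summaries
        conf = ws.StageWindowConfig(windows={("N2", "L1"): (0.1, 0.2)})
        with pytest.raises(ValueError, match="N2 L1"):
            ws.select_window(su, conf, "N2", "L1")

    def test_yaml_round_trip(self, tmp_path):
        conf = ws.StageWindowConfig()
        conf.to_yaml(tmp_path / "w.yaml")
        back = ws.StageWindowConfig.from_yaml(tmp_path / "w.yaml")
        assert back.windows == dict(conf.windows)


class TestKernelSmooth:
    def test_constant_reproduced(self):
        t = np.linspace(0, 10, 40)
        grid = np.linspace(1, 9, 17)
        yhat, dyhat = ws.kernel_smooth(t, np.full(40, 250.0), grid, 1.5)
        assert np.allclose(yhat, 250.0, atol=1e-9)
        assert np.allclose(dyhat, 0.0, atol=1e-9)

    def test_line_reproduced_exactly(self):
        t = np.linspace(0, 10, 37)
        grid = np.linspace(0.5, 9.5, 19)
        yhat, dyhat = ws.kernel_smooth(t, 3.0 * t + 7.0, grid, 1.2)
        assert np.allclose(yhat, 3.0 * grid + 7.0, atol=1e-9)
        assert np.allclose(dyhat, 3.0, atol=1e-9)

    def test_matches_wls_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n = rng.integers(30, 80)
            t = np.sort(rng.uniform(0, 10, n))
            y = rng.normal(0, 1, n) + np.sin(t)
            h = rng.uniform(1.5, 2.5)
            grid = np.linspace(t[2], t[-3], 15)
            yhat, dyhat = ws.kernel_smooth(t, y, grid, h)
            b0, b1 = wls_derivative_oracle(t, y, grid, h)
            assert np.allclose(yhat, b0, atol=1e-9, rtol=1e-9)
            assert np.allclose(dyhat, b1, atol=1e-9, rtol=1e-9)

    def test_quadratic_derivative_against_oracle(self):
        t = np.linspace(1, 10, 200)
        grid = np.linspace(2, 9, 20)
        _, dyhat = ws.kernel_smooth(t, t**2, grid, 1.0)
        _, oracle = wls_derivative_oracle(t, t**2, grid, 1.0)
        assert np.allclose(dyhat, oracle, atol=1e-9)

    def test_tiny_bandwidth_raises(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError, match="bandwidth"):
            ws.kernel_smooth(t, t, np.array([4.5]), 0.3)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            ws.kernel_smooth(np.array([1.0, 1.0, 2.0, 3.0]), np.arange(4.0),
                             np.array([2.0]), 1.0)


class TestBootstrap:
    def test_identical_wells_zero_sd(self):
        t = np.arange(1.0, 11.0)
        obs = shape_obs(t, 10 * t + 100, 2 * t + 10, n_wells=6, noise=0.0)
        curve = ws.bootstrap_bands(obs, n_boot=100, seed=0)
        assert np.allclose(curve.length_sd, 0.0, atol=1e-9)
        assert np.allclose(curve.width_sd, 0.0, atol=1e-9)

    def test_deterministic_under_seed(self):
        t = np.arange(1.0, 11.0)
        obs = shape_obs(t, 10 * t + 100, 2 * t + 10, n_wells=6, noise=2.0, seed=5)
        a = ws.bootstrap_bands(obs, n_boot=120, seed=9)
        b = ws.bootstrap_bands(obs, n_boot=120, seed=9)
        assert np.array_equal(a.length_mean, b.length_mean)
        assert np.array_equal(a.length_sd, b.length_sd)

    def test_too_few_wells_raises(self):
        t = np.arange(1.0, 11.0)
        obs = shape_obs(t, 10 * t, 2 * t, n_wells=3)
        with pytest.raises(ValueError, match="wells"):
            ws.bootstrap_bands(obs, n_boot=100)

    def test_sd_shrinks_with_wells(self):
        # quadrupling wells shrinks the band roughly like 1/sqrt(n)
        t = np.arange(1.0, 11.0)
        ratios = []
        for seed in range(5):
            sds = {}
            for n_wells in (6, 24):
                obs = shape_obs(t, 10 * t + 100, 2 * t + 10,
                                n_wells=n_wells, noise=3.0, seed=seed)
                curve = ws.bootstrap_bands(obs, n_boot=150, seed=seed)
                sds[n_wells] = np.mean(curve.length_sd)
            ratios.append(sds[24] / sds[6])
        assert 0.35 < np.mean(ratios) < 0.65


class TestSlopeRatio:
    def test_proportional_width_gives_constant_ratio(self):
        t = np.linspace(1, 10, 50)
        L = 25 * t + 200
        obs = shape_obs(t, L, 0.2 * L + 3.0, n_wells=6)
        curve = ws.bootstrap_bands(obs, n_boot=0, seed=0)
        ratio = ws.slope_ratio(curve)
        assert np.allclose(ratio.ratio[ratio.mask], 0.2, atol=1e-9)

    def test_quadratic_closed_form(self):
        t = np.round(np.arange(1.0, 2.0001, 0.01), 10)
        obs = shape_obs(t, t, t**2, n_wells=5)
        curve = ws.bootstrap_bands(obs, grid_step=0.25, h_bw=0.4, n_boot=0, seed=0)
        i = int(np.argmin(np.abs(curve.grid - 1.5)))
        ratio = ws.slope_ratio(curve)
        assert ratio.ratio[i] == pytest.approx(3.0, abs=1e-6)

    def test_plateau_masked(self):
        t = np.arange(1.0, 13.0)
        L = np.where(t < 7, 10 * t, 70.0)  # growth then hard plateau
        obs = shape_obs(t, L, 0.2 * L, n_wells=5)
        curve = ws.bootstrap_bands(obs, n_boot=0, seed=0)
        ratio = ws.slope_ratio(curve)
        assert not ratio.mask[-1]
        assert ratio.mask[4]

    def test_all_masked_raises(self):
        t = np.arange(1.0, 11.0)
        obs = shape_obs(t, np.full_like(t, 70.0), np.full_like(t, 20.0), n_wells=5)
        curve = ws.bootstrap_bands(obs, n_boot=0, seed=0)
        with pytest.raises(ValueError, match="masked"):
            ws.slope_ratio(curve)

    def test_planted_ramp_recovered_within_band(self):
        prof = wide_stage_profile()
        model = ws.CalibrationModel(
            tof_to_um_slope=1 / ws.PIXELS_PER_MICRON,
            normext_to_um_slope=1 / ws.PIXELS_PER_MICRON,
        )
        conf = ws.StageWindowConfig(windows={("wide", "L2"): (17.0, 22.5)})
        covered = []
        for seed in range(5):
            cfg = ws.SimulationConfig(
                strain_profiles=(prof,), n_wells_per_hour=20, n_animals_per_well=30,
                contaminant_rate=0.0, seed=3000 + seed,
                hours=tuple(float(h) for h in range(15, 27)),
            )
            su = ws.convert_units(ws.summarize_wells(ws.simulate_dataset(cfg)), model)
            _, ratio, _ = ws.analyze_stage(su, conf, "wide", "L2",
                                           n_boot=200, seed=seed)
            a, b = prof.active_window(2)
            ton = a + 0.7 * (b - a)
            expected = np.where(
                ratio.grid <= ton, 0.2,
                0.2 * (1 + 0.5 * (ratio.grid - ton) / (b - ton)),
            )
            # judge coverage away from the kink and the window edges, where
            # deterministic smoothing bias (not sampling noise) dominates
            interior = (
                ratio.mask
                & (np.abs(ratio.grid - ton) > 1.75)
                & (ratio.grid > ratio.grid[0] + 1.0)
                & (ratio.grid < ratio.grid[-1] - 1.0)
            )
            ok = np.abs(ratio.ratio - expected) <= 2 * ratio.sd
            covered.append(np.mean(ok[interior]))
        assert np.mean(covered) >= 0.90


class TestClassify:
    def flat_curve(self, r=0.2, sd=0.01, n=41):
        grid = np.linspace(16, 24, n)
        return SlopeRatioCurve(
            "s", "L2", grid, np.full(n, r), np.full(n, sd), np.ones(n, bool)
        )

    def test_constant_ratio_all_linear(self):
        seg = ws.classify_regimes(self.flat_curve())
        assert seg.onset_time is None
        assert all(l == "linear" for l in seg.labels)

    def test_strictly_increasing_onset_at_first_admissible(self):
        grid = np.linspace(16, 24, 41)
        curve = SlopeRatioCurve(
            "s", "L2", grid, np.linspace(0.1, 0.5, 41),
            np.full(41, 1e-9), np.ones(41, bool),
        )
        seg = ws.classify_regimes(curve)
        t_base = grid[0] + (grid[-1] - grid[0]) / 3
        first_admissible = grid[grid > t_base][0]
        assert seg.onset_time == pytest.approx(first_admissible)

    def test_z_monotonicity(self):
        grid = np.linspace(16, 24, 41)
        rng = np.random.default_rng(3)
        r = np.where(grid < 21, 0.2, 0.2 + 0.02 * (grid - 21)) + rng.normal(0, 5e-4, 41)
        curve = SlopeRatioCurve("s", "L2", grid, r, np.full(41, 2e-3),
                                np.ones(41, bool))
        onsets = []
        for z in (1.0, 1.5, 2.0, 2.5, 3.0):
            seg = ws.classify_regimes(curve, z=z)
            onsets.append(np.inf if seg.onset_time is None else seg.onset_time)
        assert all(a <= b for a, b in zip(onsets, onsets[1:]))

    def test_short_window_flagged(self):
        grid = np.linspace(16, 18, 9)
        curve = SlopeRatioCurve("s", "L2", grid, np.full(9, 0.2),
                                np.full(9, 0.01), np.ones(9, bool))
        seg = ws.classify_regimes(curve)
        assert seg.flagged and "3 h" in seg.note

    def test_nonlinear_labels_form_suffix(self):
        grid = np.linspace(16, 24, 41)
        curve = SlopeRatioCurve(
            "s", "L2", grid, np.where(grid < 21, 0.2, 0.3),
            np.full(41, 1e-3), np.ones(41, bool),
        )
        seg = ws.classify_regimes(curve)
        labels = list(seg.labels)
        first = labels.index("nonlinear")
        assert all(l == "nonlinear" for l in labels[first:])


class TestRelaxation:
    def summaries_with_step(self, dL, dW, molt=20.0):
        hours = np.arange(1.0, 43.0)
        rows = []
        for w in range(4):
            for h in hours:
                L = 400.0 + (dL if h > molt else 0.0)
                W = 40.0 + (dW if h > molt else 0.0)
                rows.append({"strain": "s", "well": f"w{w}", "hour": h,
                             "median_length_um": L, "median_width_um": W})
        return pd.DataFrame(rows)

    def annotation(self, molt=20.0):
        return [ws.MoltAnnotation("s", (molt,), (("L1", 1.0, molt),
                                                 ("L2", molt, 42.0)))]

    def test_sign_bookkeeping_length_relax(self):
        su = self.summaries_with_step(10.0, -2.0)
        rec = ws.characterize_relaxation(su, self.annotation())[0]
        assert rec.direction == "length-relax"
        assert rec.delta_length_um == pytest.approx(10.0)
        assert rec.delta_width_um == pytest.approx(-2.0)
        assert rec.magnitude_um == pytest.approx(2.0)

    def test_sign_bookkeeping_width_relax(self):
        rec = ws.characterize_relaxation(
            self.summaries_with_step(-5.0, 1.5), self.annotation()
        )[0]
        assert rec.direction == "width-relax"
        assert rec.magnitude_um == pytest.approx(5.0)

    def test_no_change_flagged_ambiguous(self):
        rec = ws.characterize_relaxation(
            self.summaries_with_step(0.0, 0.0), self.annotation()
        )[0]
        assert rec.flagged and rec.direction is None
        assert rec.magnitude_um == 0.0

    def test_molt_near_edge_skipped(self):
        recs = ws.characterize_relaxation(
            self.summaries_with_step(10.0, -2.0, molt=41.5),
            self.annotation(molt=41.5),
        )
        assert recs == []

    def test_invalid_margins_raise(self):
        with pytest.raises(ValueError):
            ws.characterize_relaxation(
                self.summaries_with_step(1.0, -1.0), self.annotation(), pre_margin=0.0
            )

    def test_planted_directions_recovered(self, clean_summaries):
        cfg, su = clean_summaries
        anns = [ws.detect_molts(s) for s in ws.build_fluorescence_series(su)]
        expected = {p.strain_id: p.relaxation_direction for p in cfg.strain_profiles}
        recs = ws.characterize_relaxation(su, anns)
        assert len(recs) == 12
        for rec in recs:
            assert rec.direction == expected[rec.strain_id], rec


class TestAffineInvariance:
    def test_common_scale_leaves_ratio_and_labels_unchanged(self):
        t = np.linspace(1, 12, 60)
        L = 20 * t + 200
        W = np.where(t < 8, 0.2 * L, 0.2 * L + 0.05 * 20 * (t - 8) ** 2 / 2)
        obs = shape_obs(t, L, W, n_wells=6, noise=1.0, seed=4)
        scaled = obs.copy()
        scaled[["median_length_um", "median_width_um"]] *= 7.3
        for df in (obs, scaled):
            curve = ws.bootstrap_bands(df, n_boot=150, seed=1)
            ratio = ws.slope_ratio(curve)
            seg = ws.classify_regimes(ratio)
            df.attrs["out"] = (ratio, seg)
        r1, s1 = obs.attrs["out"]
        r2, s2 = scaled.attrs["out"]
        assert np.allclose(r1.ratio[r1.mask], r2.ratio[r2.mask], rtol=1e-9)
        assert s1.onset_time == s2.onset_time
        assert list(s1.labels) == list(s2.labels)
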