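import itertools

import numpy as np
import pandas as pd
import pytest

from memnano import diffusion as di
from memnano import synth
from conftest import make_localization_df


def tracks_df(points):
    """points: list of (track, frame, x, y)."""
    return pd.DataFrame(points, columns=["track_id", "frame", "x_nm", "y_nm"])


class TestLinking:
    def test_single_clean_molecule_one_track(self, rng):
        frames = np.arange(1, 21)
        df = make_localization_df(
            100 + rng.normal(0, 5, 20), 100 + rng.normal(0, 5, 20), frame=frames
        )
        tr = di.link_trajectories(df)
        assert tr["track_id"].nunique() == 1
        assert len(tr) == 20

    def test_distant_molecules_never_swap(self, rng):
        rows = []
        for f in range(1, 16):
            rows.append((f, 0.0 + rng.normal(0, 10), 0.0 + rng.normal(0, 10)))
            rows.append((f, 6000.0 + rng.normal(0, 10), 6000.0 + rng.normal(0, 10)))
        df = make_localization_df(
            [r[1] for r in rows], [r[2] for r in rows], frame=[r[0] for r in rows]
        )
        tr = di.link_trajectories(df, max_jump_nm=800.0)
        assert tr["track_id"].nunique() == 2
        for _, g in tr.groupby("track_id"):
            assert g["x_nm"].std() < 100  # no cross-over

    def test_crossing_minimizes_total_displacement(self):
        """2 x 2 assignment agrees with exhaustive matching."""
        # frame 1: A=(0,0), B=(300,0); frame 2 candidates: (40,0) and (260,0)
        df = make_localization_df([0.0, 300.0, 40.0, 260.0], [0.0] * 4, frame=[1, 1, 2, 2])
        tr = di.link_trajectories(df, max_jump_nm=800.0)
        # exhaustive oracle over the two possible matchings
        a, b = np.array([0.0, 0.0]), np.array([300.0, 0.0])
        c1, c2 = np.array([40.0, 0.0]), np.array([260.0, 0.0])
        direct = np.linalg.norm(a - c1) + np.linalg.norm(b - c2)
        swapped = np.linalg.norm(a - c2) + np.linalg.norm(b - c1)
        assert direct < swapped
        g = tr.set_index(["frame", "x_nm"])["track_id"]
        assert g[(1, 0.0)] == g[(2, 40.0)]
        assert g[(1, 300.0)] == g[(2, 260.0)]

    def test_row_order_invariance(self, rng):
        frames = np.repeat(np.arange(1, 11), 2)
        x = np.where(np.arange(20) % 2 == 0, 0.0, 5000.0) + rng.normal(0, 10, 20)
        df = make_localization_df(x, np.zeros(20), frame=frames)
        t1 = di.link_trajectories(df)
        t2 = di.link_trajectories(df.sample(frac=1.0, random_state=1))
        key = lambda t: sorted(
            tuple(sorted(map(tuple, g[["frame", "x_nm"]].to_numpy())))
            for _, g in t.groupby("track_id")
        )
        assert key(t1) == key(t2)


class TestMSD:
    def test_stationary_track(self):
        df = tracks_df([(0, f, 10.0, 20.0) for f in range(1, 12)])
        m = di.msd(df, dt_ms=10.0, max_lag=5)
        assert np.allclose(m.msd_um2, 0.0)
        assert m.d_um2_s == 0.0

    def test_deterministic_drift(self):
        s = 50.0  # nm per frame
        df = tracks_df([(0, f, (f - 1) * s, 0.0) for f in range(1, 22)])
        m = di.msd(df, dt_ms=10.0, max_lag=5)
        expect = (np.arange(1, 6) * s) ** 2 / 1e6
        np.testing.assert_allclose(m.msd_um2, expect, rtol=1e-9)

    def test_parameter_recovery(self):
        model = synth.DiffusionModel(1.0, 0.3, 0.0, 10.0, 0.0)
        df = synth.gen_trajectories(model, 1000, 10, seed=91)
        m = di.msd(df, dt_ms=10.0)
        assert m.d_um2_s == pytest.approx(0.3, abs=0.01)

    def test_static_noise_gives_intercept(self):
        sigma = 0.05  # um
        model = synth.DiffusionModel(1.0, 0.2, 0.0, 10.0, sigma * 1000)
        df = synth.gen_trajectories(model, 4000, 10, seed=92)
        m = di.msd(df, dt_ms=10.0)
        assert m.offset_um2 == pytest.approx(4 * sigma**2, rel=0.1)

    def test_msd_linearity_for_brownian(self):
        model = synth.DiffusionModel(1.0, 0.25, 0.0, 10.0, 0.0)
        df = synth.gen_trajectories(model, 2000, 10, seed=93)
        m = di.msd(df, dt_ms=10.0, max_lag=5)
        r = np.corrcoef(m.lags_ms, m.msd_um2)[0, 1]
        assert r**2 > 0.99


class TestStepCDF:
    def test_zero_steps_mass_at_zero(self):
        df = pd.concat(
            [tracks_df([(i, f, 1.0, 2.0) for f in range(1, 60)]) for i in range(2)]
        )
        cdfs = di.step_cdf(df, [1])
        assert np.all(cdfs[1] == 0.0)

    def test_single_population_recovery(self):
        model = synth.DiffusionModel(1.0, 0.3, 0.0, 10.0, 0.0)
        df = synth.gen_trajectories(model, 2000, 8, seed=94)
        cdfs = di.step_cdf(df, [1, 2])
        # fit 1 - exp(-r2 / 4 D t) by matching the empirical mean: E[r2] = 4 D t
        d1 = cdfs[1].mean() / (4 * 0.01) / 1e6
        d2 = cdfs[2].mean() / (4 * 0.02) / 1e6
        assert d1 == pytest.approx(0.3, rel=0.05)
        assert d2 == pytest.approx(0.3, rel=0.05)
        assert d1 == pytest.approx(d2, rel=0.05)

    def test_short_lags_dropped(self):
        df = tracks_df([(0, f, 0.0, 0.0) for f in range(1, 10)])
        cdfs = di.step_cdf(df, [1, 8], min_n=50)
        assert 8 not in cdfs


class TestBinaryFit:
    def test_pure_fast_degenerate(self):
        model = synth.DiffusionModel(1.0, 0.3, 0.0, 10.5, 0.0)
        df = synth.gen_trajectories(model, 3000, 10, seed=95)
        fit = di.fit_binary(di.step_cdf(df, [1, 2, 3]), dt_ms=10.5)
        assert fit.fast_fraction >= 0.95
        assert fit.degenerate

    def test_two_population_recovery_modest_n(self):
        model = synth.DiffusionModel(0.7, 0.35, 0.03, 10.5, 0.0)
        df = synth.gen_trajectories(model, 5000, 12, seed=96)
        fit = di.fit_binary(di.step_cdf(df, [1, 2, 3]), dt_ms=10.5)
        assert fit.fast_fraction == pytest.approx(0.7, abs=0.05)
        assert fit.d1_um2_s == pytest.approx(0.35, rel=0.10)
        assert fit.d2_um2_s == pytest.approx(0.03, rel=0.30)

    def test_needs_two_lags(self):
        with pytest.raises(ValueError):
            di.fit_binary({1: np.arange(100.0)})


class TestIFRAP:
    def test_bleach_only_decay_corrected_flat(self):
        stack = np.ones((12, 30, 30)) * 200.0
        for k in range(12):
            stack[k] *= (1 - 0.03) ** k
        res = di.ifrap_analyze(
            stack, (slice(0, 10), slice(0, 10)), (slice(20, 28), slice(20, 28))
        )
        assert np.allclose(res.i_in_normalized, 1.0, atol=0.01)

    def test_immobile_scenario_ratio_zero(self):
        stack = np.zeros((5, 30, 30))
        stack[:, 0:10, 0:10] = 100.0  # signal confined to the converted region
        res = di.ifrap_analyze(
            stack, (slice(0, 10), slice(0, 10)), (slice(20, 28), slice(20, 28)),
            bleach_per_frame=0.0,
        )
        assert np.allclose(res.out_in_ratio, 0.0)
        assert np.allclose(res.i_in_normalized, 1.0)

    def test_fast_dispersal_loses_signal(self):
        # synthetic dispersal: converted-region signal decays to 20%
        n = 16
        stack = np.zeros((n, 30, 30))
        for k in range(n):
            stack[k, 0:10, 0:10] = 100.0 * (0.2 + 0.8 * np.exp(-k / 3.0))
        res = di.ifrap_analyze(
            stack, (slice(0, 10), slice(0, 10)), (slice(20, 28), slice(20, 28)),
            bleach_per_frame=0.0,
        )
        assert res.i_in_normalized[-1] < 0.3  # >= 70% dispersed

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            di.ifrap_analyze(np.zeros((1, 5, 5)), (slice(0, 2), slice(0, 2)),
                             (slice(3, 5), slice(3, 5)))


def test_binary_fit_bias_grid():
    """Parameter recovery across a grid of (F, D1/D2) has bias < 10%."""
    for f, (d1, d2) in itertools.product((0.6, 0.8), ((0.3, 0.03), (0.4, 0.05))):
        model = synth.DiffusionModel(f, d1, d2, 10.5, 0.0)
        df = synth.gen_trajectories(model, 4000, 10, seed=hash((f, d1)) % 2**31)
        fit = di.fit_binary(di.step_cdf(df, [1, 2, 3]), dt_ms=10.5)
        assert fit.fast_fraction == pytest.approx(f, abs=0.1 * f)
        assert fit.d1_um2_s == pytest.approx(d1, rel=0.1)
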