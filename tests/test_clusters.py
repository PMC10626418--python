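import numpy as np
import pandas as pd
import pytest

from memnano import clusters as cl
from memnano import synth
from conftest import make_localization_df


class TestRipley:
    def test_two_points_brute_force(self):
        # 2 points 5 nm apart in a 100 x 100 nm ROI, no edge correction:
        # K(r >= 5) = (1e4 / 4) * 2 = 5000 nm^2
        df = make_localization_df([50.0, 55.0], [50.0, 50.0])
        curve = cl.ripley_l(df, (100.0, 100.0), radii=[2.0, 5.0, 10.0])
        k = np.pi * (curve.l_minus_r + np.array([2.0, 5.0, 10.0])) ** 2
        assert k[0] == pytest.approx(0.0)
        assert k[1] == pytest.approx(5000.0)
        assert k[2] == pytest.approx(5000.0)

    def test_brute_force_pair_count_random(self, rng):
        xy = rng.uniform(0, 1000.0, (40, 2))
        df = make_localization_df(xy[:, 0], xy[:, 1])
        radii = np.array([50.0, 150.0, 400.0])
        curve = cl.ripley_l(df, (1000.0, 1000.0), radii)
        # independent O(n^2) oracle
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        for r, lmr in zip(radii, curve.l_minus_r):
            k = 1e6 / 40**2 * (d <= r).sum()
            assert lmr == pytest.approx(np.sqrt(k / np.pi) - r, abs=1e-9)

    def test_coincident_points_diverge_at_small_r(self):
        df = make_localization_df(np.full(10, 500.0), np.full(10, 500.0))
        curve = cl.ripley_l(df, (1000.0, 1000.0), radii=[1.0, 5.0])
        # K(1) = area/n^2 * n(n-1) -> L - r huge at r=1
        expect_k = 1e6 / 100 * 90
        assert curve.l_minus_r[0] == pytest.approx(np.sqrt(expect_k / np.pi) - 1.0)
        assert curve.l_minus_r[0] > 100

    def test_requires_two_points(self):
        df = make_localization_df([1.0], [1.0])
        with pytest.raises(ValueError):
            cl.ripley_l(df, (100.0, 100.0), radii=[10.0])

    def test_max_radius_capped_by_roi(self):
        df = make_localization_df([10.0, 20.0], [10.0, 20.0])
        with pytest.raises(ValueError):
            cl.ripley_l(df, (100.0, 100.0), radii=[60.0])


class TestRipleyEnvelope:
    def test_csr_map_called_random(self, csr_map):
        _, loc, blinks = csr_map
        curve = cl.ripley_envelope(loc, (3000.0, 3000.0), blinks, seed=1)
        assert curve.verdict == "random"
        assert curve.env_mean is not None and len(curve.env_mean) == len(curve.radii_nm)

    def test_clustered_map_called_clustered(self, clustered_map):
        _, loc, blinks = clustered_map
        curve = cl.ripley_envelope(loc, (3000.0, 3000.0), blinks, seed=2)
        assert curve.verdict == "clustered"

    def test_empty_map_errors(self):
        df = make_localization_df([], [])
        with pytest.raises(ValueError):
            cl.ripley_envelope(df, (3000.0, 3000.0), synth.BlinkStatistics.default())


class TestMergeBlinks:
    def test_single_detection_single_group(self):
        df = make_localization_df([10.0], [10.0], frame=[1])
        merged, stats = cl.merge_blinks(df)
        assert len(merged) == 1
        assert merged["n_detections"].iloc[0] == 1

    def test_within_gates_merges(self):
        df = make_localization_df([100.0, 150.0], [0.0, 0.0], frame=[1, 5])
        merged, _ = cl.merge_blinks(df)  # gap 4 <= 20, displacement 50 <= 100
        assert len(merged) == 1
        assert merged["x_nm"].iloc[0] == pytest.approx(125.0)

    def test_beyond_displacement_splits(self):
        df = make_localization_df([100.0, 250.0], [0.0, 0.0], frame=[1, 5])
        merged, _ = cl.merge_blinks(df)  # 150 nm > 100 nm gate
        assert len(merged) == 2

    def test_beyond_gap_splits(self):
        df = make_localization_df([100.0, 110.0], [0.0, 0.0], frame=[1, 30])
        merged, _ = cl.merge_blinks(df)  # gap 29 > 20 frames
        assert len(merged) == 2

    def test_outlier_groups_discarded(self):
        n = 40
        df = make_localization_df(np.full(n, 5.0), np.full(n, 5.0), frame=np.arange(1, n + 1))
        merged, _ = cl.merge_blinks(df)
        assert len(merged) == 0  # one group of 40 > 30 threshold

    def test_molecule_count_recovery_with_generous_gates(self):
        """Blink merging recovers the simulated molecule count within 5%."""
        blinks = synth.BlinkStatistics.default()
        pat = synth.gen_point_pattern(30.0, (3000.0, 3000.0), seed=61)
        loc = synth.gen_localizations(pat, blinks, (15.0, 3.0), seed=62)
        merged, stats = cl.merge_blinks(loc)
        assert len(merged) == pytest.approx(len(pat), rel=0.05)
        assert stats.mean_detections == pytest.approx(blinks.mean_detections, rel=0.15)


class TestLDV:
    def test_single_localization_disk_geometry(self):
        # threshold t on a unit-peak Gaussian: supra-threshold disk radius
        # sigma * sqrt(2 ln(1/t))
        roi = (1000.0, 1000.0)
        df = make_localization_df([500.0], [500.0])
        t = 0.5
        cm = cl.ldv_analyze(df, roi, sigma_nm=35.0, threshold=t)
        r = 35.0 * np.sqrt(2 * np.log(1 / t))
        disk = np.pi * r**2
        assert cm.eta == pytest.approx(disk / 1e6, rel=0.05)
        assert cm.rho_um2 == pytest.approx(1.0 / (disk / 1e6), rel=0.05)

    def test_threshold_above_max_flags_undefined(self):
        df = make_localization_df([500.0], [500.0])
        cm = cl.ldv_analyze(df, (1000.0, 1000.0), threshold=4.0)
        assert cm.eta == 0.0
        assert cm.rho_um2 == 0.0
        assert not cm.rho_defined

    def test_reference_curve_values(self):
        assert cl.ldv_reference(100.0, 0.0) == pytest.approx(100.0)
        assert cl.ldv_reference(100.0, 1.0) == pytest.approx(240.0)
        assert cl.ldv_reference(100.0, 0.5) == pytest.approx(108.75)
        # alternative typographic reading preserves the eta -> 0 limit
        assert cl.ldv_reference(100.0, 0.0, divide=True) == pytest.approx(100.0)
        assert cl.ldv_reference(100.0, 1.0, divide=True) == pytest.approx(100.0 / 2.4)

    def test_eta_bounds_validated(self):
        with pytest.raises(ValueError):
            cl.ldv_reference(100.0, 1.5)

    def test_clustered_rho_exceeds_reference(self, clustered_map, csr_map):
        _, loc_c, _ = clustered_map
        _, loc_r, _ = csr_map
        roi = (3000.0, 3000.0)
        cm_c = cl.ldv_analyze(loc_c, roi)
        cm_r = cl.ldv_analyze(loc_r, roi)
        rho0 = cl.fit_ldv_rho0([cm_r.eta], [cm_r.rho_um2])
        assert cm_c.rho_um2 > cl.ldv_reference(rho0, cm_c.eta)


def brute_force_dbscan(xy, eps, minpts):
    """O(n^2) textbook DBSCAN used as an independent oracle."""
    n = len(xy)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    neigh = [np.nonzero(d[i] <= eps)[0] for i in range(n)]  # includes self
    core = np.array([len(neigh[i]) >= minpts for i in range(n)])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for q in neigh[j]:
                if labels[q] == -1:
                    labels[q] = cid
                    stack.append(q)
        cid += 1
    return labels


class TestDBSCAN:
    def test_tight_cluster_all_assigned(self, rng):
        xy = rng.uniform(0, 20.0, (10, 2))
        res = cl.dbscan_summary(xy, epsilon_nm=50.0, minpts=5)
        assert res.n_clusters == 1
        assert res.pct_in_clusters == 100.0
        assert res.molecules_per_cluster == 10.0

    def test_all_isolated_is_noise(self):
        xy = np.column_stack([np.arange(10) * 500.0, np.zeros(10)])
        res = cl.dbscan_summary(xy, epsilon_nm=50.0, minpts=5)
        assert res.n_clusters == 0
        assert np.all(res.labels == -1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        """Summary statistics agree exactly with an O(n^2) DBSCAN for n <= 200."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 201))
        # mixture of CSR and a few tight blobs to exercise both regimes
        xy = rng.uniform(0, 2000.0, (n, 2))
        blob = rng.uniform(200, 1800, (3, 2))
        xy[: n // 3] = blob[rng.integers(0, 3, n // 3)] + rng.normal(0, 15.0, (n // 3, 2))
        eps, minpts = 60.0, 5
        res = cl.dbscan_summary(xy, eps, minpts)
        oracle = brute_force_dbscan(xy, eps, minpts)
        assert set(np.nonzero(res.labels == -1)[0]) == set(np.nonzero(oracle == -1)[0])
        assert res.n_clusters == oracle.max() + 1
        assert res.pct_in_clusters == pytest.approx(100.0 * (oracle >= 0).mean())

    def test_epsilon_calibration_on_csr(self):
        """After epsilon calibration, CSR data itself shows ~1% clustered."""
        pat = synth.gen_point_pattern(100.0, (3000.0, 3000.0), seed=71)
        xy = np.column_stack([pat.x, pat.y])
        eps = cl.select_epsilon(xy, (3000.0, 3000.0), seed=72)
        res = cl.dbscan_summary(xy, eps)
        assert res.pct_in_clusters <= 3.0

    def test_minpts_default_is_five(self):
        import inspect

        assert inspect.signature(cl.select_epsilon).parameters["minpts"].default == 5
        assert inspect.signature(cl.dbscan_summary).parameters["minpts"].default == 5


class TestDetectability:
    def test_zero_fraction_not_resolvable(self):
        specs = [synth.ClusterSpec(60.0, 0.0, 10.0)]
        out = cl.detectability_map(specs, n_sims=4, seed=81)
        assert out[0].verdict == "Not resolvable"

    def test_extreme_regime_resolvable(self):
        specs = [synth.ClusterSpec(100.0, 1.0, 20.0)]
        out = cl.detectability_map(specs, n_sims=8, seed=82)
        assert out[0].verdict == "Resolvable"

    def test_verdict_monotone_in_fraction(self):
        rank = {"Not resolvable": 0, "Borderline": 1, "Resolvable": 2}
        specs = [synth.ClusterSpec(100.0, f, 10.0) for f in (0.0, 0.5, 1.0)]
        out = cl.detectability_map(specs, n_sims=8, seed=83)
        ranks = [rank[e.verdict] for e in out]
        assert ranks == sorted(ranks)
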