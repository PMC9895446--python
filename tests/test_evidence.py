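"""Voxel-wise evidence: splits, cvLME vs quadrature, LBF maps, clusters, ROI."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp

from langexp.evidence import (
    GroupDataset,
    LBFMap,
    VolumeGrid,
    count_preferring_voxels,
    cvlme_map,
    cvlme_voxel,
    lbf_map,
    partial_correlation,
    residualize,
    roi_percent_signal_change,
    split_half,
    threshold_clusters,
)


def quadrature_logpred(x1, y1, x2, y2, n_beta=2001, n_ltau=801, span=50.0):
    """Independent numeric integration of the held-out marginal likelihood.

    Integrates the held-out Gaussian likelihood against the trained
    normal-gamma posterior over (slope, log-precision) on a dense grid —
    the same model, a different route to the number.  The slope grid must
    be wide (many nominal SDs) because at these tiny fold sizes the
    posterior's small-precision region spreads the slope far out.
    """
    n1 = len(y1)
    G = float(np.dot(x1, x1))
    bhat = float(np.dot(x1, y1)) / G
    rss = float(((y1 - x1 * bhat) ** 2).sum())
    a, b = n1 / 2.0, rss / 2.0
    ltau = np.linspace(np.log(a / b) - 12, np.log(a / b) + 9, n_ltau)
    taus = np.exp(ltau)
    sd_b = 1.0 / np.sqrt(G * a / b)
    betas = np.linspace(bhat - span * sd_b, bhat + span * sd_b, n_beta)
    db, dl = betas[1] - betas[0], ltau[1] - ltau[0]
    B, T = np.meshgrid(betas, taus, indexing="ij")
    log_post = (
        a * np.log(b) - gammaln(a) + a * np.log(T) - b * T
        + 0.5 * (np.log(G * T) - np.log(2 * np.pi))
        - 0.5 * G * T * (B - bhat) ** 2
    )
    n2 = len(y2)
    resid2 = y2[None, None, :] - x2[None, None, :] * B[:, :, None]
    log_lik = (n2 / 2.0) * np.log(T / (2 * np.pi)) - 0.5 * T * (
        resid2**2
    ).sum(axis=2)
    return logsumexp(log_post + log_lik) + np.log(db * dl)


def make_grid(dims=(4, 4, 2)):
    return VolumeGrid(dims=dims, mask=np.ones(dims, dtype=bool))


def make_dataset(n=16, n_vox=32, seed=0, k_extra=1):
    rng = np.random.default_rng(seed)
    grid = VolumeGrid(dims=(n_vox, 1, 1), mask=np.ones((n_vox, 1, 1), bool))
    design = pd.DataFrame(
        {f"r{i}": rng.normal(size=n) for i in range(k_extra)}
    )
    contrast = rng.normal(size=(n, n_vox))
    return GroupDataset(
        subjects=[f"s{i}" for i in range(n)],
        grid=grid,
        contrast=contrast,
        design=design,
    )


class TestSplitHalf:
    def test_deterministic_given_seed(self):
        assert all(
            np.array_equal(a, b)
            for a, b in zip(split_half(10, seed=4), split_half(10, seed=4))
        )

    def test_default_seed_is_n(self):
        assert all(
            np.array_equal(a, b)
            for a, b in zip(split_half(10), split_half(10, seed=10))
        )

    def test_even_and_odd_sizes(self):
        a, b = split_half(10)
        assert len(a) == len(b) == 5
        a, b = split_half(9)
        assert (len(a), len(b)) == (5, 4)  # first part gets the extra subject
        assert sorted(np.concatenate([a, b]).tolist()) == list(range(9))

    def test_disjoint_and_exhaustive(self):
        a, b = split_half(17, seed=3)
        assert set(a) & set(b) == set()
        assert set(a) | set(b) == set(range(17))

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_half(3)


class TestCvlme:
    def test_identical_designs_identical_evidence(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        s = split_half(12)
        assert cvlme_voxel(y, X, s) == cvlme_voxel(y, X.copy(), s)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.0, 1.0, 8)
        y = 0.8 * x + rng.normal(0, 0.7, 8)
        i1, i2 = split_half(8)
        closed = cvlme_voxel(y, x.reshape(-1, 1), (i1, i2))
        orac = quadrature_logpred(x[i1], y[i1], x[i2], y[i2]) + (
            quadrature_logpred(x[i2], y[i2], x[i1], y[i1])
        )
        assert closed == pytest.approx(orac, abs=1e-3)

    def test_occam_noise_regressor_lowers_mean_evidence(self):
        rng = np.random.default_rng(7)
        n, n_vox = 24, 100
        x = rng.normal(size=n)
        noise_reg = rng.normal(size=n)
        Y = 0.8 * x[:, None] + rng.normal(size=(n, n_vox))
        s = split_half(n)
        X_true = np.column_stack([np.ones(n), x])
        X_over = np.column_stack([X_true, noise_reg])
        lme_true = [cvlme_voxel(Y[:, v], X_true, s) for v in range(n_vox)]
        lme_over = [cvlme_voxel(Y[:, v], X_over, s) for v in range(n_vox)]
        assert np.mean(lme_over) < np.mean(lme_true)

    def test_rank_deficiency_in_a_part_raises(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(8), np.zeros(8)])
        with pytest.raises(ValueError):
            cvlme_voxel(rng.normal(size=8), X, split_half(8))

    def test_map_single_voxel_equals_scalar_path(self):
        ds = make_dataset(n=16, n_vox=1, seed=5)
        s = split_half(16)
        emap = cvlme_map(ds, ["r0"], splits=s)
        X = np.column_stack([np.ones(16), ds.design["r0"].to_numpy()])
        assert emap.values[0] == pytest.approx(
            cvlme_voxel(ds.contrast[:, 0], X, s), abs=1e-10
        )

    def test_identical_specs_identical_maps(self):
        ds = make_dataset(seed=6)
        a = cvlme_map(ds, ["r0"])
        b = cvlme_map(ds, ["r0"])
        assert np.array_equal(a.values, b.values)


class TestLbfMaps:
    def test_self_comparison_is_zero(self):
        ds = make_dataset(seed=8)
        a = cvlme_map(ds, ["r0"])
        m = lbf_map(a, a)
        assert np.all(m.values == 0)

    def test_antisymmetry(self):
        ds = make_dataset(seed=9, k_extra=2)
        a = cvlme_map(ds, ["r0"])
        b = cvlme_map(ds, ["r0", "r1"])
        assert np.array_equal(lbf_map(a, b).values, -lbf_map(b, a).values)

    def test_grid_mismatch_raises(self):
        a = cvlme_map(make_dataset(n_vox=8, seed=1), ["r0"])
        b = cvlme_map(make_dataset(n_vox=9, seed=1), ["r0"])
        with pytest.raises(ValueError):
            lbf_map(a, b)

    def test_count_preferring_voxels(self):
        grid = make_grid((10, 1, 1))
        vals = np.zeros(10)
        m = LBFMap("a", "b", grid, vals)
        assert count_preferring_voxels(m, 1.5) == 0
        vals = np.array([4.0] * 7 + [0.0] * 3)
        m = LBFMap("a", "b", grid, vals)
        assert count_preferring_voxels(m, 3.0) == 7
        assert count_preferring_voxels(m, 3.0) <= count_preferring_voxels(m, 1.5)


class TestClusters:
    def _map_from_volume(self, vol):
        grid = VolumeGrid(dims=vol.shape, mask=np.ones(vol.shape, bool))
        return LBFMap("a", "b", grid, vol[grid.mask])

    def test_single_blob(self):
        vol = np.zeros((8, 8, 4))
        vol[2:5, 2:4, 1:3] = 5.0  # 3*2*2 = 12 voxels
        table = threshold_clusters(self._map_from_volume(vol), 3.0)
        assert len(table) == 1
        assert table.rows.iloc[0]["size"] == 12

    def test_min_size_drops_small_blob(self):
        vol = np.zeros((12, 8, 4))
        vol[0:3, 0:2, 0:2] = 5.0  # 12 voxels
        vol[8:10, 4:6, 1:3] = 5.0  # 8 voxels
        table = threshold_clusters(self._map_from_volume(vol), 3.0, min_size=10)
        assert len(table) == 1
        assert table.rows.iloc[0]["size"] == 12

    def test_connectivity_convention(self):
        vol = np.zeros((4, 4, 2))
        vol[0, 0, 0] = 4.0
        vol[1, 1, 0] = 4.0  # diagonal neighbor
        m = self._map_from_volume(vol)
        t26 = threshold_clusters(m, 3.0, min_size=1, connectivity=26)
        t6 = threshold_clusters(m, 3.0, min_size=1, connectivity=6)
        assert len(t26) == 1
        assert len(t6) == 2

    def test_sorted_by_size_with_peaks(self):
        vol = np.zeros((16, 8, 4))
        vol[0:2, 0:2, 0:2] = 4.0  # 8 voxels
        vol[8:12, 2:5, 1:3] = 3.5
        vol[9, 3, 1] = 9.0  # peak of the 24-voxel blob
        table = threshold_clusters(self._map_from_volume(vol), 3.0, min_size=1)
        assert list(table.rows["size"]) == sorted(
            table.rows["size"], reverse=True
        )
        assert table.rows.iloc[0]["peak_lbf"] == pytest.approx(9.0)
        assert tuple(table.rows.iloc[0][["peak_x", "peak_y", "peak_z"]]) == (
            9, 3, 1,
        )

    def test_supra_at_3_subset_of_supra_at_1p5(self):
        rng = np.random.default_rng(11)
        vol = rng.normal(0, 2, size=(10, 10, 4))
        m = self._map_from_volume(vol)
        assert count_preferring_voxels(m, 3.0) <= count_preferring_voxels(m, 1.5)
        hi = set(map(tuple, np.argwhere(vol > 3.0)))
        lo = set(map(tuple, np.argwhere(vol > 1.5)))
        assert hi <= lo


class TestRoiFollowups:
    def test_psc_constant_fraction(self):
        grid = make_grid((4, 4, 2))
        base = np.full((5, grid.n_voxels), 200.0)
        contrast = np.full((5, grid.n_voxels), 2.0)
        roi = np.zeros(grid.dims, bool)
        roi[0:2, 0:2, 0] = True
        psc = roi_percent_signal_change(contrast, base, grid, roi)
        assert psc == pytest.approx(np.ones(5))
        assert roi_percent_signal_change(
            np.zeros_like(contrast), base, grid, roi
        ) == pytest.approx(np.zeros(5))

    def test_psc_recovers_coupling_slope(self):
        rng = np.random.default_rng(12)
        grid = make_grid((6, 6, 2))
        n = 40
        index = rng.normal(size=n)
        roi = np.zeros(grid.dims, bool)
        roi[1:4, 1:4, 0] = True
        base = np.full((n, grid.n_voxels), 100.0)
        contrast = rng.normal(0, 0.1, size=(n, grid.n_voxels))
        contrast[:, roi[grid.mask]] += 3.0 * index[:, None]
        psc = roi_percent_signal_change(contrast, base, grid, roi)
        slope = np.polyfit(index, psc, 1)[0]
        assert slope == pytest.approx(3.0, abs=0.2)

    def test_residualize_properties(self):
        rng = np.random.default_rng(13)
        Z = rng.normal(size=(50, 2))
        y_orth = rng.normal(size=50)
        y_orth = residualize(y_orth, Z)  # make it exactly orthogonal
        assert residualize(y_orth, Z) == pytest.approx(y_orth, abs=1e-10)
        assert residualize(Z[:, 0], Z) == pytest.approx(np.zeros(50), abs=1e-10)
        resid = residualize(rng.normal(size=50) + Z @ [1.0, -2.0], Z)
        for j in range(2):
            assert abs(np.corrcoef(resid, Z[:, j])[0, 1]) < 1e-10

    def test_partial_correlation_basics(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(0, 0.5, 60)
        assert partial_correlation(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1]
        )
        Z = rng.normal(size=(60, 2))
        assert partial_correlation(x, x + Z @ [0.0, 0.0], Z) == pytest.approx(
            1.0, abs=1e-10
        )

    def test_partial_correlation_null_calibration(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            Z = rng.normal(size=(200, 2))
            x = Z @ [1.0, 0.5] + rng.normal(size=200)
            y = Z @ [-0.5, 1.0] + rng.normal(size=200)
            hits += abs(partial_correlation(x, y, Z)) < 0.2
        assert hits >= 90
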