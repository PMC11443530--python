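import math

import numpy as np
import pandas as pd
import pytest

from oracles import triangle_scan_oracle
from sparkquant.core import ImageStack
from sparkquant.segment3d import (
    CellExpression,
    expression_vs_morphology,
    segment_stack,
    sphericity,
    triangle_threshold,
    triangle_threshold_index,
)
from sparkquant.synthetic import Droplet3D, NoiseConfig, SceneConfig, render_zstack


def _ball_mask(r, shape=None, dims=(1.0, 1.0, 1.0)):
    n = int(math.ceil(r)) + 2
    shape = shape or (2 * n + 1,) * 3
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    c = [(s - 1) / 2 for s in shape]
    return (
        ((zz - c[0]) * dims[0]) ** 2
        + ((yy - c[1]) * dims[1]) ** 2
        + ((xx - c[2]) * dims[2]) ** 2
    ) <= r**2


class TestTriangle:
    def test_delta_peak_with_uniform_tail_matches_scan(self):
        counts = np.zeros(201)
        counts[10] = 1000
        counts[11:201] = 5
        assert triangle_threshold_index(counts) == triangle_scan_oracle(counts)

    def test_random_histograms_match_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(250):
            counts = rng.integers(0, 100, 64)
            if (counts > 0).sum() < 2:
                continue
            assert triangle_threshold_index(counts) == triangle_scan_oracle(counts)

    def test_threshold_within_histogram_range(self, rng):
        counts = rng.integers(0, 50, 32)
        counts[10] += 60
        idx = triangle_threshold_index(counts)
        nz = np.nonzero(counts)[0]
        assert nz[0] <= idx <= nz[-1]

    def test_shift_equivariance_via_bin_values(self):
        counts = np.zeros(50)
        counts[5] = 100
        counts[6:40] = 3
        t0 = triangle_threshold(counts, np.arange(50))
        t1 = triangle_threshold(counts, np.arange(50) + 17)
        assert t1 == t0 + 17

    def test_single_occupied_bin_rejected(self):
        counts = np.zeros(10)
        counts[4] = 99
        with pytest.raises(ValueError):
            triangle_threshold_index(counts)


class TestSphericity:
    def test_rasterized_ball_is_nearly_spherical(self):
        assert sphericity(_ball_mask(10), (1.0, 1.0, 1.0)) >= 0.95

    def test_thin_rod_is_far_from_spherical(self):
        rod = np.ones((1, 1, 20), dtype=bool)
        assert sphericity(rod, (1.0, 1.0, 1.0)) < 0.5

    def test_scale_invariance(self):
        ball = _ball_mask(6)
        a = sphericity(ball, (1.0, 1.0, 1.0))
        b = sphericity(ball, (2.0, 2.0, 2.0))
        assert a == pytest.approx(b, abs=1e-6)

    def test_empty_and_non3d_rejected(self):
        with pytest.raises(ValueError):
            sphericity(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            sphericity(np.ones((3, 3), bool), (1, 1, 1))


def _zstack_scene(n_z=24, seed=0, noise=None):
    return SceneConfig(
        image_shape=(64, 64),
        n_z=n_z,
        pixel_size_um=0.2,
        z_step_um=0.3,
        rng_seed=seed,
        noise=noise or NoiseConfig(poisson_gain=5.0, read_sigma=0.5, offset=10.0),
    )


class TestSegmentStack:
    def test_recovers_five_separated_spheres(self):
        scene = _zstack_scene()
        mid_z = scene.n_z * scene.z_step_um / 2
        droplets = [
            Droplet3D(mid_z, 4.0, 4.0, 1.5),
            Droplet3D(mid_z, 4.0, 9.0, 1.5),
            Droplet3D(mid_z, 9.0, 4.0, 1.5),
            Droplet3D(mid_z, 9.0, 9.0, 1.5),
            Droplet3D(mid_z, 6.5, 6.5, 1.5),
        ]
        stack = render_zstack(droplets, scene)
        result = segment_stack(stack, rolling_radius_px=12)
        assert len(result.clusters) == 5

    def test_zero_droplets_zero_clusters(self):
        scene = SceneConfig(
            image_shape=(64, 64),
            n_z=16,
            cells=[],
            expression_levels=[],
            noise=NoiseConfig(poisson_gain=0, read_sigma=0, offset=5.0),
        )
        stack = render_zstack([], scene)
        result = segment_stack(stack, rolling_radius_px=12)
        assert result.clusters == []

    def test_sphere_volume_matches_isophote_oracle(self):
        """A d=2 µm sphere segments to the volume enclosed by the
        threshold isophote of its PSF-softened edge: the closed-form
        erfc-profile prediction from the realized Triangle threshold
        agrees with the measured volume within 20%. The low Triangle
        threshold makes the measured volume a generous (upper) estimate
        of the nominal sphere volume."""
        from scipy.special import erfinv

        scene = _zstack_scene(
            noise=NoiseConfig(poisson_gain=20.0, read_sigma=0.2, offset=5.0)
        )
        d = 2.0
        mid_z = scene.n_z * scene.z_step_um / 2
        stack = render_zstack([Droplet3D(mid_z, 6.4, 6.4, d)], scene)
        result = segment_stack(stack, rolling_radius_px=12)
        assert len(result.clusters) == 1
        # isophote level on the linear intensity scale (chain squares
        # intensities before the 8-bit rescale)
        t_lin = math.sqrt((result.threshold + 0.5) / 255.0)
        delta = math.sqrt(2.0) * scene.psf_sigma_um * erfinv(1.0 - 2.0 * t_lin)
        expected = 4.0 / 3.0 * math.pi * (d / 2.0 + delta) ** 3
        measured = result.clusters[0].volume_um3
        assert measured == pytest.approx(expected, rel=0.2)
        assert measured >= math.pi / 6 * d**3  # generous by construction

    def test_volume_conservation(self):
        scene = _zstack_scene(seed=3)
        mid_z = scene.n_z * scene.z_step_um / 2
        stack = render_zstack(
            [Droplet3D(mid_z, 4.0, 4.0, 1.2), Droplet3D(mid_z, 9.0, 9.0, 2.0)], scene
        )
        result = segment_stack(stack, rolling_radius_px=12)
        total_vox = sum(c.n_voxels for c in result.clusters)
        assert total_vox == int(result.foreground.sum())
        assert sum(c.volume_um3 for c in result.clusters) == pytest.approx(
            result.foreground.sum() * result.voxel_volume_um3
        )

    def test_rotation_equivariance_on_isotropic_stack(self):
        """90° rotation of an isotropic stack permutes clusters but keeps
        counts and volumes."""
        rng = np.random.default_rng(5)
        vol = np.zeros((32, 32, 32))
        zz, yy, xx = np.mgrid[0:32, 0:32, 0:32]
        for c in ((10, 10, 20), (22, 18, 8)):
            vol += 300 * np.exp(
                -((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) / (2 * 2.0**2)
            )
        vol += rng.normal(20, 1, vol.shape).clip(0)
        a = ImageStack(vol, "ZYX", 0.2, z_step_um=0.2)
        b = ImageStack(np.rot90(vol, axes=(1, 2)).copy(), "ZYX", 0.2, z_step_um=0.2)
        ra = segment_stack(a, rolling_radius_px=8)
        rb = segment_stack(b, rolling_radius_px=8)
        assert len(ra.clusters) == len(rb.clusters)
        assert sorted(c.n_voxels for c in ra.clusters) == sorted(
            c.n_voxels for c in rb.clusters
        )

    def test_missing_z_calibration_rejected(self):
        st = ImageStack(np.zeros((4, 8, 8)), "ZYX", 0.2, z_step_um=0.3)
        object.__setattr__(st, "z_step_um", None)
        with pytest.raises(ValueError):
            segment_stack(st)


class TestExpressionCorrelation:
    @staticmethod
    def _cells(expr, count, vol, sph):
        return [
            CellExpression(i, e, c, v, v / max(c, 1), s)
            for i, (e, c, v, s) in enumerate(zip(expr, count, vol, sph))
        ]

    def test_perfectly_monotone_gives_rho_one(self):
        n = 12
        expr = np.arange(1.0, n + 1)
        cells = self._cells(expr, np.arange(n) + 1, expr * 2, np.linspace(0.5, 0.9, n))
        df = expression_vs_morphology(cells, n_permutations=200, seed=0)
        assert df.loc[df.metric == "total_volume_um3", "rho"].item() == pytest.approx(1.0)
        assert df.loc[df.metric == "cluster_count", "rho"].item() == pytest.approx(1.0)

    def test_anti_monotone_gives_rho_minus_one(self):
        n = 10
        expr = np.arange(1.0, n + 1)
        cells = self._cells(expr, np.arange(n, 0, -1), expr[::-1], np.linspace(0.9, 0.5, n))
        df = expression_vs_morphology(cells, n_permutations=200, seed=0)
        assert df.loc[df.metric == "total_volume_um3", "rho"].item() == pytest.approx(-1.0)

    def test_independent_draws_rarely_look_correlated(self):
        """Under the null (independent expression and morphology, n=50),
        |rho| stays below 0.4 in at least 95% of seeds."""
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            expr = rng.random(50) * 100
            cells = self._cells(
                expr, rng.integers(0, 30, 50), rng.random(50) * 40, rng.random(50)
            )
            df = expression_vs_morphology(cells, n_permutations=10, seed=seed)
            if (df["rho"].abs() < 0.4).all():
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_constant_covariate_reported_undefined(self):
        cells = self._cells([1.0, 2.0, 3.0, 4.0], [5, 5, 5, 5], [1.0, 2.0, 1.5, 2.5], [0.8] * 4)
        df = expression_vs_morphology(cells, n_permutations=50, seed=0)
        row = df[df.metric == "cluster_count"].iloc[0]
        assert not row["defined"] and np.isnan(row["rho"])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            expression_vs_morphology(self._cells([1.0], [1], [1.0], [0.9]))

    def test_permutation_p_small_for_strong_monotone_signal(self):
        n = 20
        expr = np.arange(1.0, n + 1)
        cells = self._cells(expr, np.arange(n) + 1, expr * 3, np.linspace(0.5, 0.9, n))
        df = expression_vs_morphology(cells, n_permutations=2000, seed=1)
        assert df.loc[df.metric == "total_volume_um3", "p_value"].item() < 0.01
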