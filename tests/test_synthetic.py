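import math

import numpy as np
import pytest

from sparkquant.core import ImageStack
from sparkquant.synthetic import (
    ActivityProtocol,
    CellGeometry,
    Droplet,
    Droplet3D,
    DropletSchedule,
    NoiseConfig,
    SceneConfig,
    cell_mask,
    render_movie,
    render_zstack,
    simulate_droplet_kinetics,
)


def _noise_free(**kw):
    kw.setdefault("noise", NoiseConfig(poisson_gain=0.0, read_sigma=0.0, offset=0.0))
    return SceneConfig(**kw)


def _static_droplet(scene, n_frames, d=3.0, y=6.4, x=6.4):
    diam = np.full(n_frames, float(d))
    return DropletSchedule(
        droplets=[
            Droplet(
                id=0, cell_id=0, birth=0, persistent=True,
                diameter_um=diam, y_um=np.full(n_frames, y), x_um=np.full(n_frames, x),
            )
        ],
        n_frames=n_frames,
    )


class TestKinetics:
    def test_zero_activity_gives_empty_schedule(self):
        proto = ActivityProtocol(np.zeros(40), np.ones(40))
        sched = simulate_droplet_kinetics(proto, SceneConfig(rng_seed=0))
        assert sched.droplets == []

    def test_instant_dissolution_limit_disperses_everything(self):
        """Huge dissolution hazard, no persistent droplets: washout kills
        every droplet, so the realized dispersion fraction is 100%."""
        a = np.concatenate([np.ones(30), np.zeros(30)])
        proto = ActivityProtocol(a, np.ones(60))
        sched = simulate_droplet_kinetics(
            proto,
            SceneConfig(rng_seed=1),
            dissolve_rate_per_min=1e6,
            persistent_fraction=0.0,
        )
        counts = sched.counts_per_frame()
        assert counts[:30].max() > 0
        assert (counts[31:] == 0).all()

    def test_persistent_droplets_survive_washout(self):
        a = np.concatenate([np.ones(30), np.zeros(30)])
        proto = ActivityProtocol(a, np.ones(60))
        sched = simulate_droplet_kinetics(
            proto,
            SceneConfig(rng_seed=2),
            dissolve_rate_per_min=1e6,
            persistent_fraction=1.0,
        )
        counts = sched.counts_per_frame()
        assert counts[-1] == counts[29]

    def test_nucleation_count_matches_direct_poisson_oracle(self):
        """Sustained activity, rate 2/min for 10 min: total nucleation is
        Poisson with mean 20. Compare the simulator's mean over seeds
        against an independent per-frame Poisson accumulation."""
        n_frames, rate = 120, 2.0  # 5 s frames -> 10 min
        proto = ActivityProtocol(np.ones(n_frames), np.ones(n_frames))
        n_seeds = 60
        sim_totals = []
        for seed in range(n_seeds):
            sched = simulate_droplet_kinetics(
                proto,
                SceneConfig(rng_seed=seed),
                nucleation_rate_per_min=rate,
                growth_rate_um_per_min=0.0,
                coalesce=False,
                exclusion_margin_um=0.0,
            )
            sim_totals.append(len(sched.droplets))
        oracle_rng = np.random.default_rng(999)
        dt_min = 5.0 / 60.0
        oracle_totals = [
            oracle_rng.poisson(rate * dt_min, n_frames).sum() for _ in range(n_seeds)
        ]
        mean = 20.0
        se3 = 3 * math.sqrt(mean / n_seeds)
        assert abs(np.mean(sim_totals) - mean) < se3
        assert abs(np.mean(sim_totals) - np.mean(oracle_totals)) < math.sqrt(2) * se3

    def test_growth_is_monotone_during_activity(self):
        proto = ActivityProtocol(np.ones(30), np.ones(30))
        sched = simulate_droplet_kinetics(
            proto, SceneConfig(rng_seed=3), growth_rate_um_per_min=0.5, coalesce=False
        )
        for d in sched.droplets:
            alive = d.diameter_um[~np.isnan(d.diameter_um)]
            assert (np.diff(alive) >= 0).all()

    def test_centers_inside_parent_cell(self):
        scene = SceneConfig(rng_seed=4)
        proto = ActivityProtocol(np.ones(40), np.ones(40))
        sched = simulate_droplet_kinetics(proto, scene)
        mask = cell_mask(scene, 0)
        px = scene.pixel_size_um
        for d in sched.droplets:
            t = d.birth
            assert mask[int(d.y_um[t] / px), int(d.x_um[t] / px)]

    def test_coalescence_conserves_volume(self):
        """Densely nucleated, fast-growing droplets merge; each merged
        diameter is the volume-conserving combination of the post-growth
        diameters of host and partner."""
        n = 6
        proto = ActivityProtocol(np.ones(n), np.ones(n))
        scene = SceneConfig(rng_seed=5)
        g_per_frame = 3.0 * scene.frame_interval_s / 60.0
        sched = simulate_droplet_kinetics(
            proto,
            scene,
            nucleation_rate_per_min=200.0,
            growth_rate_um_per_min=3.0,
            initial_diameter_um=0.8,
            exclusion_margin_um=0.0,
            persistent_fraction=1.0,  # isolate coalescence from dissolution
        )
        merges = [d for d in sched.droplets if d.merged_into is not None]
        assert merges, "expected coalescence at this density and growth"
        by_id = {d.id: d for d in sched.droplets}
        checked = 0
        for host in sched.droplets:
            for t in range(1, n):
                if not host.alive_at(t) or not host.alive_at(t - 1):
                    continue
                partners = [
                    p
                    for p in merges
                    if p.merged_into == host.id and p.death == t and p.birth < t
                ]
                if not partners:
                    continue
                # skip chained merges (a partner that itself absorbed a
                # droplet this frame): its t-1 diameter underestimates it
                if any(
                    q.merged_into == p.id and q.death == t
                    for p in partners
                    for q in merges
                ):
                    continue
                expected = (host.diameter_um[t - 1] + g_per_frame) ** 3 + sum(
                    (p.diameter_um[t - 1] + g_per_frame) ** 3 for p in partners
                )
                assert host.diameter_um[t] ** 3 == pytest.approx(expected, rel=1e-9)
                checked += 1
        assert checked > 0

    def test_increasing_nucleation_rate_never_reduces_mean_count(self):
        proto = ActivityProtocol(np.ones(40), np.ones(40))
        means = []
        for rate in (1.0, 4.0):
            totals = [
                len(
                    simulate_droplet_kinetics(
                        proto,
                        SceneConfig(rng_seed=s),
                        nucleation_rate_per_min=rate,
                        coalesce=False,
                        exclusion_margin_um=0.0,
                    ).droplets
                )
                for s in range(10)
            ]
            means.append(np.mean(totals))
        assert means[1] >= means[0]

    def test_unplaceable_droplets_rejected(self):
        scene = SceneConfig(
            cells=[CellGeometry(center_um=(6.4, 6.4), radii_um=(0.01, 0.01))],
        )
        proto = ActivityProtocol(np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            simulate_droplet_kinetics(proto, scene)


class TestRenderMovie:
    def test_empty_schedule_constant_frames(self):
        scene = _noise_free(rng_seed=0)
        scene = scene.model_copy(
            update={"noise": NoiseConfig(poisson_gain=0, read_sigma=0, offset=12.0)}
        )
        proto = ActivityProtocol(np.zeros(4), np.ones(4))
        render = render_movie(DropletSchedule([], 4), proto, scene)
        data = render.stack.data
        assert np.allclose(data[0], data[1]) and np.allclose(data[0], data[3])
        mask = cell_mask(scene, 0)
        assert np.allclose(data[0][mask], 12.0 + scene.expression_levels[0])
        assert np.allclose(data[0][~mask], 12.0)

    def test_gcamp_doubling_doubles_cell_intensity(self):
        scene = _noise_free(rng_seed=0)
        c = np.ones(4)
        c[2:] = 2.0
        proto = ActivityProtocol(np.zeros(4), c)
        render = render_movie(DropletSchedule([], 4), proto, scene, gcamp_mode=True)
        mask = cell_mask(scene, 0)
        m1 = render.stack.data[1][mask].mean()
        m2 = render.stack.data[2][mask].mean()
        assert m2 == pytest.approx(2 * m1, rel=1e-9)

    def test_flux_conservation_before_noise(self):
        """Total reporter photons per cell are constant even as droplets
        drain the diffuse pool."""
        scene = _noise_free(rng_seed=6)
        proto = ActivityProtocol.step(30, 2, 25)
        sched = simulate_droplet_kinetics(proto, scene, nucleation_rate_per_min=8.0)
        render = render_movie(sched, proto, scene)
        budget = scene.expression_levels[0] * cell_mask(scene, 0).sum()
        totals = render.stack.data.sum(axis=(1, 2))
        assert np.allclose(totals, budget, rtol=1e-12)

    def test_blob_integral_matches_closed_form(self):
        """One 3 µm droplet: its rendered integrated brightness equals the
        enrichment x volume closed form within 1%."""
        scene = _noise_free(rng_seed=0)
        sched = _static_droplet(scene, 2, d=3.0)
        proto = ActivityProtocol(np.zeros(2), np.ones(2))
        render = render_movie(sched, proto, scene)
        E = scene.expression_levels[0]
        area = cell_mask(scene, 0).sum()
        expected_b = (
            E
            * scene.enrichment
            * (math.pi / 6 * 3.0**3)
            / (scene.pixel_size_um**2 * scene.section_depth_um)
        )
        expected_b = min(expected_b, 0.9 * E * area)  # pool rationing cap
        diffuse = (E * area - expected_b) / area
        measured = render.stack.data[0].sum() - diffuse * area
        assert measured == pytest.approx(expected_b, rel=0.01)

    def test_bit_identical_given_same_seed(self, step_protocol, scene):
        sched = simulate_droplet_kinetics(step_protocol, scene)
        a = render_movie(sched, step_protocol, scene, gcamp_mode=True)
        b = render_movie(sched, step_protocol, scene, gcamp_mode=True)
        assert np.array_equal(a.stack.data, b.stack.data)
        sched2 = simulate_droplet_kinetics(step_protocol, scene)
        assert len(sched.droplets) == len(sched2.droplets)
        assert np.array_equal(sched.counts_per_frame(), sched2.counts_per_frame())

    def test_droplet_outside_image_rejected(self):
        scene = _noise_free(rng_seed=0)
        sched = _static_droplet(scene, 1, d=1.0, y=-5.0, x=-5.0)
        proto = ActivityProtocol(np.zeros(1), np.ones(1))
        with pytest.raises(ValueError):
            render_movie(sched, proto, scene)

    def test_schedule_protocol_length_mismatch_rejected(self, scene):
        proto = ActivityProtocol(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            render_movie(DropletSchedule([], 5), proto, scene)


class TestRenderZstack:
    def test_single_droplet_peaks_at_center_slice(self):
        scene = _noise_free(rng_seed=0, n_z=15)
        mid_z = scene.n_z * scene.z_step_um / 2
        stack = render_zstack([Droplet3D(mid_z, 6.4, 6.4, 1.5)], scene)
        profile = stack.data.max(axis=(1, 2))
        assert int(np.argmax(profile)) == scene.n_z // 2

    def test_requires_multiple_slices(self):
        with pytest.raises(ValueError):
            render_zstack([], _noise_free(rng_seed=0, n_z=1))

    def test_calibration_attached(self):
        scene = _noise_free(rng_seed=0, n_z=8)
        stack = render_zstack([], scene)
        assert stack.axes == "ZYX"
        assert stack.z_step_um == scene.z_step_um
        assert stack.pixel_size_um == scene.pixel_size_um
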