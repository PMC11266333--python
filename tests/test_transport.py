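import numpy as np
import pytest
from scipy import integrate

from petbench.digitiser import DigitiserConfig
from petbench.geometry import ScannerConfig, build_scanner
from petbench.materials import get_material
from petbench.phantoms import PhantomModel, Primitive, make_scatter_phantom
from petbench.transport import (SPEED_OF_LIGHT_MM_NS, EmissionBatch, SimConfig,
                                detect_hits, intersect_detector, run_acquisition,
                                sample_decays, transport_photons)
from petbench.transport import _sample_klein_nishina


def point_source(activity_bq: float, pos=(0.0, 0.0, 0.0)) -> PhantomModel:
    r = 0.01
    conc = activity_bq / (4 / 3 * np.pi * r**3 / 1000.0)
    return PhantomModel([Primitive("sphere", pos, get_material("vacuum"),
                                   activity_bq_ml=conc, radius=r)])


class TestSampleDecays:
    def test_zero_duration(self, rng):
        batch = sample_decays(point_source(1e6), SimConfig(), 0.0, rng)
        assert len(batch) == 0 and batch.n_decays == 0

    def test_decay_count_matches_closed_form(self):
        cfg = SimConfig(beta_plus_fraction=1.0)
        lam = cfg.decay_constant
        a0, t = 2e4, 60.0
        expected = a0 * (1 - np.exp(-lam * t)) / lam
        counts = [sample_decays(point_source(a0), cfg, t,
                                np.random.default_rng(s)).n_decays
                  for s in range(5)]
        pooled_sigma = np.sqrt(expected / 5)
        assert abs(np.mean(counts) - expected) < 3 * pooled_sigma

    def test_decay_times_follow_the_decay_curve(self, rng):
        cfg = SimConfig(half_life_s=10.0, beta_plus_fraction=1.0)
        batch = sample_decays(point_source(1e5), cfg, 30.0, rng)
        lam = cfg.decay_constant
        # median of the truncated exponential
        cdf_total = 1 - np.exp(-lam * 30.0)
        median = -np.log(1 - 0.5 * cdf_total) / lam
        observed = np.median(batch.time_s)
        assert abs(observed - median) < 0.5

    def test_directions_are_unit_and_isotropic(self, rng):
        batch = sample_decays(point_source(1e5), SimConfig(), 1.0, rng)
        norms = np.linalg.norm(batch.direction, axis=1)
        assert np.allclose(norms, 1.0)
        assert abs(batch.direction[:, 2].mean()) < 0.02


class TestTransport:
    def test_vacuum_photons_exit_unscattered(self, rng):
        ph = PhantomModel([Primitive("cylinder", (0, 0, 0), get_material("vacuum"),
                                     radius=100.0, length=200.0)])
        n = 1000
        out = transport_photons(np.zeros((n, 3)),
                                np.tile([1.0, 0, 0], (n, 1)), ph, rng)
        assert not out["scattered"].any() and not out["absorbed"].any()
        assert np.all(out["energy_kev"] == 511.0)

    def test_water_survival_against_ray_marching_oracle(self, rng):
        mu = get_material("water").mu_511_mm
        ph = PhantomModel([Primitive("cylinder", (0, 0, 0), get_material("water"),
                                     radius=60.0, length=100.0)])
        n = 100_000
        origins = np.tile([0.0, 0.0, -50.0], (n, 1))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
        out = transport_photons(origins, dirs, ph, rng)
        untouched = (~out["scattered"]) & (~out["absorbed"])
        # independent fine ray-marching line integral over the same path
        zs = np.linspace(-50.0, 50.0, 20001)
        inside = ph.primitives[0].contains(
            np.column_stack([np.zeros_like(zs), np.zeros_like(zs), zs]))
        depth = np.trapezoid(inside * mu, zs)
        expected = np.exp(-depth)
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(untouched.mean() - expected) < 3 * sigma

    def test_compton_energy_at_ninety_degrees(self):
        # E' = E / (1 + (E/511)(1 - cos theta)); at 90 deg and 511 keV: 255.5
        e = 511.0 / (1.0 + (511.0 / 511.0) * (1.0 - np.cos(np.pi / 2)))
        assert e == pytest.approx(255.5)

    def test_klein_nishina_sampler_matches_analytic_pdf(self, rng):
        ct = _sample_klein_nishina(np.full(200_000, 511.0), rng)

        def kn(c):
            r = 1.0 / (2.0 - c)  # E'/E at alpha = 1
            return r**2 * (r + 1.0 / r - (1.0 - c**2))

        norm = integrate.quad(kn, -1, 1)[0]
        edges = np.linspace(-1, 1, 21)
        hist, _ = np.histogram(ct, bins=edges, density=True)
        expected = np.array([integrate.quad(kn, a, b)[0] / norm / (b - a)
                             for a, b in zip(edges[:-1], edges[1:])])
        assert np.max(np.abs(hist - expected) / expected) < 0.05

    def test_scattered_energy_below_511(self, rng):
        ph = make_scatter_phantom(1e6)
        n = 20_000
        pts = ph.primitives[-1].contains  # just to assert phantom built
        origins = np.tile([0.0, -45.0, 0.0], (n, 1))
        v = rng.normal(size=(n, 3))
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
        out = transport_photons(origins, dirs, ph, rng)
        sc = out["scattered"] & ~out["absorbed"]
        assert sc.any()
        assert np.all(out["energy_kev"][sc] < 511.0)


class TestDetector:
    def test_axial_ray_misses_the_ring(self, geometry, rng):
        flat, _ = intersect_detector(np.zeros((1, 3)), np.array([[0.0, 0.0, 1.0]]),
                                     geometry, rng)
        assert flat[0] == -1

    def test_time_of_flight_differences(self, geometry):
        """Centred source -> equal arrival times; 100-mm offset along the
        LOR -> dt = 200 mm / c ~ 0.667 ns before any timing blur."""
        sim = SimConfig()
        rng = np.random.default_rng(0)
        for x0, expected_ns in ((0.0, 0.0), (100.0, 200.0 / SPEED_OF_LIGHT_MM_NS)):
            batch = EmissionBatch(
                n_decays=200, event_id=np.arange(200),
                time_s=np.zeros(200),
                position=np.tile([x0, 0.0, 0.0], (200, 1)),
                direction=np.tile([1.0, 0.0, 0.0], (200, 1)),
            )
            ph = PhantomModel([])  # vacuum
            hits = detect_hits(batch, ph, geometry, sim, rng)
            pairs = hits.groupby("event_id").filter(lambda g: len(g) == 2)
            dt = pairs.groupby("event_id")["time_ns"].agg(np.ptp)
            assert dt.mean() == pytest.approx(expected_ns, abs=1e-3)

    def test_capture_probability_against_closed_form(self, geometry):
        """Perpendicular rays through the 25-mm crystal depth are captured
        with probability 1 - exp(-mu_LYSO * 25)."""
        rng = np.random.default_rng(7)
        n = 40_000
        batch = EmissionBatch(
            n_decays=n, event_id=np.arange(n), time_s=np.zeros(n),
            position=np.zeros((n, 3)),
            direction=np.tile([1.0, 0.0, 0.0], (n, 1)),
        )
        hits = detect_hits(batch, PhantomModel([]), geometry, SimConfig(), rng)
        mu = get_material("lyso").mu_511_mm
        p = 1.0 - np.exp(-mu * 25.0)
        observed = len(hits) / (2 * n)  # every ray enters a crystal
        sigma = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(observed - p) < 3 * sigma

    def test_unscattered_acceptance_matches_solid_angle_quadrature(self, geometry):
        """Line-source geometric acceptance vs an independent quadrature of
        the ring solid angle (within 2%)."""
        rng = np.random.default_rng(11)
        c = geometry.config
        half_len = 50.0
        n = 200_000
        z0 = rng.uniform(-half_len, half_len, n)
        v = rng.normal(size=(n, 3))
        dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
        pos = np.column_stack([np.zeros(n), np.zeros(n), z0])
        flat, _ = intersect_detector(pos, dirs, geometry, rng)
        observed = (flat >= 0).mean()

        fill_t = (c.crystals_per_ring * c.crystal_transaxial_mm
                  / (2 * np.pi * c.ring_radius_mm))
        half_ax = geometry.axial_extent_mm / 2.0

        def hit_prob(z):
            def f(s):
                z_hit = z + c.ring_radius_mm * s / np.sqrt(1.0 - s * s)
                return 0.5 * (np.abs(z_hit) < half_ax)
            return integrate.quad(f, -0.999999, 0.999999, limit=200)[0]

        zs = np.linspace(-half_len, half_len, 41)
        expected = fill_t * np.mean([hit_prob(z) for z in zs])
        assert abs(observed - expected) / expected < 0.02


class TestRunAcquisition:
    def test_same_seed_is_bit_identical(self, geometry):
        ph = make_scatter_phantom(1e6)
        frames = [(0.0, 0.01)]
        a = run_acquisition(ph, geometry, SimConfig(), DigitiserConfig(),
                            frames, seed=5)
        b = run_acquisition(ph, geometry, SimConfig(), DigitiserConfig(),
                            frames, seed=5)
        assert a[0]["coincidences"].equals(b[0]["coincidences"])
        assert a[0]["singles"].equals(b[0]["singles"])

    def test_zero_activity_no_noise_is_empty(self, geometry):
        ph = make_scatter_phantom(0.0)
        res = run_acquisition(ph, geometry, SimConfig(),
                              DigitiserConfig(noise_rate_hz=0.0),
                              [(0.0, 0.001)], seed=1)
        assert len(res[0]["singles"]) == 0
        assert len(res[0]["coincidences"]) == 0

    def test_frame_activities_decay_with_half_life(self, geometry):
        ph = make_scatter_phantom(1e6)
        frames = [(0.0, 0.001), (6586.2, 0.001)]
        res = run_acquisition(ph, geometry, SimConfig(),
                              DigitiserConfig(noise_rate_hz=0.0), frames, seed=2)
        ratio = res[1]["avg_activity_bq"] / res[0]["avg_activity_bq"]
        assert ratio == pytest.approx(0.5, rel=1e-6)

    def test_overlapping_frames_rejected(self, geometry):
        ph = make_scatter_phantom(1e6)
        with pytest.raises(ValueError, match="non-overlapping"):
            run_acquisition(ph, geometry, SimConfig(), DigitiserConfig(),
                            [(0.0, 1.0), (0.5, 1.0)], seed=1)

    def test_truth_labels_survive_the_chain(self, geometry):
        ph = make_scatter_phantom(5e6)
        res = run_acquisition(ph, geometry, SimConfig(), DigitiserConfig(),
                              [(0.0, 0.005)], seed=3)
        hits = res[0]["hits"]
        co = res[0]["coincidences"]
        trues = co[co["kind"] == "true"]
        assert (trues["event_a"] == trues["event_b"]).all()
        scattered_events = set(hits.loc[hits["scattered"], "event_id"])
        assert not scattered_events & set(trues["event_a"])
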