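import numpy as np
import pandas as pd
import pytest

from petbench.errors import AnalysisError
from petbench.sinogram import (N_TOF_BINS, TOF_BIN_PS, Sinogram,
                               bin_coincidences, mash_tof, michelogram_planes,
                               rfs, ssrb)


def coincidence_frame(pairs, dt_ps=0.0):
    """pairs: list of (crystal_a, crystal_b)."""
    n = len(pairs)
    return pd.DataFrame({
        "crystal_a": [p[0] for p in pairs],
        "crystal_b": [p[1] for p in pairs],
        "time_a_ns": np.zeros(n), "time_b_ns": np.zeros(n),
        "dt_ps": np.full(n, dt_ps, dtype=float),
        "event_a": np.arange(n), "event_b": np.arange(n),
        "kind": ["true"] * n,
    })


def random_accepted_pairs(geometry, n, rng):
    out = []
    n_c = geometry.config.n_crystals
    while len(out) < n:
        a = int(rng.integers(0, n_c))
        b = int(rng.integers(0, n_c))
        if geometry.lor_accepted(a, b):
            out.append((a, b))
    return out


class TestBinning:
    def test_total_counts_conserved(self, small_geometry, rng):
        pairs = random_accepted_pairs(small_geometry, 500, rng)
        sino = bin_coincidences(coincidence_frame(pairs), small_geometry,
                                n_radial=61)
        assert sino.total + sino.n_discarded == 500

    def test_rejected_lor_counted_as_discarded(self, small_geometry):
        # same-sector pair violates the sector rule
        a = int(small_geometry.flat_from_ring_pos(0, 0))
        b = int(small_geometry.flat_from_ring_pos(0, 1))
        sino = bin_coincidences(coincidence_frame([(a, b)]), small_geometry,
                                n_radial=61)
        assert sino.total == 0 and sino.n_discarded == 1

    def test_diametral_lor_hits_central_radial_bin(self, geometry):
        a = int(geometry.flat_from_ring_pos(5, 0))
        b = int(geometry.flat_from_ring_pos(5, 272))
        sino = bin_coincidences(coincidence_frame([(a, b)]), geometry)
        radial, plane, view = np.nonzero(sino.counts)
        assert radial[0] == 207  # centre of the 415-bin radial axis

    def test_projection_count_is_half_the_ring(self, geometry, small_geometry):
        for g in (geometry, small_geometry):
            a = int(g.flat_from_ring_pos(0, 0))
            b = int(g.flat_from_ring_pos(0, g.config.crystals_per_ring // 2))
            sino = bin_coincidences(coincidence_frame([(a, b)]), g)
            assert sino.n_views == g.config.crystals_per_ring // 2

    def test_zero_dt_lands_in_central_tof_bin(self, geometry):
        a = int(geometry.flat_from_ring_pos(5, 0))
        b = int(geometry.flat_from_ring_pos(5, 272))
        sino = bin_coincidences(coincidence_frame([(a, b)], dt_ps=0.0),
                                geometry, tof=True, planes="ssrb")
        assert sino.counts.shape[-1] == N_TOF_BINS == 29
        tof_idx = np.nonzero(sino.counts)[-1]
        assert tof_idx[0] == 14

    def test_out_of_window_dt_discarded(self, geometry):
        a = int(geometry.flat_from_ring_pos(5, 0))
        b = int(geometry.flat_from_ring_pos(5, 272))
        sino = bin_coincidences(coincidence_frame([(a, b)], dt_ps=9000.0),
                                geometry, tof=True, planes="ssrb")
        assert sino.total == 0 and sino.n_discarded == 1

    def test_max_ring_difference_filter(self, small_geometry):
        a = int(small_geometry.flat_from_ring_pos(0, 0))
        b = int(small_geometry.flat_from_ring_pos(5, 16))
        sino = bin_coincidences(coincidence_frame([(a, b)]), small_geometry,
                                max_ring_difference=2)
        assert sino.total == 0 and sino.n_discarded == 1


class TestSSRB:
    def test_ring_pair_lands_in_sum_slice(self, geometry):
        a = int(geometry.flat_from_ring_pos(10, 0))
        b = int(geometry.flat_from_ring_pos(12, 272))
        sino3d = bin_coincidences(coincidence_frame([(a, b)]), geometry)
        sino2d = ssrb(sino3d)
        assert sino2d.counts.shape[1] == 71
        plane = np.nonzero(sino2d.counts)[1]
        assert plane[0] == 22  # slice index = ring_a + ring_b

    def test_counts_conserved_exactly(self, small_geometry, rng):
        pairs = random_accepted_pairs(small_geometry, 800, rng)
        sino3d = bin_coincidences(coincidence_frame(pairs), small_geometry,
                                  n_radial=61)
        assert ssrb(sino3d).total == sino3d.total

    def test_uniform_michelogram_gives_triangular_axial_profile(self, small_geometry):
        nr = small_geometry.config.n_rings
        ra, rb, _ = michelogram_planes(nr)
        sino3d = bin_coincidences(coincidence_frame([]), small_geometry, n_radial=61)
        sino3d.counts[30, :, 0] = 1  # one count in every plane
        profile = ssrb(sino3d).counts.sum(axis=(0, 2))
        # brute-force count of ring pairs per slice
        expected = np.zeros(2 * nr - 1, dtype=int)
        for r1 in range(nr):
            for r2 in range(nr):
                expected[r1 + r2] += 1
        assert np.array_equal(profile, expected)

    def test_direct_ssrb_binning_equals_michelogram_then_ssrb(self, small_geometry, rng):
        """The analyses are invariant to the Michelogram plane ordering."""
        pairs = random_accepted_pairs(small_geometry, 600, rng)
        co = coincidence_frame(pairs)
        via_3d = ssrb(bin_coincidences(co, small_geometry, n_radial=61))
        direct = bin_coincidences(co, small_geometry, n_radial=61, planes="ssrb")
        assert np.array_equal(via_3d.counts, direct.counts)

    def test_requires_ring_metadata(self, small_geometry):
        direct = bin_coincidences(coincidence_frame([]), small_geometry,
                                  n_radial=61, planes="ssrb")
        with pytest.raises(AnalysisError, match="ring-pair metadata"):
            ssrb(direct)


class TestRFS:
    def test_example_rate_product(self, small_geometry):
        """2tau = 4.9 ns, s_x = 1 kHz, s_y = 2 kHz -> 9.8e-3 Hz on their LOR."""
        g = small_geometry
        rates = np.zeros(g.config.n_crystals)
        a = int(g.flat_from_ring_pos(0, 0))
        b = int(g.flat_from_ring_pos(0, 16))  # opposite side, accepted
        assert g.lor_accepted(a, b)
        rates[a], rates[b] = 1000.0, 2000.0
        sino = rfs(rates, 4.9, g, n_radial=61)
        assert sino.total == pytest.approx(4.9e-9 * 1000.0 * 2000.0, rel=1e-12)

    def test_zero_rate_crystal_contributes_nothing(self, small_geometry, rng):
        g = small_geometry
        rates = rng.uniform(100.0, 500.0, g.config.n_crystals)
        sino_full = rfs(rates, 4.9, g, n_radial=61)
        rates_zero = rates.copy()
        rates_zero[:] = 0.0
        assert rfs(rates_zero, 4.9, g, n_radial=61).total == 0.0
        assert sino_full.total > 0

    def test_bilinearity_doubling_rates_quadruples_total(self, small_geometry, rng):
        g = small_geometry
        rates = rng.uniform(50.0, 200.0, g.config.n_crystals)
        t1 = rfs(rates, 4.9, g, n_radial=61).total
        t2 = rfs(2 * rates, 4.9, g, n_radial=61).total
        assert t2 == pytest.approx(4 * t1, rel=1e-9)

    def test_coarse_upper_bound(self, small_geometry, rng):
        g = small_geometry
        rates = rng.uniform(0.0, 300.0, g.config.n_crystals)
        total = rfs(rates, 4.9, g, n_radial=61).total
        assert total <= 4.9e-9 * rates.sum() ** 2

    def test_negative_rates_rejected(self, small_geometry):
        with pytest.raises(AnalysisError):
            rfs(np.full(small_geometry.config.n_crystals, -1.0), 4.9,
                small_geometry)


class TestMashing:
    def test_no_mash_keeps_fine_sampling(self):
        dt = np.array([0.0, 6.0, 13.02, 20.0])
        out = mash_tof(dt, factor=1)
        assert np.allclose(out, np.round(dt / 13.02) * 13.02)

    def test_default_bin_width(self):
        assert TOF_BIN_PS == pytest.approx(169.26)
        out = mash_tof(np.array([100.0]), 13, 13.02)
        assert out[0] == pytest.approx(169.26)

    def test_values_within_a_bin_are_indistinguishable(self, rng):
        base = 3 * 169.26
        dts = base + rng.uniform(-84.0, 84.0, 100)
        out = mash_tof(dts)
        assert np.allclose(out, base)

    def test_invalid_parameters(self):
        with pytest.raises(AnalysisError):
            mash_tof(np.array([0.0]), factor=0)
        with pytest.raises(AnalysisError):
            mash_tof(np.array([0.0]), base_bin_ps=0.0)


class TestIO:
    def test_round_trip_is_bit_exact(self, small_geometry, rng, tmp_path):
        pairs = random_accepted_pairs(small_geometry, 300, rng)
        sino = bin_coincidences(coincidence_frame(pairs), small_geometry,
                                n_radial=61, duration_s=1.5,
                                avg_activity_kbq_ml=4.2)
        sino.save(tmp_path / "sino")
        back = Sinogram.load(tmp_path / "sino")
        assert np.array_equal(back.counts, sino.counts)
        assert back.radial_bin_mm == sino.radial_bin_mm
        assert back.duration_s == 1.5
        assert back.avg_activity_kbq_ml == 4.2
        assert np.array_equal(back.ring_a, sino.ring_a)
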