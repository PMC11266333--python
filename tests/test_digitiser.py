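import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from petbench.digitiser import (DigitiserConfig, adder, apply_deadtime,
                                apply_pileup, apply_qe_energy_time, blur_energy,
                                energy_window, inject_noise, process_hits,
                                readout, sort_coincidences, str_from_ctr)
from petbench.errors import ConfigurationError


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "crystal", "energy_kev",
                                       "time_ns", "scattered"])


def singles_frame(rows):
    df = pd.DataFrame(rows, columns=["event_id", "crystal", "energy_kev",
                                     "time_ns", "scattered"])
    return df.sort_values(["time_ns", "crystal"], ignore_index=True)


class TestConfig:
    def test_default_str_follows_from_ctr(self):
        assert str_from_ctr(375.0) / 1e3 == pytest.approx(0.265, abs=5e-4)
        assert DigitiserConfig().single_time_resolution_fwhm_ns == 0.265

    @pytest.mark.parametrize("kwargs", [
        {"energy_window_kev": (650.0, 425.0)},
        {"quantum_efficiency": 1.5},
        {"readout_policy": "bogus"},
        {"deadtime_model": "semi"},
    ])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigurationError):
            DigitiserConfig(**kwargs)


class TestAdder:
    def test_single_hit_passes_through(self):
        hits = hits_frame([(0, 5, 511.0, 1.0, False)])
        out = adder(hits)
        assert len(out) == 1
        assert out.loc[0, "energy_kev"] == 511.0

    def test_same_crystal_same_event_sums_energy(self):
        hits = hits_frame([(0, 5, 200.0, 1.0, False), (0, 5, 311.0, 1.2, True)])
        out = adder(hits)
        assert len(out) == 1
        assert out.loc[0, "energy_kev"] == pytest.approx(511.0)
        assert out.loc[0, "time_ns"] == 1.0     # earliest
        assert bool(out.loc[0, "scattered"])    # OR of flags

    def test_different_crystals_stay_distinct(self):
        hits = hits_frame([(0, 5, 200.0, 1.0, False), (0, 6, 311.0, 1.2, False)])
        assert len(adder(hits)) == 2


class TestReadout:
    def test_single_pulse_unchanged_under_both_policies(self, geometry):
        pulses = hits_frame([(0, 100, 511.0, 2.0, False)])
        for policy in ("energy_centroid", "energy_winner"):
            out = readout(adder(pulses), geometry, policy)
            assert out.loc[0, "crystal"] == 100
            assert out.loc[0, "energy_kev"] == 511.0

    def test_centroid_weighted_mean_rounds_to_crystal(self, geometry):
        # (400*10 + 100*14)/500 = 10.8 -> crystal 11 (same module: ids 0..143)
        pulses = hits_frame([(0, 10, 400.0, 1.0, False), (0, 14, 100.0, 1.1, False)])
        out = readout(pulses, geometry, "energy_centroid")
        assert len(out) == 1
        assert out.loc[0, "crystal"] == 11
        assert out.loc[0, "energy_kev"] == pytest.approx(500.0)
        assert out.loc[0, "time_ns"] == 1.0  # earliest, not recomputed

    def test_centroid_tie_breaks_to_lower_index(self, geometry):
        pulses = hits_frame([(0, 20, 250.0, 1.0, False), (0, 21, 250.0, 1.1, False)])
        out = readout(pulses, geometry, "energy_centroid")
        assert out.loc[0, "crystal"] == 20

    def test_winner_keeps_max_energy_index_and_time(self, geometry):
        pulses = hits_frame([(0, 10, 400.0, 1.5, False), (0, 14, 100.0, 1.0, False)])
        out = readout(pulses, geometry, "energy_winner")
        assert out.loc[0, "crystal"] == 10
        assert out.loc[0, "time_ns"] == 1.5
        assert out.loc[0, "energy_kev"] == pytest.approx(500.0)

    def test_different_modules_not_merged(self, geometry):
        # crystals 0 and 144 sit in different modules of sector 0
        pulses = hits_frame([(0, 0, 300.0, 1.0, False), (0, 144, 300.0, 1.0, False)])
        assert len(readout(pulses, geometry, "energy_centroid")) == 2


class TestPileup:
    def _pulses(self, geometry, times, energies):
        df = hits_frame([(i, 0, e, t, False)
                         for i, (t, e) in enumerate(zip(times, energies))])
        return readout(df, geometry, "energy_centroid")

    def test_zero_window_is_identity(self, geometry):
        pulses = self._pulses(geometry, [0.0, 5.0], [511.0, 511.0])
        out = apply_pileup(pulses, 0.0)
        assert len(out) == 2

    def test_close_pulses_merge_and_fail_energy_window(self, geometry):
        pulses = self._pulses(geometry, [0.0, 10.0], [511.0, 511.0])
        out = apply_pileup(pulses, 20.0)
        assert len(out) == 1
        assert out.loc[0, "energy_kev"] == pytest.approx(1022.0)
        assert len(energy_window(out, (425.0, 650.0))) == 0

    def test_separated_pulses_survive(self, geometry):
        pulses = self._pulses(geometry, [0.0, 25.0], [511.0, 511.0])
        assert len(apply_pileup(pulses, 20.0)) == 2


class TestDeadtime:
    def _stream(self, times):
        df = pd.DataFrame({
            "event_id": np.arange(len(times)), "volume": 0,
            "crystal": 0, "energy_kev": 511.0,
            "time_ns": np.asarray(times, dtype=float),
            "scattered": False,
        })
        return df

    def test_zero_deadtime_is_identity(self):
        s = self._stream([0.0, 1.0, 2.0])
        assert len(apply_deadtime(s, 0.0)) == 3

    def test_non_paralyzable_extends_from_accepted(self):
        # events at 0, 4, 8 with tau=5: 4 blocked, 8 accepted (vs last ACCEPTED 0)
        s = self._stream([0.0, 4.0, 8.0])
        out = apply_deadtime(s, 5.0, "non_paralyzable")
        assert list(out["time_ns"]) == [0.0, 8.0]

    def test_paralyzable_extends_from_arrival(self):
        # 4 blocked by 0; 8 blocked by the ARRIVAL at 4
        s = self._stream([0.0, 4.0, 8.0])
        out = apply_deadtime(s, 5.0, "paralyzable")
        assert list(out["time_ns"]) == [0.0]


class TestNoise:
    def test_zero_rate(self, geometry, rng):
        assert len(inject_noise(1.0, 0.0, geometry, rng)) == 0

    def test_rate_is_poisson(self, geometry, rng):
        n = len(inject_noise(0.05, 1.193e6, geometry, rng))
        mean = 1.193e6 * 0.05
        assert abs(n - mean) < 3 * np.sqrt(mean)

    def test_crystals_uniform_chi_square(self, small_geometry, rng):
        from scipy.stats import chisquare
        noise = inject_noise(0.1, 1e6, small_geometry, rng)
        counts = np.bincount(noise["crystal"],
                             minlength=small_geometry.config.n_crystals)
        assert chisquare(counts).pvalue > 1e-3

    def test_noise_energies_inside_window(self, geometry, rng):
        noise = inject_noise(0.01, 1e6, geometry, rng)
        assert noise["energy_kev"].between(425.0, 650.0).all()
        assert (noise["event_id"] == -1).all()


class TestQEEnergyTime:
    def test_unblurred_511_passes_window(self, geometry, rng):
        cfg = DigitiserConfig(quantum_efficiency=1.0, energy_resolution_fwhm=0.0,
                              single_time_resolution_fwhm_ns=0.0)
        pulses = hits_frame([(0, 0, 511.0, 1.0, False)])
        assert len(apply_qe_energy_time(pulses, cfg, rng)) == 1

    def test_scattered_340_kev_rejected(self, geometry, rng):
        cfg = DigitiserConfig(quantum_efficiency=1.0, energy_resolution_fwhm=0.0,
                              single_time_resolution_fwhm_ns=0.0)
        pulses = hits_frame([(0, 0, 340.0, 1.0, True)])
        assert len(apply_qe_energy_time(pulses, cfg, rng)) == 0

    def test_energy_blur_fwhm_at_511(self, rng):
        pulses = hits_frame([(i, 0, 511.0, 0.0, False) for i in range(100_000)])
        out = blur_energy(pulses, 0.094, rng)
        fwhm = out["energy_kev"].std() * 2.3548
        assert fwhm == pytest.approx(0.094 * 511.0, rel=0.02)

    def test_qe_thinning_rate(self, rng):
        pulses = hits_frame([(i, 0, 511.0, 0.0, False) for i in range(100_000)])
        cfg = DigitiserConfig(energy_resolution_fwhm=0.0,
                              single_time_resolution_fwhm_ns=0.0)
        kept = len(apply_qe_energy_time(pulses, cfg, rng))
        assert abs(kept / 1e5 - 0.9775) < 3 * np.sqrt(0.9775 * 0.0225 / 1e5)


class TestSorter:
    def test_pair_within_window(self, geometry):
        a = geometry.flat_from_ring_pos(0, 0)
        b = geometry.flat_from_ring_pos(0, 17 * 16)
        singles = singles_frame([(0, a, 511.0, 0.0, False),
                                 (0, b, 511.0, 2.0, False)])
        out = sort_coincidences(singles, DigitiserConfig(), geometry)
        assert len(out) == 1

    def test_pair_outside_window(self, geometry):
        a = geometry.flat_from_ring_pos(0, 0)
        b = geometry.flat_from_ring_pos(0, 17 * 16)
        singles = singles_frame([(0, a, 511.0, 0.0, False),
                                 (0, b, 511.0, 3.0, False)])
        assert len(sort_coincidences(singles, DigitiserConfig(), geometry)) == 0

    def test_triple_in_window_yields_three_pairs(self, geometry):
        ids = [geometry.flat_from_ring_pos(0, s * 16) for s in (0, 11, 22)]
        singles = singles_frame([(i, c, 511.0, 0.5 * i, False)
                                 for i, c in enumerate(ids)])
        out = sort_coincidences(singles, DigitiserConfig(), geometry)
        assert len(out) == 3  # take-all-goods emits every unordered pair once

    def test_unsorted_input_rejected(self, geometry):
        singles = pd.DataFrame({
            "event_id": [0, 1], "crystal": [0, 5000],
            "energy_kev": [511.0, 511.0], "time_ns": [2.0, 1.0],
            "scattered": [False, False],
        })
        with pytest.raises(ValueError, match="sorted"):
            sort_coincidences(singles, DigitiserConfig(), geometry)

    @given(st.lists(st.tuples(st.integers(0, 33), st.floats(0.0, 10.0),
                              st.integers(0, 4)),
                    min_size=2, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_enumeration(self, burst):
        import petbench
        geometry = petbench.build_scanner()
        cfg = DigitiserConfig()
        rows = []
        for i, (sector, t, ev) in enumerate(burst):
            crystal = int(geometry.flat_from_ring_pos(0, sector * 16))
            rows.append((ev, crystal, 511.0, t, False))
        singles = singles_frame(rows)
        out = sort_coincidences(singles, cfg, geometry)
        # independent O(n^2) oracle
        expected = 0
        t = singles["time_ns"].to_numpy()
        c = singles["crystal"].to_numpy()
        for i in range(len(singles)):
            for j in range(i + 1, len(singles)):
                if abs(t[j] - t[i]) <= cfg.coincidence_window_ns and c[i] != c[j] \
                        and geometry.sector_distance(c[i], c[j]) >= 4:
                    expected += 1
        assert len(out) == expected

    def test_classification_partition(self, geometry, rng):
        from petbench.phantoms import make_scatter_phantom
        from petbench.transport import SimConfig, run_acquisition
        res = run_acquisition(make_scatter_phantom(5e6), geometry, SimConfig(),
                              DigitiserConfig(), [(0.0, 0.01)], seed=9)
        co = res[0]["coincidences"]
        kinds = co["kind"].value_counts()
        assert kinds.sum() == len(co)
        assert set(kinds.index) <= {"true", "scatter", "random"}


class TestNullChain:
    def test_transparent_chain_is_identity_on_singles(self, geometry, rng):
        """All widths/rates zero, QE = 1: unscattered single-hit events pass
        through unchanged and pair into true coincidences."""
        cfg = DigitiserConfig(pileup_window_ns=0.0, deadtime_ns=0.0,
                              noise_rate_hz=0.0, quantum_efficiency=1.0,
                              energy_resolution_fwhm=0.0,
                              single_time_resolution_fwhm_ns=0.0)
        a = int(geometry.flat_from_ring_pos(3, 0))
        b = int(geometry.flat_from_ring_pos(3, 17 * 16))
        hits = hits_frame([(0, a, 511.0, 1.0, False),
                           (0, b, 511.0, 1.4, False),
                           (1, a, 511.0, 50.0, False),
                           (1, b, 511.0, 50.3, False)])
        singles, coinc = process_hits(hits, cfg, geometry, rng, 1e-6)
        assert len(singles) == 4
        assert np.allclose(sorted(singles["energy_kev"]), [511.0] * 4)
        assert np.allclose(sorted(singles["time_ns"]), [1.0, 1.4, 50.0, 50.3])
        assert len(coinc) == 2
        assert (coinc["kind"] == "true").all()
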