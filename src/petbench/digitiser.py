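"""The electronic signal chain: hits -> pulses -> singles -> coincidences.

Stage order (defaults reproduce the modelled scanner's electronics):

    adder -> readout (energy centroid, module depth) -> pile-up (20 ns)
    -> quantum efficiency (0.9775) -> energy blur (9.4% at 511 keV)
    -> [deadtime if placed before the window]
    -> energy window (425-650 keV)
    -> [deadtime if placed after the window; default placement]
    -> time blur (STR 0.265 ns FWHM) -> background noise (1193 kHz)
    -> coincidence sorting (tau = 2.45 ns, every single opens a window,
       take-all-goods, min sector difference 4)

Pile-up precedes energy discrimination because summed pulses must be
re-discriminated; the readout centroid deliberately keeps the earliest
constituent timestamp (it is not recomputed), reproducing the timing
degradation of Anger-logic repositioning.

Energy resolution scales as FWHM(E) = f * sqrt(511 * E) keV with
f = 0.094, i.e. constant fractional resolution at 511 keV and
inverse-square-root scaling elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import ScannerGeometry

__all__ = [
    "DigitiserConfig",
    "adder",
    "readout",
    "apply_pileup",
    "apply_deadtime",
    "inject_noise",
    "apply_qe_energy_time",
    "sort_coincidences",
    "process_hits",
    "str_from_ctr",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def str_from_ctr(ctr_ps: float) -> float:
    """Single-detector timing resolution from a coincidence timing
    resolution, assuming two identical Gaussian detectors: STR = CTR/sqrt(2)."""
    return ctr_ps / np.sqrt(2.0)


@dataclass(frozen=True)
class DigitiserConfig:
    readout_policy: str = "energy_centroid"   # or "energy_winner"
    pileup_window_ns: float = 20.0
    deadtime_ns: float = 0.0
    deadtime_model: str = "non_paralyzable"   # or "paralyzable"
    deadtime_placement: str = "after_window"  # or "before_window"
    noise_rate_hz: float = 1.193e6
    quantum_efficiency: float = 0.9775
    energy_resolution_fwhm: float = 0.094     # fractional, at 511 keV
    energy_window_kev: tuple[float, float] = (425.0, 650.0)
    single_time_resolution_fwhm_ns: float = 0.265
    coincidence_window_ns: float = 2.45       # tau; nominal CTW = 2*tau = 4.9 ns
    all_pulse_open_gate: bool = True
    multiples_policy: str = "take_all_goods"
    min_sector_difference: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.energy_window_kev
        if not lo < hi:
            raise ConfigurationError("energy window bounds must be ordered")
        for name in ("pileup_window_ns", "deadtime_ns", "noise_rate_hz",
                     "energy_resolution_fwhm", "single_time_resolution_fwhm_ns",
                     "coincidence_window_ns"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.quantum_efficiency <= 1.0:
            raise ConfigurationError("quantum_efficiency must be in [0, 1]")
        if self.readout_policy not in ("energy_centroid", "energy_winner"):
            raise ConfigurationError(f"unknown readout policy {self.readout_policy!r}")
        if self.deadtime_model not in ("paralyzable", "non_paralyzable"):
            raise ConfigurationError(f"unknown deadtime model {self.deadtime_model!r}")
        if self.deadtime_placement not in ("before_window", "after_window"):
            raise ConfigurationError(f"unknown deadtime placement {self.deadtime_placement!r}")


# ---------------------------------------------------------------------------
# Hits -> pulses
# ---------------------------------------------------------------------------

def adder(hits: pd.DataFrame) -> pd.DataFrame:
    """Merge hits in the same crystal within the same event: energies are
    summed, the time is the earliest hit time."""
    if hits.empty:
        return hits.assign()
    g = hits.groupby(["event_id", "crystal"], sort=False)
    out = g.agg(energy_kev=("energy_kev", "sum"),
                time_ns=("time_ns", "min"),
                scattered=("scattered", "any")).reset_index()
    return out.sort_values("time_ns", kind="stable", ignore_index=True)


def _module_volume(crystal: np.ndarray, geometry: ScannerGeometry) -> np.ndarray:
    c = geometry.config
    sector = geometry.sector[crystal]
    module = geometry.module[crystal]
    return sector * c.n_modules_axial + module


def readout(pulses: pd.DataFrame, geometry: ScannerGeometry,
            policy: str = "energy_centroid") -> pd.DataFrame:
    """Group pulses at module depth.

    energy_centroid: one output pulse per (event, module); total energy,
    crystal index = energy-weighted centroid of the constituent flat ids
    rounded to the nearest crystal (ties to the lower index), time =
    earliest constituent time (deliberately not recomputed).

    energy_winner: crystal and time of the max-energy constituent, total
    energy.
    """
    if policy not in ("energy_centroid", "energy_winner"):
        raise ConfigurationError(f"unknown readout policy {policy!r}")
    if pulses.empty:
        out = pulses.copy()
        out["volume"] = pd.Series(dtype=np.int64)
        return out
    df = pulses.copy()
    df["volume"] = _module_volume(df["crystal"].to_numpy(), geometry)
    g = df.groupby(["event_id", "volume"], sort=False)
    if policy == "energy_centroid":
        df["_ew"] = df["energy_kev"] * df["crystal"]
        agg = g.agg(energy_kev=("energy_kev", "sum"),
                    _ew=("_ew", "sum"),
                    time_ns=("time_ns", "min"),
                    scattered=("scattered", "any")).reset_index()
        centroid = agg["_ew"] / agg["energy_kev"]
        # round half down: ties between adjacent crystals go to the lower id
        agg["crystal"] = np.ceil(centroid - 0.5).astype(np.int64)
        agg = agg.drop(columns="_ew")
    else:
        # winner: max energy, ties to the lower crystal id
        df = df.sort_values(["energy_kev", "crystal"],
                            ascending=[False, True], kind="stable")
        winner = df.groupby(["event_id", "volume"], sort=False).first().reset_index()
        tot = g["energy_kev"].sum().reset_index(name="energy_total")
        agg = winner.merge(tot, on=["event_id", "volume"])
        agg["energy_kev"] = agg["energy_total"]
        agg = agg.drop(columns="energy_total")
    cols = ["event_id", "volume", "crystal", "energy_kev", "time_ns", "scattered"]
    return agg[cols].sort_values("time_ns", kind="stable", ignore_index=True)


def apply_pileup(pulses: pd.DataFrame, window_ns: float) -> pd.DataFrame:
    """Merge pulses in the same readout volume closer than ``window_ns``.

    Chained merging: a pulse joins the cluster of its predecessor when the
    inter-arrival gap is below the window.  The merged pulse sums the
    energies and keeps the first pulse's time, crystal and event id (the
    scattered flag is the OR).  Applied before energy discrimination.
    """
    if pulses.empty or window_ns <= 0:
        return pulses.copy()
    df = pulses.sort_values(["volume", "time_ns"], kind="stable", ignore_index=True)
    gap = df["time_ns"].diff().to_numpy()
    new_volume = df["volume"].diff().fillna(1).to_numpy() != 0
    new_cluster = new_volume | ~(gap < window_ns)
    cluster = np.cumsum(new_cluster)
    g = df.groupby(cluster, sort=False)
    out = g.agg(event_id=("event_id", "first"),
                volume=("volume", "first"),
                crystal=("crystal", "first"),
                energy_kev=("energy_kev", "sum"),
                time_ns=("time_ns", "first"),
                scattered=("scattered", "any")).reset_index(drop=True)
    return out.sort_values("time_ns", kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# Pulses -> singles
# ---------------------------------------------------------------------------

def _deadtime_keep(times: np.ndarray, tau: float, paralyzable: bool) -> np.ndarray:
    """Boolean keep-mask for a time-sorted stream under deadtime ``tau``."""
    keep = np.ones(len(times), dtype=bool)
    if tau <= 0 or len(times) == 0:
        return keep
    if paralyzable:
        # an event is lost if the previous ARRIVAL is within tau
        gaps = np.diff(times)
        keep[1:] = gaps >= tau
        return keep
    last = -np.inf
    for i, t in enumerate(times):
        if t - last >= tau:
            last = t
        else:
            keep[i] = False
    return keep


def apply_deadtime(singles: pd.DataFrame, deadtime_ns: float,
                   model: str = "non_paralyzable") -> pd.DataFrame:
    """Thin a time-sorted stream per readout volume.

    non_paralyzable: drop events within ``deadtime_ns`` of the last
    accepted event; paralyzable: of the last arrived event.
    """
    if deadtime_ns <= 0 or singles.empty:
        return singles.copy()
    if model not in ("paralyzable", "non_paralyzable"):
        raise ConfigurationError(f"unknown deadtime model {model!r}")
    df = singles.sort_values(["volume", "time_ns"], kind="stable")
    keep = np.concatenate([
        _deadtime_keep(grp["time_ns"].to_numpy(), deadtime_ns,
                       model == "paralyzable")
        for _, grp in df.groupby("volume", sort=False)
    ]) if "volume" in df.columns else _deadtime_keep(
        df["time_ns"].to_numpy(), deadtime_ns, model == "paralyzable")
    return df[keep].sort_values("time_ns", kind="stable", ignore_index=True)


def inject_noise(duration_s: float, rate_hz: float, geometry: ScannerGeometry,
                 rng: np.random.Generator,
                 energy_window_kev: tuple[float, float] = (425.0, 650.0)) -> pd.DataFrame:
    """Homogeneous Poisson background singles (LYSO radioactivity + dark
    counts), uniform over crystals, energies uniform inside the energy
    window (so the window cut passes them by construction)."""
    if rate_hz < 0:
        raise ConfigurationError("noise rate must be >= 0")
    n = rng.poisson(rate_hz * duration_s) if rate_hz * duration_s > 0 else 0
    crystal = rng.integers(0, geometry.config.n_crystals, n)
    return pd.DataFrame({
        "event_id": np.full(n, -1, dtype=np.int64),
        "volume": _module_volume(crystal, geometry) if n else np.zeros(0, dtype=np.int64),
        "crystal": crystal,
        "energy_kev": rng.uniform(*energy_window_kev, n),
        "time_ns": np.sort(rng.uniform(0.0, duration_s * 1e9, n)),
        "scattered": np.zeros(n, dtype=bool),
        "origin": np.repeat("noise", n),
    })


def apply_qe_energy_time(pulses: pd.DataFrame, config: DigitiserConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Quantum efficiency thinning, energy and time blur, energy window."""
    df = apply_qe(pulses, config.quantum_efficiency, rng)
    df = blur_energy(df, config.energy_resolution_fwhm, rng)
    df = blur_time(df, config.single_time_resolution_fwhm_ns, rng)
    return energy_window(df, config.energy_window_kev)


def apply_qe(pulses: pd.DataFrame, qe: float, rng: np.random.Generator) -> pd.DataFrame:
    if pulses.empty or qe >= 1.0:
        return pulses.copy()
    return pulses[rng.random(len(pulses)) < qe].reset_index(drop=True)


def blur_energy(pulses: pd.DataFrame, fwhm_frac: float,
                rng: np.random.Generator) -> pd.DataFrame:
    df = pulses.copy()
    if fwhm_frac > 0 and len(df):
        fwhm = fwhm_frac * np.sqrt(511.0 * df["energy_kev"].to_numpy())
        df["energy_kev"] = df["energy_kev"] + rng.normal(size=len(df)) * fwhm / _FWHM_TO_SIGMA
    return df


def blur_time(pulses: pd.DataFrame, fwhm_ns: float,
              rng: np.random.Generator) -> pd.DataFrame:
    df = pulses.copy()
    if fwhm_ns > 0 and len(df):
        df["time_ns"] = df["time_ns"] + rng.normal(
            scale=fwhm_ns / _FWHM_TO_SIGMA, size=len(df))
        df = df.sort_values("time_ns", kind="stable", ignore_index=True)
    return df


def energy_window(pulses: pd.DataFrame, window_kev: tuple[float, float]) -> pd.DataFrame:
    lo, hi = window_kev
    if pulses.empty:
        return pulses.copy()
    e = pulses["energy_kev"].to_numpy()
    return pulses[(e >= lo) & (e <= hi)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Singles -> coincidences
# ---------------------------------------------------------------------------

def sort_coincidences(singles: pd.DataFrame, config: DigitiserConfig,
                      geometry: ScannerGeometry) -> pd.DataFrame:
    """Pair time-sorted singles into coincidences.

    Every single opens its own window of length ``coincidence_window_ns``
    (tau); under take-all-goods every unordered pair with |dt| <= tau
    that satisfies the sector-difference rule is emitted exactly once.
    Classification against truth labels: same event id and neither
    scattered -> true; same event id and any scattered -> scatter;
    otherwise (different events or noise) -> random.
    """
    t = singles["time_ns"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise ValueError("singles must be time-sorted")
    n = len(singles)
    tau = config.coincidence_window_ns
    hi = np.searchsorted(t, t + tau, side="right")
    cnt = hi - np.arange(n) - 1
    cnt = np.maximum(cnt, 0)
    total = int(cnt.sum())
    i_idx = np.repeat(np.arange(n), cnt)
    offs = np.cumsum(cnt) - cnt
    j_idx = np.arange(total) - np.repeat(offs, cnt) + i_idx + 1

    crystal = singles["crystal"].to_numpy()
    ca, cb = crystal[i_idx], crystal[j_idx]
    if total:
        ok = geometry.lor_accepted(ca, cb)
        ok &= geometry.sector_distance(ca, cb) >= config.min_sector_difference
    else:
        ok = np.zeros(0, dtype=bool)
    i_idx, j_idx = i_idx[ok], j_idx[ok]

    ev = singles["event_id"].to_numpy()
    sc = singles["scattered"].to_numpy()
    ea, eb = ev[i_idx], ev[j_idx]
    same = (ea == eb) & (ea >= 0)
    any_scattered = sc[i_idx] | sc[j_idx]
    kind = np.where(same & ~any_scattered, "true",
                    np.where(same, "scatter", "random"))

    # canonical order: crystal A is the smaller flat id
    a_first = crystal[i_idx] <= crystal[j_idx]
    ia = np.where(a_first, i_idx, j_idx)
    ib = np.where(a_first, j_idx, i_idx)
    return pd.DataFrame({
        "crystal_a": crystal[ia],
        "crystal_b": crystal[ib],
        "time_a_ns": t[ia],
        "time_b_ns": t[ib],
        "dt_ps": (t[ia] - t[ib]) * 1e3,
        "event_a": ev[ia],
        "event_b": ev[ib],
        "kind": kind,
    })


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def process_hits(hits: pd.DataFrame, config: DigitiserConfig,
                 geometry: ScannerGeometry, rng: np.random.Generator,
                 duration_s: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the complete chain; returns (singles, coincidences)."""
    pulses = adder(hits)
    pulses = readout(pulses, geometry, config.readout_policy)
    pulses = apply_pileup(pulses, config.pileup_window_ns)
    pulses = apply_qe(pulses, config.quantum_efficiency, rng)
    pulses = blur_energy(pulses, config.energy_resolution_fwhm, rng)
    if config.deadtime_placement == "before_window":
        pulses = apply_deadtime(pulses, config.deadtime_ns, config.deadtime_model)
    pulses = energy_window(pulses, config.energy_window_kev)
    if config.deadtime_placement == "after_window":
        pulses = apply_deadtime(pulses, config.deadtime_ns, config.deadtime_model)
    pulses = blur_time(pulses, config.single_time_resolution_fwhm_ns, rng)
    pulses = pulses.assign(origin="annihilation")
    noise = inject_noise(duration_s, config.noise_rate_hz, geometry, rng,
                         config.energy_window_kev)
    singles = pd.concat([pulses, noise], ignore_index=True)
    # stable tie-break on equal times: crystal id order
    singles = singles.sort_values(["time_ns", "crystal"], kind="stable",
                                  ignore_index=True)
    coincidences = sort_coincidences(singles, config, geometry)
    return singles, coincidences
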