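"""Decay generation and annihilation-photon transport.

This is a deliberately simplified stand-in for a full Monte Carlo
physics engine: annihilation photon pairs are emitted back-to-back
(optional Gaussian acollinearity), transported through the phantom
primitives with exact analytic ray intersections, and undergo at most
``max_scatters`` single Compton scatters with Klein-Nishina-sampled
angles; interactions are otherwise photoelectric-equivalent absorption.
Detection is a photoelectric-equivalent capture in the entered LYSO
crystal with probability 1 - exp(-mu_LYSO * chord).

Sources decay exponentially: A(t) = A0 * 2^(-t / half_life); each decay
yields an annihilation pair with probability ``beta_plus_fraction``
(positron branching, 0.969 for F-18).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScannerGeometry
from .materials import get_material
from .phantoms import PhantomModel

__all__ = [
    "SimConfig",
    "EmissionBatch",
    "sample_decays",
    "transport_photons",
    "intersect_detector",
    "run_acquisition",
    "SPEED_OF_LIGHT_MM_NS",
]

SPEED_OF_LIGHT_MM_NS = 299.792458
_E0_KEV = 511.0
_RAY_HORIZON_MM = 4000.0


@dataclass(frozen=True)
class SimConfig:
    """Physics options of the transport stage."""

    half_life_s: float = 6586.2         # forced F-18 half-life
    beta_plus_fraction: float = 0.969   # F-18 positron branching
    acollinearity_fwhm_deg: float = 0.0 # 0 = exactly back-to-back
    positron_range_mm: float = 0.0      # Gaussian blur of the annihilation point
    max_scatters: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_plus_fraction <= 1.0:
            raise ValueError("beta_plus_fraction must be in [0, 1]")
        if self.half_life_s <= 0:
            raise ValueError("half_life_s must be > 0")

    @property
    def decay_constant(self) -> float:
        return np.log(2.0) / self.half_life_s


@dataclass
class EmissionBatch:
    """Annihilation events of one frame (struct-of-arrays)."""

    n_decays: int                 # all decays, annihilating or not
    event_id: np.ndarray          # (N,)
    time_s: np.ndarray            # (N,) within-frame decay times
    position: np.ndarray          # (N, 3) annihilation points, mm
    direction: np.ndarray         # (N, 3) unit direction of photon 1

    def __len__(self) -> int:
        return len(self.event_id)

    @property
    def annihilation_fraction(self) -> float:
        return len(self.event_id) / self.n_decays if self.n_decays else 0.0


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_decays(phantom: PhantomModel, config: SimConfig, duration_s: float,
                  rng: np.random.Generator, activity_bq: float | None = None,
                  event_id_offset: int = 0) -> EmissionBatch:
    """Sample decays of an exponentially decaying source over one frame.

    The number of decays is Poisson with mean A0*(1 - e^(-lambda*T))/lambda;
    each decay annihilates with probability ``beta_plus_fraction``.
    Positions are uniform within the active primitives, weighted by
    concentration x volume.
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    a0 = phantom.total_activity_bq if activity_bq is None else activity_bq
    lam = config.decay_constant
    mean = a0 * (1.0 - np.exp(-lam * duration_s)) / lam
    n_decays = int(rng.poisson(mean)) if mean > 0 else 0
    annihilates = rng.random(n_decays) < config.beta_plus_fraction
    n = int(annihilates.sum())
    # inverse-CDF times of the truncated exponential decay curve
    u = rng.random(n_decays)
    times = -np.log1p(-u * (1.0 - np.exp(-lam * duration_s))) / lam
    times = np.sort(times[annihilates])
    pos = phantom.sample_emission_points(n, rng)
    if config.positron_range_mm > 0:
        pos = pos + rng.normal(scale=config.positron_range_mm / 2.3548, size=pos.shape)
    dirs = _isotropic_directions(n, rng)
    return EmissionBatch(
        n_decays=n_decays,
        event_id=event_id_offset + np.arange(n, dtype=np.int64),
        time_s=times,
        position=pos,
        direction=dirs,
    )


def _second_photon_direction(dirs: np.ndarray, config: SimConfig,
                             rng: np.random.Generator) -> np.ndarray:
    back = -dirs
    if config.acollinearity_fwhm_deg <= 0:
        return back
    sigma = np.deg2rad(config.acollinearity_fwhm_deg) / 2.3548
    theta = np.abs(rng.normal(scale=sigma, size=len(dirs)))
    return _rotate_about(back, theta, rng)


def _rotate_about(dirs: np.ndarray, theta: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Deviate unit vectors by polar angle theta with uniform azimuth."""
    n = len(dirs)
    # orthonormal basis per vector
    a = np.where(np.abs(dirs[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(dirs, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    phi = rng.uniform(0, 2 * np.pi, n)
    st = np.sin(theta)
    return (
        dirs * np.cos(theta)[:, None]
        + e1 * (st * np.cos(phi))[:, None]
        + e2 * (st * np.sin(phi))[:, None]
    )


# ---------------------------------------------------------------------------
# Photon transport
# ---------------------------------------------------------------------------

def _segment_grid(origins, dirs, phantom):
    """Breakpoints of the piecewise-constant mu along each ray."""
    n = len(origins)
    columns = [np.zeros(n), np.full(n, _RAY_HORIZON_MM)]
    for prim in phantom.primitives:
        for t0, t1 in prim.ray_intervals(origins, dirs):
            valid = t0 <= t1
            columns.append(np.where(valid, np.clip(t0, 0.0, _RAY_HORIZON_MM), 0.0))
            columns.append(np.where(valid, np.clip(t1, 0.0, _RAY_HORIZON_MM), 0.0))
    grid = np.sort(np.column_stack(columns), axis=1)
    return grid


def _sample_interaction(origins, dirs, phantom, rng):
    """Free-path sampling along each ray against the line-integrated mu.

    Returns (t_interaction, interacted mask); t is inf where the photon
    escapes the phantom region.
    """
    n = len(origins)
    if n == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    grid = _segment_grid(origins, dirs, phantom)
    t_lo, t_hi = grid[:, :-1], grid[:, 1:]
    lengths = t_hi - t_lo
    mid = (t_lo + t_hi) / 2.0
    # mu at the midpoint of every segment (priority rule applied inside)
    pts = origins[:, None, :] + mid[:, :, None] * dirs[:, None, :]
    mu = phantom.mu_at(pts.reshape(-1, 3)).reshape(mid.shape)
    depth = mu * lengths
    cum = np.cumsum(depth, axis=1)
    target = rng.exponential(size=n)
    seg = np.sum(cum < target[:, None], axis=1)
    interacted = seg < cum.shape[1]
    segc = np.minimum(seg, cum.shape[1] - 1)
    rows = np.arange(n)
    before = np.where(segc > 0, cum[rows, segc - 1], 0.0)
    mu_seg = mu[rows, segc]
    # a boundary-rounding edge case can select a vacuum segment: escape
    interacted &= mu_seg > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_int = t_lo[rows, segc] + (target - before) / mu_seg
    t_int = np.where(interacted, t_int, np.inf)
    return t_int, interacted


def _sample_klein_nishina(energy_kev: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample Compton cos(theta) from the Klein-Nishina distribution
    (vectorised rejection against a constant envelope)."""
    n = len(energy_kev)
    alpha = energy_kev / _E0_KEV
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        ct = rng.uniform(-1.0, 1.0, todo.size)
        ratio = 1.0 / (1.0 + alpha[todo] * (1.0 - ct))  # E'/E
        f = ratio**2 * (ratio + 1.0 / ratio - (1.0 - ct**2))
        accept = rng.random(todo.size) * 2.0 <= f
        out[todo[accept]] = ct[accept]
        todo = todo[~accept]
    return out


def transport_photons(origins: np.ndarray, dirs: np.ndarray, phantom: PhantomModel,
                      rng: np.random.Generator, max_scatters: int = 1):
    """Transport photons through the phantom.

    Returns a dict of arrays: ``position`` and ``direction`` of the
    escaping photon, remaining ``energy_kev``, boolean ``scattered``,
    accumulated ``path_mm`` from the origin to the last interaction, and
    boolean ``absorbed``.  After ``max_scatters`` scatters a photon is
    forced to escape without further interaction.
    """
    n = len(origins)
    pos = np.array(origins, dtype=float)
    d = np.array(dirs, dtype=float)
    energy = np.full(n, _E0_KEV)
    scattered = np.zeros(n, dtype=bool)
    absorbed = np.zeros(n, dtype=bool)
    path = np.zeros(n)
    active = np.ones(n, dtype=bool)

    for _ in range(max_scatters + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        t_int, interacted = _sample_interaction(pos[idx], d[idx], phantom, rng)
        # escaping photons are done
        active[idx[~interacted]] = False
        hit = idx[interacted]
        if hit.size == 0:
            break
        t = t_int[interacted]
        pos[hit] = pos[hit] + t[:, None] * d[hit]
        path[hit] += t
        prim_idx = phantom.material_index_at(pos[hit])
        cf = np.array([
            phantom.primitives[i].material.compton_fraction if i >= 0
            else get_material("air").compton_fraction
            for i in prim_idx
        ])
        is_compton = rng.random(hit.size) < cf
        dead = hit[~is_compton]
        absorbed[dead] = True
        active[dead] = False
        sc = hit[is_compton]
        if sc.size:
            ct = _sample_klein_nishina(energy[sc], rng)
            energy[sc] = energy[sc] / (1.0 + (energy[sc] / _E0_KEV) * (1.0 - ct))
            d[sc] = _rotate_about(d[sc], np.arccos(ct), rng)
            scattered[sc] = True
        # photons that have used up their scatter budget escape on the
        # next loop exit (forced escape)
    return {
        "position": pos,
        "direction": d,
        "energy_kev": energy,
        "scattered": scattered,
        "path_mm": path,
        "absorbed": absorbed,
    }


# ---------------------------------------------------------------------------
# Detector intersection
# ---------------------------------------------------------------------------

def intersect_detector(pos: np.ndarray, dirs: np.ndarray, geometry: ScannerGeometry,
                       rng: np.random.Generator):
    """Intersect escaping photons with the crystal ring.

    Returns (crystal flat id or -1, path-to-front-face mm).  Capture is
    decided by the caller; this resolves geometry only.
    """
    c = geometry.config
    r_front = c.ring_radius_mm
    a = dirs[:, 0] ** 2 + dirs[:, 1] ** 2
    b = pos[:, 0] * dirs[:, 0] + pos[:, 1] * dirs[:, 1]
    q = pos[:, 0] ** 2 + pos[:, 1] ** 2 - r_front**2
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = b * b - a * q
        ok = (disc >= 0) & (a > 1e-16) & (q < 0)  # origin inside the ring
        t = np.where(ok, (-b + np.sqrt(np.where(disc > 0, disc, 0.0))) / a, np.inf)
    with np.errstate(invalid="ignore"):
        x = pos[:, 0] + t * dirs[:, 0]
        y = pos[:, 1] + t * dirs[:, 1]
        z = pos[:, 2] + t * dirs[:, 2]
    phi = np.arctan2(y, x)
    flat = np.full(len(pos), -1, dtype=np.int64)
    valid = np.isfinite(t)
    if np.any(valid):
        flat[valid] = geometry.crystal_at(phi[valid], z[valid])
    return flat, t


def detect_hits(batch: EmissionBatch, phantom: PhantomModel,
                geometry: ScannerGeometry, sim_config: SimConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Full decay-to-hit pipeline for one emission batch.

    Returns a time-sorted hit table with truth labels (event id and
    phantom-scatter flag).
    """
    if len(batch) == 0:
        return _empty_hits()
    n = len(batch)
    origins = np.vstack([batch.position, batch.position])
    d2 = _second_photon_direction(batch.direction, sim_config, rng)
    dirs = np.vstack([batch.direction, d2])
    event = np.concatenate([batch.event_id, batch.event_id])
    t0_ns = np.concatenate([batch.time_s, batch.time_s]) * 1e9

    tr = transport_photons(origins, dirs, phantom, rng, sim_config.max_scatters)
    alive = ~tr["absorbed"]
    flat, t_face = intersect_detector(tr["position"][alive], tr["direction"][alive],
                                      geometry, rng)
    entered = flat >= 0
    idx = np.flatnonzero(alive)[entered]
    flat = flat[entered]
    t_face = t_face[entered]
    # chord through the 25-mm crystal annulus along the ray
    c = geometry.config
    p = tr["position"][idx]
    dd = tr["direction"][idx]
    a = dd[:, 0] ** 2 + dd[:, 1] ** 2
    b = p[:, 0] * dd[:, 0] + p[:, 1] * dd[:, 1]
    q = p[:, 0] ** 2 + p[:, 1] ** 2 - (c.ring_radius_mm + c.crystal_depth_mm) ** 2
    t_back = (-b + np.sqrt(b * b - a * q)) / a
    chord = np.maximum(t_back - t_face, 0.0)
    mu_lyso = get_material("lyso").mu_511_mm
    captured = rng.random(len(idx)) < 1.0 - np.exp(-mu_lyso * chord)
    idx = idx[captured]
    flat = flat[captured]
    path = tr["path_mm"][idx] + t_face[captured]
    hits = pd.DataFrame({
        "event_id": event[idx],
        "crystal": flat,
        "energy_kev": tr["energy_kev"][idx],
        "time_ns": t0_ns[idx] + path / SPEED_OF_LIGHT_MM_NS,
        "scattered": tr["scattered"][idx],
    })
    return hits.sort_values("time_ns", kind="stable", ignore_index=True)


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame({
        "event_id": pd.Series(dtype=np.int64),
        "crystal": pd.Series(dtype=np.int64),
        "energy_kev": pd.Series(dtype=float),
        "time_ns": pd.Series(dtype=float),
        "scattered": pd.Series(dtype=bool),
    })


# ---------------------------------------------------------------------------
# Acquisition orchestration
# ---------------------------------------------------------------------------

def run_acquisition(phantom: PhantomModel, geometry: ScannerGeometry,
                    sim_config: SimConfig, digitiser_config, frames,
                    seed: int | None = None):
    """Run decays -> transport -> hits -> digitiser for each frame.

    ``frames`` is a list of (start_s, duration_s), non-overlapping and
    sorted.  The source activity decays across frames with the configured
    half-life.  Returns a list of per-frame dicts with the singles and
    coincidence tables plus bookkeeping (average activity, decay count).
    """
    from .digitiser import process_hits  # local import to avoid a cycle

    starts = [f[0] for f in frames]
    if any(s1 < s0 + d0 for (s0, d0), s1 in zip(frames, starts[1:])):
        raise ValueError("frames must be sorted and non-overlapping")
    rng = np.random.default_rng(sim_config.seed if seed is None else seed)
    a0 = phantom.total_activity_bq
    lam = sim_config.decay_constant
    out = []
    offset = 0
    for start_s, duration_s in frames:
        a_start = a0 * np.exp(-lam * start_s)
        batch = sample_decays(phantom, sim_config, duration_s, rng,
                              activity_bq=a_start, event_id_offset=offset)
        offset += len(batch) + 1
        hits = detect_hits(batch, phantom, geometry, sim_config, rng)
        singles, coincidences = process_hits(hits, digitiser_config, geometry,
                                             rng, duration_s)
        avg_activity = (
            a_start * (1.0 - np.exp(-lam * duration_s)) / (lam * duration_s)
            if duration_s > 0 else a_start
        )
        out.append({
            "start_s": start_s,
            "duration_s": duration_s,
            "avg_activity_bq": avg_activity,
            "n_decays": batch.n_decays,
            "n_annihilations": len(batch),
            "hits": hits,
            "singles": singles,
            "coincidences": coincidences,
        })
    return out
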