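"""Coincidence list-mode -> sinograms; SSRB; randoms from singles; TOF mashing.

Binning convention (documented, not the vendor's proprietary layout):

* transaxial: for the crystal pair with transaxial centres ``pA``, ``pB``
  (2D points at the crystal-centre radius ``Rc``), the LOR normal angle is
  ``theta in [0, pi)`` and the signed radial offset is ``s = pA . n(theta)``;
  ``view = floor(theta / (pi / n_views))`` with
  ``n_views = crystals_per_ring / 2`` (272 by default) and
  ``radial = (n_radial - 1)/2 + round(s / ds)`` with the radial bin size
  ``ds = pi * Rc / crystals_per_ring`` (the interleaved half-crystal
  sampling pitch).  A diametral LOR of two same-ring crystals lands in the
  central radial bin ((415-1)/2 = 207).
* axial: the full ring-pair Michelogram, ``n_rings**2`` planes ordered by
  segment (ring difference 0, +1, -1, +2, ...), each segment by the first
  ring.  The vendor's 1261-plane layout derives from proprietary look-up
  tables and is not replicated; every analysis here operates post-SSRB or
  on axial sums and is invariant to the plane ordering.
* TOF: 29 bins of 169.26 ps (mash factor 13 x sampling 13.02 ps) centred
  on dt = 0, spanning the 4.9-ns coincidence window; out-of-range dt are
  discarded and counted.

Binning can alternatively rebin axially on the fly (``planes="ssrb"``),
which is what the count-rate and sensitivity pipelines use: it is exactly
``ssrb(bin_coincidences(...))`` but never materialises the Michelogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .geometry import ScannerGeometry

__all__ = [
    "Sinogram",
    "bin_coincidences",
    "ssrb",
    "rfs",
    "mash_tof",
    "TOF_SAMPLING_PS",
    "TOF_MASH_FACTOR",
    "TOF_BIN_PS",
    "N_TOF_BINS",
]

TOF_SAMPLING_PS = 13.02   # fine sampling S
TOF_MASH_FACTOR = 13      # mash factor C
TOF_BIN_PS = TOF_MASH_FACTOR * TOF_SAMPLING_PS  # CS = 169.26 ps
N_TOF_BINS = 29           # odd; 29 * 169.26 ps spans the 4.9-ns window


@dataclass
class Sinogram:
    """Count (or rate) array with binning and frame metadata.

    ``counts`` has shape (n_radial, n_planes, n_views) and, when a TOF
    axis is present, (n_radial, n_planes, n_views, n_tof).
    """

    counts: np.ndarray
    radial_bin_mm: float
    kind: str = "michelogram"            # or "ssrb"
    ring_a: np.ndarray | None = None     # per-plane first ring (michelogram)
    ring_b: np.ndarray | None = None
    slice_z_mm: np.ndarray | None = None # per-plane axial position (ssrb)
    tof_bin_ps: float | None = None
    duration_s: float | None = None
    avg_activity_kbq_ml: float | None = None
    n_discarded: int = 0

    @property
    def n_radial(self) -> int:
        return self.counts.shape[0]

    @property
    def n_planes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_views(self) -> int:
        return self.counts.shape[2]

    @property
    def has_tof(self) -> bool:
        return self.counts.ndim == 4

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def radial_offsets_mm(self) -> np.ndarray:
        centre = (self.n_radial - 1) / 2.0
        return (np.arange(self.n_radial) - centre) * self.radial_bin_mm

    # -- I/O: raw array + JSON metadata sidecar --------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.counts)
        meta = {
            "radial_bin_mm": self.radial_bin_mm,
            "kind": self.kind,
            "ring_a": None if self.ring_a is None else self.ring_a.tolist(),
            "ring_b": None if self.ring_b is None else self.ring_b.tolist(),
            "slice_z_mm": None if self.slice_z_mm is None else self.slice_z_mm.tolist(),
            "tof_bin_ps": self.tof_bin_ps,
            "duration_s": self.duration_s,
            "avg_activity_kbq_ml": self.avg_activity_kbq_ml,
            "n_discarded": self.n_discarded,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Sinogram":
        path = Path(path)
        counts = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        for key in ("ring_a", "ring_b", "slice_z_mm"):
            if meta[key] is not None:
                meta[key] = np.asarray(meta[key])
        return cls(counts=counts, **meta)


# ---------------------------------------------------------------------------
# plane ordering
# ---------------------------------------------------------------------------

def michelogram_planes(n_rings: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ring-pair plane table ordered by segment (0, +1, -1, +2, ...).

    Returns (ring_a, ring_b, plane_of) with plane_of[rA, rB] the plane
    index of the ordered ring pair.
    """
    segments = [0]
    for d in range(1, n_rings):
        segments += [d, -d]
    ra, rb = [], []
    for d in segments:
        for r in range(n_rings):
            r2 = r + d
            if 0 <= r2 < n_rings:
                ra.append(r)
                rb.append(r2)
    ra = np.asarray(ra)
    rb = np.asarray(rb)
    plane_of = np.empty((n_rings, n_rings), dtype=np.int64)
    plane_of[ra, rb] = np.arange(len(ra))
    return ra, rb, plane_of


# ---------------------------------------------------------------------------
# transaxial LOR -> (view, radial)
# ---------------------------------------------------------------------------

def _transaxial_bins(geometry: ScannerGeometry, tpos_a: np.ndarray,
                     tpos_b: np.ndarray, n_radial: int):
    """(view, radial) indices of transaxial crystal pairs; radial = -1 when
    the offset falls outside the radial axis."""
    c = geometry.config
    n_views = c.crystals_per_ring // 2
    rc = c.ring_radius_mm + c.crystal_depth_mm / 2.0
    phi_a = geometry._phi_of_tpos(np.asarray(tpos_a, dtype=float))
    phi_b = geometry._phi_of_tpos(np.asarray(tpos_b, dtype=float))
    xa, ya = rc * np.cos(phi_a), rc * np.sin(phi_a)
    xb, yb = rc * np.cos(phi_b), rc * np.sin(phi_b)
    ux, uy = xb - xa, yb - ya
    norm = np.hypot(ux, uy)
    degenerate = norm < 1e-12  # transaxially coincident pair (purely axial LOR)
    norm = np.where(degenerate, 1.0, norm)
    ux, uy = ux / norm, uy / norm
    nx, ny = -uy, ux
    theta = np.arctan2(ny, nx)
    flip = theta < 0
    theta = np.where(flip, theta + np.pi, theta)
    nx = np.where(flip, -nx, nx)
    ny = np.where(flip, -ny, ny)
    theta = np.where(theta >= np.pi, theta - np.pi, theta)
    s = xa * nx + ya * ny
    view = np.floor(theta / (np.pi / n_views)).astype(np.int64)
    view = np.clip(view, 0, n_views - 1)
    ds = np.pi * rc / c.crystals_per_ring
    centre = (n_radial - 1) // 2
    radial = centre + np.round(s / ds).astype(np.int64)
    radial = np.where((radial >= 0) & (radial < n_radial) & ~degenerate, radial, -1)
    return view, radial, n_views


def bin_coincidences(coincidences: pd.DataFrame, geometry: ScannerGeometry,
                     tof: bool = False, n_radial: int = 415,
                     planes: str = "michelogram",
                     max_ring_difference: int | None = None,
                     tof_bin_ps: float = TOF_BIN_PS,
                     n_tof_bins: int = N_TOF_BINS,
                     duration_s: float | None = None,
                     avg_activity_kbq_ml: float | None = None) -> Sinogram:
    """Histogram coincidence list-mode into a sinogram.

    Records failing the sector-difference rule, exceeding
    ``max_ring_difference`` (when set), or falling outside the radial
    (or TOF) axis are discarded and counted in ``n_discarded``.
    """
    if planes not in ("michelogram", "ssrb"):
        raise AnalysisError(f"unknown plane layout {planes!r}")
    c = geometry.config
    ca = coincidences["crystal_a"].to_numpy().astype(np.int64, copy=False)
    cb = coincidences["crystal_b"].to_numpy().astype(np.int64, copy=False)
    keep = geometry.lor_accepted(ca, cb) if len(ca) else np.zeros(0, dtype=bool)
    if max_ring_difference is not None and len(ca):
        keep &= np.abs(geometry.ring[ca] - geometry.ring[cb]) <= max_ring_difference
    n_discarded = int(len(ca) - keep.sum())
    ca, cb = ca[keep], cb[keep]

    ring_a = geometry.ring[ca]
    ring_b = geometry.ring[cb]
    view, radial, n_views = _transaxial_bins(
        geometry, geometry.transaxial_pos[ca], geometry.transaxial_pos[cb], n_radial)
    ok = radial >= 0

    if planes == "michelogram":
        ra, rb, plane_of = michelogram_planes(c.n_rings)
        plane = plane_of[ring_a, ring_b]
        n_planes = c.n_rings**2
        slice_z = None
    else:
        plane = ring_a + ring_b
        n_planes = 2 * c.n_rings - 1
        ra = rb = None
        z_ring = geometry._z_of_ring(np.arange(c.n_rings, dtype=float))
        slice_z = np.array([
            (z_ring[s // 2] + z_ring[(s + 1) // 2]) / 2.0 for s in range(n_planes)
        ])

    if tof:
        dt = coincidences["dt_ps"].to_numpy()[keep]
        tbin = np.round(dt / tof_bin_ps).astype(np.int64) + n_tof_bins // 2
        ok &= (tbin >= 0) & (tbin < n_tof_bins)
        shape = (n_radial, n_planes, n_views, n_tof_bins)
    else:
        shape = (n_radial, n_planes, n_views)

    n_discarded += int(len(ca) - ok.sum())
    counts = np.zeros(shape, dtype=np.uint32)
    if tof:
        np.add.at(counts, (radial[ok], plane[ok], view[ok], tbin[ok]), 1)
    else:
        np.add.at(counts, (radial[ok], plane[ok], view[ok]), 1)

    rc = c.ring_radius_mm + c.crystal_depth_mm / 2.0
    return Sinogram(
        counts=counts,
        radial_bin_mm=np.pi * rc / c.crystals_per_ring,
        kind=planes,
        ring_a=ra, ring_b=rb, slice_z_mm=slice_z,
        tof_bin_ps=tof_bin_ps if tof else None,
        duration_s=duration_s,
        avg_activity_kbq_ml=avg_activity_kbq_ml,
        n_discarded=n_discarded,
    )


def ssrb(sino3d: Sinogram) -> Sinogram:
    """Single-slice rebinning: oblique plane (rA, rB) -> slice rA + rB.

    Total counts are conserved exactly (integer addition).
    """
    if sino3d.kind != "michelogram" or sino3d.ring_a is None:
        raise AnalysisError("ssrb requires a Michelogram sinogram with ring-pair metadata")
    n_rings = int(max(sino3d.ring_a.max(), sino3d.ring_b.max())) + 1
    n_slices = 2 * n_rings - 1
    slices = sino3d.ring_a + sino3d.ring_b
    shape = list(sino3d.counts.shape)
    shape[1] = n_slices
    out = np.zeros(shape, dtype=np.uint64)
    np.add.at(out.transpose(1, 0, *range(2, len(shape))), slices,
              sino3d.counts.transpose(1, 0, *range(2, len(shape))))
    return Sinogram(
        counts=out,
        radial_bin_mm=sino3d.radial_bin_mm,
        kind="ssrb",
        slice_z_mm=None,
        tof_bin_ps=sino3d.tof_bin_ps,
        duration_s=sino3d.duration_s,
        avg_activity_kbq_ml=sino3d.avg_activity_kbq_ml,
        n_discarded=sino3d.n_discarded,
    )


# ---------------------------------------------------------------------------
# randoms from singles
# ---------------------------------------------------------------------------

def rfs(singles_rates_hz: np.ndarray, two_tau_ns: float,
        geometry: ScannerGeometry, n_radial: int = 415) -> Sinogram:
    """Randoms-rate sinogram from per-crystal singles rates.

    For each accepted LOR (x, y): r_xy = 2*tau * s_x * s_y (rates in Hz,
    2*tau in seconds), binned with the coincidence convention.  Exact over
    all accepted crystal pairs, evaluated blockwise per ring pair.
    """
    rates = np.asarray(singles_rates_hz, dtype=float)
    if np.any(rates < 0):
        raise AnalysisError("singles rates must be >= 0")
    c = geometry.config
    if rates.shape != (c.n_crystals,):
        raise AnalysisError(f"expected {c.n_crystals} per-crystal rates")
    two_tau_s = two_tau_ns * 1e-9
    n_rings, n_per_ring = c.n_rings, c.crystals_per_ring

    # transaxial pair -> flat bin index (or -1), computed once
    pi_, pj_ = np.meshgrid(np.arange(n_per_ring), np.arange(n_per_ring), indexing="ij")
    pi_f, pj_f = pi_.ravel(), pj_.ravel()
    flat_i = geometry.flat_from_ring_pos(0, pi_f)
    flat_j = geometry.flat_from_ring_pos(0, pj_f)
    accepted = geometry.lor_accepted(flat_i, flat_j)  # sector rule, tpos-based
    view, radial, n_views = _transaxial_bins(geometry, pi_f, pj_f, n_radial)
    binidx = np.where(accepted & (radial >= 0), radial * n_views + view, -1)
    binidx = binidx.reshape(n_per_ring, n_per_ring)

    ra, rb, plane_of = michelogram_planes(n_rings)
    n_planes = n_rings**2
    out = np.zeros((n_radial * n_views, n_planes))
    rates_by_ring = rates[geometry._flat_from_rp]  # (n_rings, n_per_ring)
    valid = binidx >= 0
    flat_bins = binidx[valid]
    iu = np.triu_indices(n_per_ring, k=1)
    valid_u = binidx[iu] >= 0
    bins_u = binidx[iu][valid_u]
    for r1 in range(n_rings):
        s1 = rates_by_ring[r1]
        for r2 in range(r1, n_rings):
            s2 = rates_by_ring[r2]
            if r1 == r2:
                w = (s1[iu[0]] * s2[iu[1]])[valid_u]
                plane = plane_of[r1, r1]
                out[:, plane] += np.bincount(bins_u, weights=w,
                                             minlength=n_radial * n_views)
            else:
                w = np.outer(s1, s2)[valid]
                # split evenly between the (r1, r2) and (r2, r1) planes
                acc = np.bincount(flat_bins, weights=w,
                                  minlength=n_radial * n_views)
                out[:, plane_of[r1, r2]] += acc / 2.0
                out[:, plane_of[r2, r1]] += acc / 2.0
    counts = (two_tau_s * out).reshape(n_radial, n_views, n_planes).transpose(0, 2, 1)
    rc = c.ring_radius_mm + c.crystal_depth_mm / 2.0
    return Sinogram(
        counts=counts,
        radial_bin_mm=np.pi * rc / c.crystals_per_ring,
        kind="michelogram",
        ring_a=ra, ring_b=rb,
    )


# ---------------------------------------------------------------------------
# TOF mashing
# ---------------------------------------------------------------------------

def mash_tof(dt_ps: np.ndarray, factor: int = TOF_MASH_FACTOR,
             base_bin_ps: float = TOF_SAMPLING_PS) -> np.ndarray:
    """Quantise time differences to bins of width factor * base_bin_ps.

    With the defaults (C = 13, S = 13.02 ps) the bin width is 169.26 ps.
    Returns the bin-centre values.
    """
    if factor < 1:
        raise AnalysisError("mash factor must be >= 1")
    if base_bin_ps <= 0:
        raise AnalysisError("base bin must be > 0")
    width = factor * base_bin_ps
    return np.round(np.asarray(dt_ps, dtype=float) / width) * width
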