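"""End-to-end study pipelines at desk scale.

Each study reproduces the structure of the corresponding full-scale
performance test with heavily reduced statistics (a few hundred thousand
decays per frame instead of tens of millions of coincidences); the frame
schedules keep the real activities and therefore real rate physics, with
frame durations shrunk accordingly.

One global seed fans out deterministically to per-stage child seeds
(CRC32 of the stage label mixed into a SeedSequence), so every stage is
individually reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

from .digitiser import DigitiserConfig
from .geometry import ScannerGeometry, build_scanner
from .nema import (countrate_analysis, iq_analysis, sensitivity_analysis,
                   spatial_resolution_analysis, tof_analysis)
from .phantoms import (IQ_SPHERE_DIAMETERS_MM, make_iq_phantom,
                       make_point_sources, make_scatter_phantom,
                       make_sensitivity_phantom, nema_point_source_offsets)
from .recon import fbp2d, synthesise_iq_image
from .sinogram import bin_coincidences
from .transport import SimConfig, run_acquisition

__all__ = [
    "child_seed",
    "SCATTER_PHANTOM_VOLUME_ML",
    "run_countrate_study",
    "run_sensitivity_study",
    "run_tof_study",
    "run_resolution_study",
    "run_iq_study",
]

#: volume of the 70-cm polyethylene scatter phantom (pi * 101.5^2 * 700 mm^3)
SCATTER_PHANTOM_VOLUME_ML = float(np.pi * 101.5**2 * 700.0 / 1000.0)


def child_seed(seed: int, label: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    mix = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return int(mix.generate_state(1)[0] % 2**31)


def _default_geometry(geometry: ScannerGeometry | None) -> ScannerGeometry:
    return build_scanner() if geometry is None else geometry


def countrate_frame_schedule(a0_bq: float, concentrations_kbq_ml,
                             volume_ml: float, decays_per_frame: int,
                             half_life_s: float = 6586.2):
    """Frame (start, duration) schedule hitting the requested average
    activity concentrations as the source decays from ``a0_bq``."""
    lam = np.log(2.0) / half_life_s
    frames = []
    for c in sorted(concentrations_kbq_ml, reverse=True):
        a = c * 1e3 * volume_ml
        if a > a0_bq:
            raise ValueError(f"concentration {c} kBq/mL exceeds the initial activity")
        start = np.log(a0_bq / a) / lam
        frames.append((start, decays_per_frame / a))
    return frames


def run_countrate_study(seed: int, geometry: ScannerGeometry | None = None,
                        a0_bq: float = 719e6,
                        concentrations_kbq_ml=(1.0, 3.0, 6.0, 10.0, 15.0,
                                               20.0, 25.0, 31.2),
                        decays_per_frame: int = 300_000,
                        digitiser: DigitiserConfig | None = None):
    """Scatter-fraction / count-losses study on the 70-cm phantom."""
    geometry = _default_geometry(geometry)
    digi = digitiser or DigitiserConfig()
    sim = SimConfig()
    phantom = make_scatter_phantom(a0_bq)
    frames = countrate_frame_schedule(a0_bq, concentrations_kbq_ml,
                                      SCATTER_PHANTOM_VOLUME_ML,
                                      decays_per_frame, sim.half_life_s)
    results = run_acquisition(phantom, geometry, sim, digi, frames,
                              seed=child_seed(seed, "countrate"))
    sinos = []
    for fr in results:
        sino = bin_coincidences(
            fr["coincidences"], geometry, planes="ssrb",
            duration_s=fr["duration_s"],
            avg_activity_kbq_ml=fr["avg_activity_bq"] / SCATTER_PHANTOM_VOLUME_ML / 1e3)
        sinos.append(sino)
    report = countrate_analysis(sinos)
    return report, results, sinos


def run_sensitivity_study(seed: int, geometry: ScannerGeometry | None = None,
                          activity_bq: float = 3.3e6,
                          decays_per_frame: int = 200_000,
                          radial_offset_mm: float = 0.0,
                          digitiser: DigitiserConfig | None = None):
    """Multi-sleeve sensitivity study (desk-scale frame durations)."""
    geometry = _default_geometry(geometry)
    # noise/randoms are negligible at 3.3 MBq but noise injection at full
    # rate over a shortened frame would not be: scale it with the frame
    digi = digitiser or DigitiserConfig()
    sim = SimConfig()
    duration = decays_per_frame / activity_bq
    sinos, thicknesses = [], []
    for n_sleeves in range(1, 6):
        phantom = make_sensitivity_phantom(n_sleeves, activity_bq,
                                           radial_offset_mm=radial_offset_mm)
        results = run_acquisition(
            phantom, geometry, sim, digi, [(0.0, duration)],
            seed=child_seed(seed, f"sensitivity{n_sleeves}"))
        fr = results[0]
        sino = bin_coincidences(fr["coincidences"], geometry, planes="ssrb",
                                duration_s=duration)
        sinos.append(sino)
        thicknesses.append(1.25 * n_sleeves)
    return sensitivity_analysis(sinos, thicknesses, activity_bq / 1e6)


def run_tof_study(seed: int, geometry: ScannerGeometry | None = None,
                  concentrations_kbq_ml=(2.0, 8.0, 20.0),
                  decays_per_frame: int = 800_000,
                  min_events: int = 4_000,
                  digitiser: DigitiserConfig | None = None):
    """TOF-resolution study on the scatter-phantom line source."""
    geometry = _default_geometry(geometry)
    digi = digitiser or DigitiserConfig()
    sim = SimConfig()
    a0 = 719e6
    phantom = make_scatter_phantom(a0)
    frames = countrate_frame_schedule(a0, concentrations_kbq_ml,
                                      SCATTER_PHANTOM_VOLUME_ML,
                                      decays_per_frame, sim.half_life_s)
    results = run_acquisition(phantom, geometry, sim, digi, frames,
                              seed=child_seed(seed, "tof"))
    tof_frames = [{
        "coincidences": fr["coincidences"],
        "avg_activity_kbq_ml": fr["avg_activity_bq"] / SCATTER_PHANTOM_VOLUME_ML / 1e3,
    } for fr in results]
    return tof_analysis(tof_frames, geometry, line_point_mm=(0.0, -45.0, 0.0),
                        line_direction=(0.0, 0.0, 1.0), min_events=min_events)


def run_resolution_study(seed: int, geometry: ScannerGeometry | None = None,
                         decays: int = 1_200_000,
                         voxel_mm: float = 0.65,
                         output_size: int = 384,
                         max_ring_difference: int = 6,
                         digitiser: DigitiserConfig | None = None):
    """Point-source spatial-resolution study: simulate the six NEMA
    sources, bin to SSRB sinograms (ring difference capped to limit the
    radially growing SSRB axial blur), FBP the slices around each axial
    position and measure the widths."""
    from .image import ImageVolume

    geometry = _default_geometry(geometry)
    digi = digitiser or DigitiserConfig(noise_rate_hz=0.0)
    sim = SimConfig()
    positions = nema_point_source_offsets()
    phantom = make_point_sources(positions, activity_bq=1e6)
    duration = decays / phantom.total_activity_bq
    results = run_acquisition(phantom, geometry, sim, digi, [(0.0, duration)],
                              seed=child_seed(seed, "resolution"))
    sino = bin_coincidences(results[0]["coincidences"], geometry, planes="ssrb",
                            max_ring_difference=max_ring_difference)
    slice_z = sino.slice_z_mm
    centre = (105.0, 0.0)  # recon grid centred between the radial offsets

    def stack_around(z_mm: float, half_extent_mm: float = 16.0) -> ImageVolume:
        sel = np.flatnonzero(np.abs(slice_z - z_mm) <= half_extent_mm)
        slices = [fbp2d(sino.counts[:, k, :].astype(float), sino.radial_bin_mm,
                        output_size=output_size, voxel_mm=voxel_mm,
                        centre_mm=centre).values[:, :, 0]
                  for k in sel]
        vals = np.stack(slices, axis=2)
        dz = slice_z[sel[1]] - slice_z[sel[0]]
        img = ImageVolume(vals, (voxel_mm, voxel_mm, float(dz)),
                          origin_mm=(centre[0] - (output_size - 1) / 2.0 * voxel_mm,
                                     centre[1] - (output_size - 1) / 2.0 * voxel_mm,
                                     float(slice_z[sel[0]])))
        return img

    images = []
    for pos in positions:
        images.append(stack_around(pos[2]))
    return spatial_resolution_analysis(images, positions)


def run_iq_study(seed: int, background_kbq_ml: float = 5.3,
                 sphere_kbq_ml: float = 20.9, psf_fwhm_mm: float = 6.4,
                 noise_level: float = 0.05):
    """Image-quality metrics on a synthesised IEC-phantom image."""
    phantom = make_iq_phantom(background_kbq_ml * 1e3, sphere_kbq_ml * 1e3)
    rng = np.random.default_rng(child_seed(seed, "iq"))
    image = synthesise_iq_image(phantom, psf_fwhm_mm=psf_fwhm_mm,
                                noise_level=noise_level, rng=rng)
    centres = [(p.centre[0], p.centre[1]) for p in phantom.primitives
               if p.shape == "sphere"]
    return iq_analysis(image, centres, sphere_kbq_ml / background_kbq_ml)
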