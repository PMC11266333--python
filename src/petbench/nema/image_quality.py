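"""Image-quality metrics: CRC, BV, residual lung error and image roughness.

For each hot sphere j a circular ROI of the sphere's diameter is drawn on
the central sphere slice; 60 background ROIs of the same diameter (12
transaxial positions x 5 slices, template shipped as a data file) provide
the background mean C_B,j and its ROI-to-ROI standard deviation SD_j:

    CRC_j = 100 * (C_H,j / C_B,j - 1) / (a_H / a_B - 1)     [%]
    BV_j  = 100 * SD_j / C_B,j                              [%]
    IR_j  = 100 * mean over ROIs of (pixel SD / pixel mean) [%]

The residual lung error is the lung-insert ROI mean relative to the
per-slice 37-mm background mean, averaged over the analysis slices.  All
metrics are ratios and therefore invariant under global rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..errors import AnalysisError
from ..image import ImageVolume
from ..phantoms import IQ_SPHERE_DIAMETERS_MM

__all__ = ["IQReport", "iq_analysis", "background_roi_template"]

_TEMPLATE = Path(__file__).parent.parent / "data" / "iq_background_rois.yaml"
_LUNG_ROI_DIAMETER_MM = 30.0


def background_roi_template() -> tuple[list[tuple[float, float]], list[float]]:
    raw = yaml.safe_load(_TEMPLATE.read_text())
    return ([tuple(p) for p in raw["positions_mm"]],
            list(raw["slice_offsets_mm"]))


@dataclass
class IQReport:
    spheres: pd.DataFrame         # diameter, crc, bv, ir
    lung_error_pct: float
    sphere_to_background_ratio: float

    def as_dict(self) -> dict:
        return {
            "spheres": self.spheres.to_dict(orient="list"),
            "lung_error_pct": self.lung_error_pct,
            "sphere_to_background_ratio": self.sphere_to_background_ratio,
        }


def _roi_mask(image: ImageVolume, centre_xy, diameter_mm: float) -> np.ndarray:
    """2D voxel-centre mask of a circular ROI on one slice."""
    x = image.axis_coords(0)[:, None]
    y = image.axis_coords(1)[None, :]
    r = diameter_mm / 2.0
    mask = (x - centre_xy[0]) ** 2 + (y - centre_xy[1]) ** 2 <= r * r
    if not mask.any():
        raise AnalysisError(f"ROI at {centre_xy} (d={diameter_mm} mm) contains no voxels")
    edge_x = np.abs(np.asarray(centre_xy[0])) + r
    edge_y = np.abs(np.asarray(centre_xy[1])) + r
    if edge_x > abs(x).max() + image.voxel_mm[0] / 2 or edge_y > abs(y).max() + image.voxel_mm[1] / 2:
        raise AnalysisError(f"ROI at {centre_xy} (d={diameter_mm} mm) exceeds the image bounds")
    return mask


def _slice_index(image: ImageVolume, z_mm: float) -> int:
    zc = image.axis_coords(2)
    k = int(np.argmin(np.abs(zc - z_mm)))
    if abs(zc[k] - z_mm) > image.voxel_mm[2]:
        raise AnalysisError(f"no image slice near z = {z_mm} mm")
    return k


def iq_analysis(image: ImageVolume, sphere_centres_mm,
                sphere_to_background_ratio: float,
                sphere_diameters_mm=IQ_SPHERE_DIAMETERS_MM,
                lung_centre_xy=(0.0, 0.0),
                central_z_mm: float = 0.0) -> IQReport:
    """Contrast recovery, background variability, image roughness and
    residual lung error of a reconstructed/synthesised IQ-phantom image.

    ``sphere_centres_mm`` are the (x, y) positions of the six spheres on
    the central slice, ordered like ``sphere_diameters_mm``;
    ``sphere_to_background_ratio`` is the true a_H/a_B.
    """
    if sphere_to_background_ratio == 1.0:
        raise AnalysisError("a_H/a_B = 1 leaves the CRC undefined")
    if len(sphere_centres_mm) != len(sphere_diameters_mm):
        raise AnalysisError("sphere centres and diameters differ in length")
    positions, slice_offsets = background_roi_template()
    k0 = _slice_index(image, central_z_mm)
    slice_ids = [_slice_index(image, central_z_mm + dz) for dz in slice_offsets]

    rows = []
    lung_ratios = []
    bg37_by_slice: dict[int, float] = {}
    for diam, centre in zip(sphere_diameters_mm, sphere_centres_mm):
        hot = _roi_mask(image, centre, diam)
        c_hot = float(image.values[:, :, k0][hot].mean())
        means, roughness = [], []
        for k in slice_ids:
            plane = image.values[:, :, k]
            for pos in positions:
                m = _roi_mask(image, pos, diam)
                vals = plane[m]
                means.append(vals.mean())
                mean = vals.mean()
                roughness.append(vals.std(ddof=1) / mean if mean != 0 else 0.0)
        means = np.asarray(means)
        c_bg = float(means.mean())
        sd = float(means.std(ddof=1))
        if diam == max(sphere_diameters_mm):
            # per-slice 37-mm background means for the lung-error ratio
            per_slice = np.asarray(means).reshape(len(slice_ids), len(positions))
            for k, row in zip(slice_ids, per_slice):
                bg37_by_slice[k] = float(row.mean())
        rows.append({
            "diameter_mm": diam,
            "crc_pct": 100.0 * (c_hot / c_bg - 1.0) / (sphere_to_background_ratio - 1.0),
            "bv_pct": 100.0 * sd / c_bg,
            "ir_pct": 100.0 * float(np.mean(roughness)),
        })
    for k in slice_ids:
        lung = _roi_mask(image, lung_centre_xy, _LUNG_ROI_DIAMETER_MM)
        lung_mean = float(image.values[:, :, k][lung].mean())
        lung_ratios.append(lung_mean / bg37_by_slice[k])
    return IQReport(
        spheres=pd.DataFrame(rows),
        lung_error_pct=100.0 * float(np.mean(lung_ratios)),
        sphere_to_background_ratio=float(sphere_to_background_ratio),
    )
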