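"""Interpolated peak-width estimation shared by the resolution and TOF
analyses.

The peak value is refined by a parabolic fit through the three samples
around the maximum; the width at a given fraction of the peak is found by
linear interpolation between the samples straddling the threshold on each
side.  On a noiseless triangular profile the estimator is exact; on
sampled Gaussians its bias is below 1% of the FWHM for sampling finer
than about half the FWHM.
"""

from __future__ import annotations

import numpy as np

from ..errors import AnalysisError

__all__ = ["parabolic_peak", "profile_width", "fwhm_fwtm"]

GAUSSIAN_FWTM_OVER_FWHM = float(np.sqrt(np.log(10.0) / np.log(2.0)))  # ~1.823


def parabolic_peak(y: np.ndarray, i: int) -> float:
    """Peak value from a parabola through (i-1, i, i+1)."""
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a local maximum shape; fall back to the sample
        return float(y1)
    return float(y1 - (y2 - y0) ** 2 / (8.0 * denom))


def profile_width(x: np.ndarray, y: np.ndarray, fraction: float) -> float:
    """Width of the profile y(x) at ``fraction`` of its (refined) peak."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(y) < 3:
        raise AnalysisError("profile must have >= 3 samples")
    if not np.any(y > 0):
        raise AnalysisError("profile is empty (all-zero)")
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        raise AnalysisError("profile peak lies on the border")
    level = fraction * parabolic_peak(y, i)

    def crossing(direction: int) -> float:
        j = i
        while 0 <= j + direction < len(y):
            k = j + direction
            if y[k] < level:
                # interpolate between j (>= level) and k (< level)
                return x[j] + (x[k] - x[j]) * (y[j] - level) / (y[j] - y[k])
            j = k
        raise AnalysisError(
            f"profile does not fall below {fraction:.2f} of the peak "
            "within the sampled range")

    return crossing(+1) - crossing(-1)


def fwhm_fwtm(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Full widths at half and tenth maximum."""
    return profile_width(x, y, 0.5), profile_width(x, y, 0.1)
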