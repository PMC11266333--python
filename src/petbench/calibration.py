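"""Digitiser calibration procedures.

* ``fit_noise_qe``: the singles-rate linear model
  S_exp = QE * (S_sim + Noise), fitted by ordinary least squares on
  low-activity frames (unaffected by deadtime): the slope is the quantum
  efficiency and intercept/slope the background noise rate.
* ``optimise_pileup``: empirical pile-up window optimisation against a
  reference prompt-rate curve; the score of a candidate window is the
  maximum relative prompt-rate difference over the activity points.
* ``normalisation_from_sources``: component-based normalisation with a
  uniform-efficiency model: geometric factors per (radial, plane) bin
  from a high-count annulus sinogram against its analytic profile, and
  crystal efficiencies from fan-sums over a flood-source trues list-mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .geometry import ScannerGeometry
from .sinogram import Sinogram

__all__ = [
    "NoiseQEFit", "fit_noise_qe",
    "optimise_pileup",
    "NormalisationFactors", "normalisation_from_sources", "apply_normalisation",
    "annulus_expected_profile",
]


@dataclass
class NoiseQEFit:
    qe: float
    noise_hz: float
    qe_stderr: float
    noise_stderr: float
    n_frames_used: int
    low_activity_cut_hz: float | None
    flagged: bool = False  # non-physical slope/intercept

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("qe", "noise_hz", "qe_stderr", "noise_stderr",
                 "n_frames_used", "low_activity_cut_hz", "flagged")}


def fit_noise_qe(s_sim_hz, s_exp_hz, low_activity_cut_hz: float | None = None) -> NoiseQEFit:
    """OLS fit of S_exp = QE * (S_sim + Noise) over low-activity frames."""
    s_sim = np.asarray(s_sim_hz, dtype=float)
    s_exp = np.asarray(s_exp_hz, dtype=float)
    if s_sim.shape != s_exp.shape:
        raise AnalysisError("rate series differ in length")
    if low_activity_cut_hz is not None:
        keep = s_sim <= low_activity_cut_hz
        s_sim, s_exp = s_sim[keep], s_exp[keep]
    if len(s_sim) < 2:
        raise AnalysisError("at least two low-activity frames are required")
    res = stats.linregress(s_sim, s_exp)
    qe = float(res.slope)
    flagged = qe <= 0
    noise = float(res.intercept / res.slope) if not flagged else float("nan")
    # delta-method standard error of intercept/slope
    if not flagged and np.isfinite(res.stderr) and res.stderr > 0:
        noise_se = float(abs(noise) * np.hypot(res.intercept_stderr / res.intercept
                                               if res.intercept else 0.0,
                                               res.stderr / res.slope))
    else:
        noise_se = float("nan")
    return NoiseQEFit(
        qe=qe, noise_hz=noise,
        qe_stderr=float(res.stderr) if res.stderr is not None else float("nan"),
        noise_stderr=noise_se,
        n_frames_used=len(s_sim),
        low_activity_cut_hz=low_activity_cut_hz,
        flagged=flagged,
    )


def optimise_pileup(reference, simulator, candidate_windows_ns, seed: int = 0):
    """Choose the pile-up window best reproducing a reference prompt-rate
    curve.

    Parameters
    ----------
    reference : (activities, prompt_rates) arrays over >= 3 activity points.
    simulator : callable(window_ns, activity, seed) -> prompt rate.
    candidate_windows_ns : >= 2 candidate windows (a single candidate is
        returned trivially with its score).

    Returns
    -------
    (best_window_ns, table) where table lists per-candidate scores
    (max relative prompt-rate difference); failed candidates are recorded
    with a NaN score and skipped.
    """
    activities, ref_rates = (np.asarray(a, dtype=float) for a in reference)
    if len(activities) < 3:
        raise AnalysisError("reference curve needs >= 3 activity points")
    if np.any(ref_rates <= 0):
        raise AnalysisError("reference prompt rates must be positive")
    rows = []
    for w in candidate_windows_ns:
        try:
            sim = np.array([simulator(w, a, seed) for a in activities], dtype=float)
            score = float(np.max(np.abs(sim - ref_rates) / ref_rates))
            rows.append({"window_ns": w, "score": score, "failed": False})
        except Exception as exc:  # candidate skipped, recorded
            rows.append({"window_ns": w, "score": float("nan"),
                         "failed": True, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise AnalysisError("every candidate window failed to simulate")
    best = float(ok.loc[ok["score"].idxmin(), "window_ns"])
    return best, table


# ---------------------------------------------------------------------------
# Component-based normalisation (uniform-efficiency model)
# ---------------------------------------------------------------------------

@dataclass
class NormalisationFactors:
    geometric: np.ndarray     # (n_radial, n_planes)
    efficiencies: np.ndarray  # per flat crystal id, mean 1
    n_flagged_bins: int = 0   # empty annulus-support bins set to 1

    def as_dict(self) -> dict:
        return {
            "geometric_shape": list(self.geometric.shape),
            "efficiency_mean": float(self.efficiencies.mean()),
            "n_flagged_bins": self.n_flagged_bins,
        }


def annulus_expected_profile(radial_offsets_mm: np.ndarray,
                             radius_mm: float = 320.0,
                             wall_mm: float = 1.0) -> np.ndarray:
    """Analytic radial projection of a thin annulus source.

    The line integral through a shell of outer radius Ro and inner radius
    Ri at radial offset s is 2*(sqrt(Ro^2 - s^2) - sqrt(max(Ri^2 - s^2, 0))).
    """
    s = np.abs(np.asarray(radial_offsets_mm, dtype=float))
    ro = radius_mm + wall_mm / 2.0
    ri = radius_mm - wall_mm / 2.0
    outer = np.sqrt(np.clip(ro * ro - s * s, 0.0, None))
    inner = np.sqrt(np.clip(ri * ri - s * s, 0.0, None))
    return 2.0 * (outer - inner)


def normalisation_from_sources(annulus_sino: Sinogram,
                               flood_coincidences: pd.DataFrame,
                               geometry: ScannerGeometry,
                               annulus_radius_mm: float = 320.0,
                               annulus_wall_mm: float = 1.0) -> NormalisationFactors:
    """Geometric factors from the annulus, crystal efficiencies by
    fan-sums from the flood trues.

    Geometric factor g(r, p) = expected(r) * scale_p / measured(r, p),
    with the per-plane scale matching total counts; bins on the annulus
    support with no counts are flagged and set to 1.
    """
    if annulus_sino.total == 0 or flood_coincidences.empty:
        raise AnalysisError("annulus and flood inputs must be non-empty")
    counts = annulus_sino.counts.astype(float)
    profile = counts.sum(axis=2)  # (radial, planes)
    expected = annulus_expected_profile(annulus_sino.radial_offsets_mm,
                                        annulus_radius_mm, annulus_wall_mm)
    support = expected > 0
    geometric = np.ones_like(profile)
    n_flagged = 0
    for p in range(profile.shape[1]):
        meas = profile[:, p]
        tot = meas[support].sum()
        if tot == 0:
            continue
        scale = tot / expected[support].sum()
        empty = support & (meas == 0)
        n_flagged += int(empty.sum())
        ok = support & (meas > 0)
        geometric[ok, p] = expected[ok] * scale / meas[ok]

    fan = np.bincount(flood_coincidences["crystal_a"],
                      minlength=geometry.config.n_crystals).astype(float)
    fan += np.bincount(flood_coincidences["crystal_b"],
                       minlength=geometry.config.n_crystals)
    mean = fan[fan > 0].mean()
    eff = np.where(fan > 0, fan / mean, 1.0)
    eff /= eff.mean()
    return NormalisationFactors(geometric=geometric, efficiencies=eff,
                                n_flagged_bins=n_flagged)


def apply_normalisation(sino: Sinogram, factors: NormalisationFactors) -> np.ndarray:
    """Multiply a sinogram by the geometric factors (broadcast over views)."""
    return sino.counts.astype(float) * factors.geometric[:, :, None]
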