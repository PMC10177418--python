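"""Semiquantitative concentration estimation and limit of detection.

A saturating response curve (Coomassie band area vs concentration) is
fitted to a dilution series, inverted for concentration estimates, and
used to derive a limit of detection as the smallest concentration whose
predicted signal reaches ``k`` times the noise level.  Concentrations
estimated against an albumin curve are albumin-equivalent: Coomassie
staining is not uniform across proteins, so a protein staining at half
the albumin response reads out at roughly twice its true concentration.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ConcentrationCurve",
    "fit_concentration_curve",
    "estimate_concentration",
    "estimate_lod",
]


@dataclass(frozen=True)
class ConcentrationCurve:
    """Invertible response model mapping mg/L to densitometric signal.

    ``kind`` is "saturating" (s = s_max * c / (c + k_half)) or "linear"
    (s = slope * c, the low-concentration limit).  The response passes
    through the origin and is strictly increasing over the calibration
    range.
    """

    kind: str                     # "saturating" | "linear"
    params: tuple                 # (s_max, k_half) or (slope,)
    conc_range: tuple             # (min, max) calibrated mg/L
    residual_rms: float = 0.0
    lod_mg_per_l: float | None = None

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        if self.kind == "saturating":
            s_max, k_half = self.params
            return s_max * c / (c + k_half)
        (slope,) = self.params
        return slope * c

    def invert(self, signal_value: float) -> float:
        """Concentration whose predicted signal equals ``signal_value``."""
        if signal_value < 0:
            raise ValueError("signal must be >= 0")
        if self.kind == "saturating":
            s_max, k_half = self.params
            if signal_value >= s_max:
                return math.inf
            return k_half * signal_value / (s_max - signal_value)
        (slope,) = self.params
        return signal_value / slope

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "params": list(self.params),
                "conc_range": list(self.conc_range),
                "residual_rms": self.residual_rms,
                "lod_mg_per_l": self.lod_mg_per_l,
            },
            indent=2,
        )


def fit_concentration_curve(points, kind: str = "saturating") -> ConcentrationCurve:
    """Least-squares fit of the response model to (mg/L, signal) points.

    Needs >= 3 points with distinct positive concentrations.  A point
    set that is non-monotone beyond its residual scatter triggers a
    warning with residual diagnostics rather than a silent fit.
    """
    pts = sorted((float(c), float(s)) for c, s in points)
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration points")
    conc = np.array([c for c, _ in pts])
    sig = np.array([s for _, s in pts])
    if np.any(conc <= 0) or len(set(conc)) != len(conc):
        raise ValueError("concentrations must be distinct and positive")

    if kind == "linear":
        slope = float(np.dot(conc, sig) / np.dot(conc, conc))
        params: tuple = (slope,)
        fitted = slope * conc
    elif kind == "saturating":
        s_guess = float(sig.max() * 2.0)
        k_guess = float(np.median(conc))
        (s_max, k_half), _ = optimize.curve_fit(
            lambda c, s, k: s * c / (c + k),
            conc,
            sig,
            p0=(s_guess, k_guess),
            bounds=((1e-9, 1e-9), (np.inf, np.inf)),
            maxfev=10000,
        )
        params = (float(s_max), float(k_half))
        fitted = s_max * conc / (conc + k_half)
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    resid = sig - fitted
    rms = float(np.sqrt(np.mean(resid**2)))
    drops = np.diff(sig)
    if np.any(drops < -0.1 * float(sig.max())):
        warnings.warn(
            f"response not monotone beyond noise (residual rms {rms:.3g}); "
            f"signal diffs: {np.round(drops, 3).tolist()}",
            stacklevel=2,
        )
    return ConcentrationCurve(
        kind=kind,
        params=params,
        conc_range=(float(conc.min()), float(conc.max())),
        residual_rms=rms,
    )


def estimate_concentration(curve: ConcentrationCurve, signal_value: float):
    """Invert the response curve for a band signal.

    Returns ``(conc_mg_per_l, qualifier)`` with qualifier one of
    "quantified", "below_LOD", "above_range".  Concentrations from an
    albumin-fitted curve are albumin-equivalent.
    """
    if signal_value < 0:
        raise ValueError("negative signal")
    conc = curve.invert(signal_value)
    lod = curve.lod_mg_per_l
    if lod is not None and conc < lod:
        return conc, "below_LOD"
    if signal_value == 0.0:
        return 0.0, "below_LOD"
    if not math.isfinite(conc) or conc > curve.conc_range[1]:
        return conc, "above_range"
    return conc, "quantified"


def estimate_lod(curve: ConcentrationCurve, noise_sd: float, k: float = 3.0) -> float:
    """Limit of detection: smallest c with predicted signal >= k * noise_sd.

    ``noise_sd`` is the noise level in the curve's signal units (for
    band areas: per-sample amplitude noise times band_sigma*sqrt(2*pi)).
    For a linear response of slope m this is exactly k*noise_sd/m; for
    the saturating model the threshold is inverted in closed form.  A
    response that saturates below the threshold has no LOD and raises.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    threshold = k * noise_sd
    if curve.kind == "saturating":
        s_max = curve.params[0]
        if threshold >= s_max:
            raise ValueError(
                f"response saturates at {s_max:.3g} below the detection "
                f"threshold {threshold:.3g}: no LOD"
            )
    return float(curve.invert(threshold))
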