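"""Molecular-weight calibration from ladder migrations.

Fits log10(MW) as a polynomial in relative migration (Rf) from a marker
ladder, estimates band MWs by evaluating the curve, and supports an
affine internal-standard correction in log10-MW space: commercial
prestained standards migrate differently from urinary proteins, so
anchoring on proteins known to be present in the sample (albumin, the
immunoglobulin free-light-chain dimer/monomer) removes the systematic
bias of the commercial curve.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .densitometry import Band

__all__ = [
    "LadderSpec",
    "CalibrationCurve",
    "fit_mw_curve",
    "estimate_mw",
    "calibrate_internal",
    "annotate_mw",
]

_MONOTONE_GRID = 512


@dataclass(frozen=True)
class LadderSpec:
    """A molecular-weight marker ladder (kDa values, heaviest first)."""

    marker_kda: tuple
    name: str = "ladder"

    def __post_init__(self):
        mws = tuple(float(m) for m in self.marker_kda)
        if len(mws) < 2:
            raise ValueError("a ladder needs at least 2 markers")
        if any(not (1.0 < m < 1000.0) for m in mws):
            raise ValueError("marker MWs must lie in (1, 1000) kDa")
        ordered = tuple(sorted(mws, reverse=True))
        if len(set(ordered)) != len(ordered):
            raise ValueError("duplicate marker MWs")
        object.__setattr__(self, "marker_kda", ordered)

    @classmethod
    def from_csv(cls, path, name=None) -> "LadderSpec":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(tuple(df["marker_kda"]), name=name or str(path))


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map Rf -> log10(MW/kDa), a degree-d polynomial fit."""

    coeffs: tuple                 # numpy polyval order (highest degree first)
    degree: int
    rf_range: tuple               # (rf_min, rf_max) of the fitted support
    residual_rms: float           # in log10(MW) units
    residuals: tuple = ()

    def log10_mw(self, rf) -> np.ndarray:
        return np.polyval(self.coeffs, np.asarray(rf, dtype=float))

    @property
    def mw_range(self) -> tuple:
        lo = 10.0 ** float(self.log10_mw(self.rf_range[1]))
        hi = 10.0 ** float(self.log10_mw(self.rf_range[0]))
        return (lo, hi)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "polynomial" if self.degree > 1 else "linear",
                "degree": self.degree,
                "coefficients": list(self.coeffs),
                "rf_range": list(self.rf_range),
                "residual_rms": self.residual_rms,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        return cls(
            coeffs=tuple(d["coefficients"]),
            degree=int(d["degree"]),
            rf_range=tuple(d["rf_range"]),
            residual_rms=float(d["residual_rms"]),
        )


def _is_monotone_decreasing(coeffs, rf_range) -> bool:
    grid = np.linspace(rf_range[0], rf_range[1], _MONOTONE_GRID)
    vals = np.polyval(coeffs, grid)
    return bool(np.all(np.diff(vals) < 0))


def fit_mw_curve(pairs, degree: int = 3) -> CalibrationCurve:
    """Least-squares fit of log10(MW) on Rf from (MW kDa, Rf) pairs.

    Monotonicity (MW strictly decreasing with Rf) is verified on a dense
    grid of the fitted Rf range; a non-monotone fit falls back to the
    next lower degree with a warning.  Input pairs themselves must be
    consistent (Rf strictly increasing as MW decreases).
    """
    pairs = sorted(((float(m), float(r)) for m, r in pairs), key=lambda p: p[1])
    if len(pairs) < 2:
        raise ValueError("need at least 2 (MW, Rf) pairs")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    for (m1, r1), (m2, r2) in zip(pairs, pairs[1:]):
        if not (m1 > m2):
            raise ValueError(
                f"non-monotone input pairs: MW {m1} at Rf {r1} vs MW {m2} at Rf {r2}"
            )
    rf = np.array([r for _, r in pairs])
    logmw = np.log10([m for m, _ in pairs])
    rf_range = (float(rf.min()), float(rf.max()))
    deg = min(degree, len(pairs) - 1)
    while True:
        coeffs = np.polyfit(rf, logmw, deg)
        if _is_monotone_decreasing(coeffs, rf_range) or deg == 1:
            break
        warnings.warn(
            f"degree-{deg} calibration fit is non-monotone; refitting at degree {deg - 1}",
            stacklevel=2,
        )
        deg -= 1
    resid = logmw - np.polyval(coeffs, rf)
    return CalibrationCurve(
        coeffs=tuple(float(c) for c in coeffs),
        degree=deg,
        rf_range=rf_range,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        residuals=tuple(float(r) for r in resid),
    )


def estimate_mw(curve: CalibrationCurve, rf: float, extrapolation_warn: bool = True) -> float:
    """MW (kDa) of a band at relative migration ``rf``.

    Values outside the fitted Rf range are extrapolated with a warning,
    never silently; rf outside [0, 1] is rejected.
    """
    if not (0.0 <= rf <= 1.0):
        raise ValueError(f"Rf must lie in [0, 1], got {rf}")
    lo, hi = curve.rf_range
    if extrapolation_warn and not (lo <= rf <= hi):
        warnings.warn(
            f"Rf {rf:.3f} outside the calibrated range [{lo:.3f}, {hi:.3f}]; extrapolating",
            stacklevel=2,
        )
    return float(10.0 ** curve.log10_mw(rf))


def calibrate_internal(
    curve: CalibrationCurve,
    bands,
    anchors,
    rf_tol: float = 0.05,
) -> CalibrationCurve:
    """Affine correction of a curve in log10-MW space from internal anchors.

    ``anchors`` is a list of ``(expected_mw_kda, label)``.  Each anchor is
    matched to the band whose curve-estimated MW is nearest in log-space,
    provided the implied Rf discrepancy is below ``rf_tol``.  One matched
    anchor gives an offset correction; two or more give offset+scale via
    least squares.  No matched anchor returns the curve unchanged with a
    warning.  Anchor residuals never increase.
    """
    matched_pred, matched_true = [], []
    band_rfs = np.array([b.rf for b in bands], dtype=float)
    if band_rfs.size:
        pred_log = curve.log10_mw(band_rfs)
        for mw, label in anchors:
            target = math.log10(mw)
            i = int(np.argmin(np.abs(pred_log - target)))
            # translate the log-MW discrepancy into an Rf discrepancy via the
            # local slope, so the tolerance is a migration tolerance
            slope = np.polyval(np.polyder(np.poly1d(curve.coeffs)), band_rfs[i])
            drf = abs((pred_log[i] - target) / slope) if slope != 0 else math.inf
            if drf <= rf_tol:
                matched_pred.append(float(pred_log[i]))
                matched_true.append(target)
            else:
                warnings.warn(f"anchor {label} ({mw} kDa) matched no band", stacklevel=2)
    if not matched_pred:
        warnings.warn("no internal anchors matched; curve unchanged", stacklevel=2)
        return curve
    x = np.array(matched_pred)
    t = np.array(matched_true)
    if len(x) == 1:
        alpha, beta = float(t[0] - x[0]), 1.0
    else:
        beta, alpha = np.polyfit(x, t, 1)
    # corrected log10 MW = alpha + beta * old polynomial
    new_coeffs = np.array(curve.coeffs, dtype=float) * beta
    new_coeffs[-1] += alpha
    resid = t - (alpha + beta * x)
    return dataclasses.replace(
        curve,
        coeffs=tuple(float(c) for c in new_coeffs),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        residuals=tuple(float(r) for r in resid),
    )


def annotate_mw(bands, curve: CalibrationCurve) -> list[Band]:
    """Return bands with ``mw_kda`` filled from the calibration curve."""
    out = []
    for b in bands:
        rf = min(max(b.rf, 0.0), 1.0)
        out.append(
            dataclasses.replace(b, mw_kda=estimate_mw(curve, rf, extrapolation_warn=False))
        )
    return out
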