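"""End-to-end gel analysis pipeline and its configuration.

Ties the stages together: lane extraction from a gel image (or profile
CSV), background subtraction, band detection, MW calibration from a
ladder lane, optional internal-anchor correction, reference annotation,
pattern classification, and an optional cohort summary.  Every stage's
intermediate artifact is written next to the final reports so each step
can be rerun or inspected in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, calibration, classify, densitometry

__all__ = ["PipelineConfig", "LaneReport", "run_pipeline", "profiles_to_csv", "profiles_from_csv"]

SCHEMA_TAG = "uripage/report-v1"


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters for every pipeline stage."""

    min_snr: float = densitometry.DEFAULT_MIN_SNR
    min_prominence: float = 0.0
    background_window: int = densitometry.DEFAULT_BACKGROUND_WINDOW
    smooth_sigma: float = densitometry.DEFAULT_SMOOTH_SIGMA
    band_sigma: float = densitometry.DEFAULT_BAND_SIGMA
    calibration_degree: int = 3
    anchors: tuple = ()               # ((mw_kda, label), ...) internal standards
    match_rel_tol: float = 0.10
    classifier: classify.ClassifierConfig = field(default_factory=classify.ClassifierConfig)
    ladder_lane: int = 0              # index of the ladder lane in the image
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.min_snr < 0 or self.min_prominence < 0:
            raise ValueError("detection thresholds must be >= 0")
        if self.background_window < 3:
            raise ValueError("background window must be >= 3")
        if self.calibration_degree < 1:
            raise ValueError("calibration degree must be >= 1")
        if not (0 < self.match_rel_tol <= 0.5):
            raise ValueError("match_rel_tol must lie in (0, 0.5]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["anchors"] = [list(a) for a in self.anchors]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "classifier" in d:
            d["classifier"] = classify.ClassifierConfig(
                **{
                    k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                    if isinstance(v, list)
                    else v
                    for k, v in d["classifier"].items()
                }
            )
        if "anchors" in d:
            d["anchors"] = tuple((float(m), str(lbl)) for m, lbl in d["anchors"])
        return cls(**d)


@dataclass(frozen=True)
class LaneReport:
    lane_id: str
    call: classify.PatternCall | None
    bands: tuple
    error: str | None = None

    def to_dict(self) -> dict:
        d = {
            "schema": SCHEMA_TAG,
            "lane_id": self.lane_id,
            "error": self.error,
            "bands": [
                {
                    "center": a.band.center,
                    "rf": a.band.rf,
                    "mw_kda": a.band.mw_kda,
                    "integrated_signal": a.band.integrated_signal,
                    "snr": a.band.snr,
                    "matches": [ref.name for ref, _ in a.matches],
                }
                for a in self.bands
            ],
        }
        if self.call is not None:
            d["pattern"] = {
                "primary": self.call.primary,
                "grade": self.call.grade,
                "tubular_sublabel": self.call.tubular_sublabel,
                "overload_flags": sorted(self.call.overload_flags),
                "notes": list(self.call.notes),
            }
        return d


def profiles_to_csv(profiles, path) -> None:
    """Write lane profiles as long-format CSV (lane_id, position, signal)."""
    frames = [
        pd.DataFrame(
            {"lane_id": p.lane_id, "position": np.arange(len(p.signal)), "signal": p.signal}
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def profiles_from_csv(path) -> list[densitometry.LaneProfile]:
    df = pd.read_csv(path)
    out = []
    for lane_id, g in df.groupby("lane_id", sort=False):
        g = g.sort_values("position")
        out.append(densitometry.LaneProfile(g["signal"].to_numpy(), lane_id=str(lane_id)))
    return out


def _bands_frame(lane_bands: dict) -> pd.DataFrame:
    rows = []
    for lane_id, bands in lane_bands.items():
        for b in bands:
            rows.append(
                {
                    "lane_id": lane_id,
                    "center": b.center,
                    "rf": b.rf,
                    "mw_kda": b.mw_kda,
                    "integrated_signal": b.integrated_signal,
                    "prominence": b.prominence,
                    "width": b.width,
                    "snr": b.snr,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lane_id", "center", "rf", "mw_kda",
            "integrated_signal", "prominence", "width", "snr",
        ],
    )


def run_pipeline(
    source,
    ladder: calibration.LadderSpec,
    reference=None,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> dict:
    """Run the full analysis on a gel image or a list of lane profiles.

    ``source`` is an image path, a 2-D array in signal polarity, or a
    list of :class:`~uripage.densitometry.LaneProfile`.  The ladder lane
    (``config.ladder_lane``) provides the MW calibration; the remaining
    lanes are analyzed and classified.  Per-lane failures are isolated
    into the lane's report rather than aborting the run.

    Returns ``{"lanes": [LaneReport...], "curve": CalibrationCurve,
    "bands": DataFrame}`` and, if ``out_dir`` is given, writes
    profiles.csv, bands.csv, curve.json and classification.json there.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"gel image not found: {path}")
        image = densitometry.load_gel_image(path)
        profiles = densitometry.extract_lane_profiles(image)
    elif isinstance(source, np.ndarray):
        profiles = densitometry.extract_lane_profiles(source)
    else:
        profiles = list(source)
    if not profiles:
        raise ValueError("no lanes found in input")
    if not (0 <= config.ladder_lane < len(profiles)):
        raise ValueError(
            f"ladder lane index {config.ladder_lane} out of range for {len(profiles)} lanes"
        )
    if reference is None:
        reference = annotation.load_reference_table()

    subtracted = [
        densitometry.subtract_background(p, window=config.background_window) for p in profiles
    ]
    detected = {
        p.lane_id: densitometry.detect_bands(
            p,
            min_snr=config.min_snr,
            min_prominence=config.min_prominence,
            smooth_sigma=config.smooth_sigma,
            band_sigma=config.band_sigma,
        )
        for p in subtracted
    }

    ladder_profile = subtracted[config.ladder_lane]
    ladder_bands = detected[ladder_profile.lane_id]
    curve = _fit_ladder(ladder_bands, ladder, degree=config.calibration_degree)

    reports = []
    lane_bands_mw: dict = {}
    for i, prof in enumerate(subtracted):
        if i == config.ladder_lane:
            lane_bands_mw[prof.lane_id] = calibration.annotate_mw(
                detected[prof.lane_id], curve
            )
            continue
        try:
            bands = calibration.annotate_mw(detected[prof.lane_id], curve)
            lane_curve = curve
            if config.anchors:
                lane_curve = calibration.calibrate_internal(curve, bands, config.anchors)
                bands = calibration.annotate_mw(detected[prof.lane_id], lane_curve)
            lane_bands_mw[prof.lane_id] = bands
            annots = (
                annotation.match_bands(bands, reference, rel_tol=config.match_rel_tol)
                if bands
                else []
            )
            call = classify.classify_lane(bands, config.classifier)
            reports.append(LaneReport(prof.lane_id, call, tuple(annots)))
        except Exception as exc:  # noqa: BLE001 - per-lane isolation is the contract
            lane_bands_mw.setdefault(prof.lane_id, [])
            reports.append(LaneReport(prof.lane_id, None, (), error=str(exc)))

    bands_df = _bands_frame(lane_bands_mw)
    result = {"lanes": reports, "curve": curve, "bands": bands_df}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        profiles_to_csv(subtracted, out / "profiles.csv")
        bands_df.to_csv(out / "bands.csv", index=False, float_format="%.6g")
        (out / "curve.json").write_text(curve.to_json())
        (out / "classification.json").write_text(
            json.dumps(
                {"schema": SCHEMA_TAG, "lanes": [r.to_dict() for r in reports]}, indent=2
            )
        )
    return result


def _fit_ladder(
    ladder_bands, ladder: calibration.LadderSpec, degree: int
) -> calibration.CalibrationCurve:
    """Pair detected ladder bands with marker MWs and fit the curve.

    The heaviest marker pairs with the smallest Rf.  If more bands than
    markers were detected, the strongest ``len(markers)`` bands are used.
    """
    markers = ladder.marker_kda
    bands = sorted(ladder_bands, key=lambda b: -b.integrated_signal)[: len(markers)]
    bands.sort(key=lambda b: b.center)
    if len(bands) < len(markers):
        warnings.warn(
            f"detected {len(bands)} ladder bands for {len(markers)} markers; "
            "fitting on the detected subset",
            stacklevel=2,
        )
        markers = markers[: len(bands)]
    pairs = list(zip(markers, (b.rf for b in bands)))
    return calibration.fit_mw_curve(pairs, degree=degree)
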