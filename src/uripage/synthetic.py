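"""Synthetic gel-lane generator with fully known ground truth.

Emulates Coomassie-stained 4-20% gradient-gel separations of urine
proteins: each protein in a lane composition is placed by a monotone
MW -> relative-migration map, given a Gaussian band whose area follows a
saturating stain-response curve, and summed onto a smooth background with
additive Gaussian noise.  Everything downstream (densitometry, MW
calibration, pattern classification, LOD estimation) is tested against
the truth records emitted here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LaneComposition",
    "GelModel",
    "TruthBand",
    "TruthRecord",
    "SampleMeta",
    "generate_lane",
    "generate_dilution_series",
    "generate_cohort",
    "render_gel_image",
    "PATTERN_TEMPLATES",
]

# Molecular weights (kDa) used by the built-in compositions; these are the
# values carried by the packaged reference table.
MW = {
    "albumin": 69.23,
    "transferrin": 77.01,
    "ceruloplasmin": 122.13,
    "flc_dimer": 46.0,
    "flc_monomer": 23.0,
    "kappa_light_chain": 23.36,
    "ambp": 38.97,
    "zag": 34.24,
    "apo_a1": 30.76,
    "rbp4": 22.99,
    "ngal": 22.57,
    "cystatin_c": 15.79,
    "beta2_microglobulin": 13.71,
    "myoglobin": 17.17,
    "lysozyme": 16.53,
    "hemoglobin_beta": 15.99,
    "ovalbumin": 45.0,
}


@dataclass(frozen=True)
class LaneComposition:
    """Known protein content of one simulated lane.

    ``entries`` holds ``(protein_id, concentration mg/L)`` pairs where
    ``protein_id`` is either a key of :data:`MW` or an explicit
    ``(mw_kda, name)`` tuple.
    """

    entries: tuple
    sample_id: str = "sample"

    def __post_init__(self):
        for pid, conc in self.entries:
            if conc <= 0:
                raise ValueError(f"non-positive concentration for {pid!r}: {conc}")
            self.resolve_mw(pid)  # raises on unknown ids

    @staticmethod
    def resolve_mw(protein_id) -> float:
        if isinstance(protein_id, str):
            try:
                return MW[protein_id]
            except KeyError:
                raise ValueError(f"unknown protein id {protein_id!r}") from None
        mw_kda, _name = protein_id
        if mw_kda <= 0:
            raise ValueError(f"non-positive MW: {mw_kda}")
        return float(mw_kda)

    @staticmethod
    def name_of(protein_id) -> str:
        return protein_id if isinstance(protein_id, str) else str(protein_id[1])


def internal_standard_composition(sample_id: str = "internal_standard") -> LaneComposition:
    """Albumin + FLC dimer/monomer with added myoglobin and lysozyme."""
    return LaneComposition(
        entries=(
            ("albumin", 150.0),
            ("flc_dimer", 80.0),
            ("flc_monomer", 80.0),
            ("myoglobin", 60.0),
            ("lysozyme", 60.0),
        ),
        sample_id=sample_id,
    )


@dataclass(frozen=True)
class GelModel:
    """Forward model of one gradient-gel lane.

    migration_coeffs are polynomial coefficients (highest degree first)
    mapping x = log10(MW/kDa) to relative migration Rf; the default cubic
    is strictly decreasing over the 10-250 kDa working range with
    Rf(250) = 0.05 and Rf(10) = 0.95.  The stain response is a saturating
    hyperbola ``A(c) = s_max * c / (c + k_half)`` (signal area vs mg/L)
    with a linear low-concentration limit of slope ``s_max / k_half``.
    """

    migration_coeffs: tuple = (-0.05, 0.255, -1.052876338651292, 1.797876338651292)
    s_max: float = 3000.0          # saturating band area, signal units
    k_half: float = 150.0          # mg/L at half-saturation
    band_sigma: float = 6.0        # Gaussian band width, profile samples
    background_amplitude: float = 6.0
    background_slope: float = -3.0
    noise_sd: float = 1.0          # additive per-sample noise, signal units
    profile_length: int = 1200
    mw_range: tuple = (10.0, 250.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.mw_range
        grid = np.linspace(math.log10(lo), math.log10(hi), 512)
        rf = np.polyval(self.migration_coeffs, grid)
        if not np.all(np.diff(rf) < 0):
            raise ValueError("migration map must be strictly decreasing in MW")

    def migration_rf(self, mw_kda: float) -> float:
        """Relative migration of a protein of the given MW."""
        lo, hi = self.mw_range
        if not (lo <= mw_kda <= hi):
            raise ValueError(
                f"MW {mw_kda} kDa outside gel range [{lo}, {hi}] kDa"
            )
        return float(np.polyval(self.migration_coeffs, math.log10(mw_kda)))

    def stain_response(self, conc_mg_per_l: float, scale: float = 1.0) -> float:
        """Integrated band signal (area) produced by a concentration."""
        if conc_mg_per_l < 0:
            raise ValueError("concentration must be >= 0")
        return scale * self.s_max * conc_mg_per_l / (conc_mg_per_l + self.k_half)

    @property
    def noise_sd_signal(self) -> float:
        """Noise expressed in integrated-signal units.

        A Gaussian band of width sigma has peak amplitude area/(sigma*sqrt(2*pi));
        the same factor converts per-sample amplitude noise to area units.
        """
        return self.noise_sd * self.band_sigma * math.sqrt(2.0 * math.pi)

    def background(self) -> np.ndarray:
        x = np.linspace(0.0, 1.0, self.profile_length)
        return self.background_amplitude + self.background_slope * x


@dataclass(frozen=True)
class TruthBand:
    protein: str
    mw_kda: float
    rf: float
    migration: float               # profile sample index (float)
    concentration: float           # mg/L
    integrated_signal: float       # noise-free band area, signal units


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    bands: tuple                   # TruthBand, sorted by migration
    seed: int
    pattern: str | None = None     # set by generate_cohort

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical metadata carried alongside a simulated lane."""

    sample_id: str
    egfr: float | None = None      # mL/min/1.73 m^2
    icd10: str | None = None
    acr: float | None = None       # mg/g
    albumin_mg_per_l: float | None = None
    age: float | None = None
    sex: str | None = None


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def generate_lane(
    composition: LaneComposition,
    model: GelModel = GelModel(),
    seed: int = 0,
    stain_scales: dict | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """Simulate one lane profile plus its ground-truth record.

    ``stain_scales`` optionally maps protein names to a per-protein stain
    response scale factor (Coomassie staining is not uniform across
    proteins); default scale is 1 for every protein.

    Returns ``(profile, truth)`` where ``profile`` is the raw signal array
    (background + bands + noise) and truth bands are sorted by migration.
    """
    n = model.profile_length
    x = np.arange(n, dtype=float)
    profile = model.background().copy()
    bands = []
    for pid, conc in composition.entries:
        mw = LaneComposition.resolve_mw(pid)
        name = LaneComposition.name_of(pid)
        rf = model.migration_rf(mw)            # raises if MW out of range
        center = rf * (n - 1)
        scale = 1.0 if stain_scales is None else stain_scales.get(name, 1.0)
        area = model.stain_response(conc, scale)
        profile += area * _gaussian(x, center, model.band_sigma)
        bands.append(TruthBand(name, mw, rf, center, conc, area))
    bands.sort(key=lambda b: b.migration)
    rng = np.random.default_rng(seed)
    profile += rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else 0.0
    truth = TruthRecord(composition.sample_id, tuple(bands), seed)
    return profile, truth


def generate_dilution_series(
    base_conc: float,
    fold: float,
    n_steps: int,
    model: GelModel = GelModel(),
    seed: int = 0,
    protein: str = "albumin",
) -> list[tuple[np.ndarray, TruthRecord]]:
    """Geometric dilution series ``base_conc / fold**k`` for k = 0..n_steps-1.

    Mirrors the albumin dilution experiment used to establish the limit of
    detection (200 mg/L halved down to 1.56 mg/L).
    """
    if base_conc <= 0 or fold <= 1 or n_steps < 1:
        raise ValueError("need base_conc > 0, fold > 1, n_steps >= 1")
    out = []
    for k in range(n_steps):
        conc = base_conc / fold**k
        comp = LaneComposition(
            entries=((protein, conc),), sample_id=f"dilution_{k}"
        )
        out.append(generate_lane(comp, model, seed=seed + k))
    return out


# --- cohort templates -------------------------------------------------------
#
# Each template draws a composition whose band content follows the pattern
# rules: glomerular = albumin + >albumin-MW proteins; tubular = several
# <albumin-MW proteins, split at 20 kDa into "upper" (all >= 20 kDa) and
# "lower" (sub-20 kDa bands present); mixed = both; normal = trace albumin.

def _t_normal(rng):
    return [("albumin", rng.uniform(5.0, 25.0))]


def _t_glomerular(rng):
    grade = rng.integers(1, 4)
    comp = [("albumin", rng.uniform(250.0, 400.0))]
    if grade == 1:
        comp.append(("transferrin", rng.uniform(4.0, 4.3)))
    else:
        comp.append(("transferrin", rng.uniform(80.0, 160.0)))
        if grade == 3:
            comp.append(("ceruloplasmin", rng.uniform(40.0, 120.0)))
    return comp


def _upper_lmw(rng):
    # tubular indicator proteins, all >= 20 kDa
    return [
        ("ambp", rng.uniform(40.0, 120.0)),
        ("zag", rng.uniform(25.0, 80.0)),
        ("rbp4", rng.uniform(30.0, 100.0)),
    ]


def _lower_lmw(rng):
    return _upper_lmw(rng) + [
        ("cystatin_c", rng.uniform(30.0, 100.0)),
        ("beta2_microglobulin", rng.uniform(25.0, 90.0)),
    ]


def _t_tubular_upper(rng):
    return [("albumin", rng.uniform(4.0, 8.0))] + _upper_lmw(rng)


def _t_tubular_lower(rng):
    return [("albumin", rng.uniform(4.0, 8.0))] + _lower_lmw(rng)


def _t_mixed(rng):
    comp = _t_glomerular(rng)
    comp += _lower_lmw(rng) if rng.random() < 0.5 else _upper_lmw(rng)
    return comp


def _t_overload_flc(rng):
    return [
        ("albumin", rng.uniform(20.0, 60.0)),
        ("flc_dimer", rng.uniform(120.0, 300.0)),
        ("flc_monomer", rng.uniform(120.0, 300.0)),
    ]


PATTERN_TEMPLATES = {
    "normal": _t_normal,
    "glomerular": _t_glomerular,
    "tubular_upper": _t_tubular_upper,
    "tubular_lower": _t_tubular_lower,
    "mixed_glomerular_tubular": _t_mixed,
    "overload_flc": _t_overload_flc,
}

# eGFR regimes per truth pattern: (median, log-sd) of a lognormal draw,
# matching the clinical gradient (preserved filtration in "upper" tubular
# and normal samples, reduced in "lower" tubular).
_EGFR_REGIME = {
    "normal": (95.0, 0.20),
    "glomerular": (66.0, 0.45),
    "tubular_upper": (71.0, 0.40),
    "tubular_lower": (31.0, 0.55),
    "mixed_glomerular_tubular": (45.0, 0.50),
    "overload_flc": (60.0, 0.50),
}

_ICD10_POOL = {
    "normal": ["Z00.0"],
    "glomerular": ["N03.x", "N04.x", "N18.x", "E11.2"],
    "tubular_upper": ["C90.0", "C90.0", "D47.2", "N18.x"],
    "tubular_lower": ["N18.x", "N17.x", "C90.0", "Z94.0"],
    "mixed_glomerular_tubular": ["N18.x", "C90.0", "N03.x"],
    "overload_flc": ["C90.0"],
}


def generate_cohort(
    n: int,
    pattern_weights: dict,
    model: GelModel = GelModel(),
    seed: int = 0,
) -> list[tuple[np.ndarray, TruthRecord, SampleMeta]]:
    """Simulate ``n`` lanes with truth patterns drawn from ``pattern_weights``.

    Weights must cover known patterns and normalize to 1 (normalization is
    applied).  Metadata (eGFR, ICD-10) is drawn from per-pattern regimes.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    patterns = list(pattern_weights)
    unknown = set(patterns) - set(PATTERN_TEMPLATES)
    if unknown:
        raise ValueError(f"unknown patterns: {sorted(unknown)}")
    w = np.asarray([pattern_weights[p] for p in patterns], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pattern = patterns[rng.choice(len(patterns), p=w)]
        entries = tuple((pid, float(c)) for pid, c in PATTERN_TEMPLATES[pattern](rng))
        comp = LaneComposition(entries=entries, sample_id=f"S{i:04d}")
        lane_seed = int(rng.integers(0, 2**31 - 1))
        profile, truth = generate_lane(comp, model, seed=lane_seed)
        truth = dataclasses.replace(truth, pattern=pattern)
        med, sd = _EGFR_REGIME[pattern]
        egfr = float(np.exp(np.log(med) + sd * rng.standard_normal()))
        icd = _ICD10_POOL[pattern][rng.integers(0, len(_ICD10_POOL[pattern]))]
        meta = SampleMeta(sample_id=comp.sample_id, egfr=egfr, icd10=icd)
        out.append((profile, truth, meta))
    return out


def render_gel_image(
    profiles: Sequence[np.ndarray],
    lane_width: int = 24,
    gap: int = 10,
    white_level: int = 60000,
    gain: float = 100.0,
) -> np.ndarray:
    """Render lane profiles as a 16-bit grayscale gel image.

    Dark bands on a light background (higher protein signal = darker
    pixel), lanes as vertical strips left to right, migration running
    down the image.
    """
    if not profiles:
        raise ValueError("no profiles to render")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("all profiles must share a length")
    width = gap + len(profiles) * (lane_width + gap)
    img = np.full((n, width), float(white_level))
    for j, prof in enumerate(profiles):
        x0 = gap + j * (lane_width + gap)
        img[:, x0 : x0 + lane_width] = white_level - gain * np.asarray(prof)[:, None]
    return np.clip(img, 0, 65535).astype(np.uint16)
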