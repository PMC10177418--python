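"""Indicator-protein annotation of calibrated bands.

Maps estimated band MWs onto a packaged reference table of urinary
proteins (the per-fraction LC-MS/MS shortlists, with the indicator
categories used for pattern calling), and implements the shortlist
filter used to reduce per-fraction LC-MS/MS candidate lists: keep
candidates whose MW is close to the fraction MW and whose peptide
sequence match (PSM) count is high, ordered by PSM.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "ReferenceProtein",
    "CandidateProtein",
    "BandAnnotation",
    "load_reference_table",
    "reference_from_frame",
    "match_bands",
    "shortlist_fraction_proteins",
]

CATEGORIES = ("glomerular_indicator", "tubular_indicator", "overload_indicator", "other")


@dataclass(frozen=True)
class ReferenceProtein:
    name: str
    mw_kda: float
    category: str
    fraction: str = ""

    def __post_init__(self):
        if self.mw_kda <= 0:
            raise ValueError("reference MW must be positive")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class CandidateProtein:
    """An LC-MS/MS candidate identification for a gel fraction."""

    name: str
    mw_kda: float
    psm: int

    def __post_init__(self):
        if self.psm < 1:
            raise ValueError("PSM count must be >= 1")
        if self.mw_kda <= 0:
            raise ValueError("candidate MW must be positive")


@dataclass(frozen=True)
class BandAnnotation:
    """A band with its reference-protein matches, nearest first."""

    band: object                          # Band with mw_kda set
    matches: tuple                        # (ReferenceProtein, rel_dmw) pairs
    unannotated: bool

    @property
    def mw_kda(self):
        return self.band.mw_kda

    @property
    def integrated_signal(self):
        return self.band.integrated_signal

    @property
    def best_name(self):
        return None if self.unannotated else self.matches[0][0].name


def load_reference_table(path=None) -> list[ReferenceProtein]:
    """Load the reference protein table (packaged fixture by default)."""
    if path is None:
        src = resources.files("uripage").joinpath("data/reference_proteins.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return reference_from_frame(df)


def reference_from_frame(df: pd.DataFrame) -> list[ReferenceProtein]:
    out = []
    for row in df.itertuples(index=False):
        frac = "" if pd.isna(getattr(row, "fraction", "")) else str(row.fraction)
        out.append(ReferenceProtein(str(row.name), float(row.mw_kda), str(row.category), frac))
    return out


def match_bands(bands, reference, rel_tol: float = 0.10) -> list[BandAnnotation]:
    """Annotate each band with reference proteins within relative MW tolerance.

    A reference protein matches when |MW_ref - MW_band| / MW_band <= rel_tol;
    matches are sorted by relative distance.  Bands with no match are
    flagged unannotated.
    """
    if not (0.0 < rel_tol <= 0.5):
        raise ValueError("rel_tol must lie in (0, 0.5]")
    if not reference:
        raise ValueError("empty reference table")
    out = []
    for b in bands:
        if b.mw_kda is None:
            raise ValueError("bands must carry MW estimates (run calibration first)")
        matches = []
        for ref in reference:
            rel = abs(ref.mw_kda - b.mw_kda) / b.mw_kda
            if rel <= rel_tol:
                matches.append((ref, rel))
        matches.sort(key=lambda m: m[1])
        out.append(BandAnnotation(band=b, matches=tuple(matches), unannotated=not matches))
    return out


def shortlist_fraction_proteins(
    candidates,
    fraction_mw: float,
    mw_rel_tol: float = 0.25,
    min_psm: int = 10,
) -> list[CandidateProtein]:
    """Shortlist LC-MS/MS candidates for one gel fraction.

    Keeps candidates with |MW - fraction_mw| / fraction_mw <= mw_rel_tol
    and PSM >= min_psm, sorted by PSM descending; the sort is stable, so
    PSM ties keep their original order.
    """
    if fraction_mw <= 0:
        raise ValueError("fraction MW must be positive")
    kept = [
        c
        for c in candidates
        if abs(c.mw_kda - fraction_mw) / fraction_mw <= mw_rel_tol and c.psm >= min_psm
    ]
    return sorted(kept, key=lambda c: -c.psm)
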