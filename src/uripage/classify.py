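"""Rule-based proteinuria pattern classification.

Assigns each lane one primary pattern from the band content:

* glomerular — albumin above trace plus at least one band of higher MW
  (transferrin or above), graded 1-3 by transferrin intensity and the
  presence of still heavier proteins;
* tubular — low-molecular-weight (below-albumin) bands, split at 20 kDa
  into the "upper" (all LMW bands >= 20 kDa) and "lower" (sub-20 kDa
  bands present) subtypes;
* mixed glomerular-tubular — both components;
* normal — neither component (a trace albumin band at most).

Overload signatures (free-light-chain dimer+monomer pair, hemoglobin,
myoglobin, lysozyme, ovalbumin) are flagged independently by MW and
intensity matching.  "Trace" and "intense" are operationalized as
fractions of the total integrated lane signal.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ClassifierConfig",
    "PatternCall",
    "classify_lane",
    "grade_glomerular",
    "detect_overload",
]

PRIMARY_LABELS = (
    "normal",
    "glomerular",
    "tubular_upper",
    "tubular_lower",
    "mixed_glomerular_tubular",
)

OVERLOAD_FLAGS = ("flc", "hemoglobin", "myoglobin", "lysozyme", "ovalbumin")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the pattern rules.

    MW windows are in kDa.  ``trace_fraction`` and ``intense_fraction``
    are fractions of the total integrated lane signal: a band below
    trace is ignored as evidence, a band at or above intense counts as
    an "intense" band.  ``lmw_threshold`` splits the tubular subtypes.
    """

    albumin_window: tuple = (62.0, 75.0)
    transferrin_window: tuple = (75.0, 85.0)
    lmw_threshold: float = 20.0
    trace_fraction: float = 0.05
    intense_fraction: float = 0.20
    overload_rel_tol: float = 0.03
    # (flag, target MW kDa); the FLC signature is the dimer+monomer pair
    flc_dimer_mw: float = 46.0
    flc_monomer_mw: float = 23.0
    overload_targets: tuple = (
        ("hemoglobin", 15.99),
        ("myoglobin", 17.17),
        ("lysozyme", 16.53),
        ("ovalbumin", 45.0),
    )

    def __post_init__(self):
        if not (0.0 < self.trace_fraction < self.intense_fraction < 1.0):
            raise ValueError("need 0 < trace_fraction < intense_fraction < 1")
        if self.lmw_threshold <= 0:
            raise ValueError("lmw_threshold must be positive")


@dataclass(frozen=True)
class PatternCall:
    """The classified proteinuria pattern of one lane."""

    primary: str                        # one of PRIMARY_LABELS
    grade: int | None = None            # 1-3 when a glomerular component exists
    tubular_sublabel: str | None = None # "upper" | "lower" when tubular component
    overload_flags: frozenset = frozenset()
    evidence: tuple = ()                # (role, mw_kda, fraction) triples
    notes: tuple = ()

    def __post_init__(self):
        if self.primary not in PRIMARY_LABELS:
            raise ValueError(f"unknown primary label {self.primary!r}")
        glom = self.primary in ("glomerular", "mixed_glomerular_tubular")
        if glom != (self.grade is not None):
            raise ValueError("grade must be set iff a glomerular component is present")
        tub = self.primary in ("tubular_upper", "tubular_lower", "mixed_glomerular_tubular")
        if tub != (self.tubular_sublabel is not None):
            raise ValueError("sublabel must be set iff a tubular component is present")


def _mw(b) -> float:
    mw = getattr(b, "mw_kda", None)
    if mw is None:
        raise ValueError("bands must carry MW estimates")
    return float(mw)


def _fractions(bands):
    total = sum(b.integrated_signal for b in bands)
    if total <= 0:
        return [0.0 for _ in bands]
    return [b.integrated_signal / total for b in bands]


def detect_overload(bands, config: ClassifierConfig = ClassifierConfig()):
    """Overload signature flags, with the indices of the signature bands.

    The FLC flag requires a co-dominant dimer (~46 kDa) + monomer
    (~23 kDa) pair, each above trace.  Hemoglobin / myoglobin / lysozyme
    / ovalbumin require a single band at their MW at or above the
    intense fraction; every target within MW tolerance of such a band is
    flagged (the three ~16-17 kDa proteins co-migrate and cannot be told
    apart by mobility alone), except that ovalbumin is suppressed when
    the band is accounted for by the FLC dimer signature.

    Returns ``(flags, flagged_indices, notes)``.
    """
    bands = list(bands)
    fracs = _fractions(bands)
    tol = config.overload_rel_tol
    flags: set[str] = set()
    flagged: set[int] = set()
    notes: list[str] = []

    def near(mw, target):
        return abs(mw - target) / target <= tol

    dimer_idx = [
        i for i, b in enumerate(bands)
        if near(_mw(b), config.flc_dimer_mw) and fracs[i] > config.trace_fraction
    ]
    mono_idx = [
        i for i, b in enumerate(bands)
        if near(_mw(b), config.flc_monomer_mw) and fracs[i] > config.trace_fraction
    ]
    if dimer_idx and mono_idx:
        flags.add("flc")
        flagged.update(dimer_idx)
        flagged.update(mono_idx)

    for i, b in enumerate(bands):
        if fracs[i] < config.intense_fraction:
            continue
        hits = [flag for flag, target in config.overload_targets if near(_mw(b), target)]
        if "ovalbumin" in hits and "flc" in flags and i in flagged:
            hits.remove("ovalbumin")  # the ~45-46 kDa band is the FLC dimer
        if len([h for h in hits if h in ("hemoglobin", "myoglobin", "lysozyme")]) > 1:
            notes.append(
                f"band at {_mw(b):.1f} kDa compatible with co-migrating proteins: {hits}"
            )
        if hits:
            flags.update(hits)
            flagged.add(i)
    return frozenset(flags), frozenset(flagged), tuple(notes)


def grade_glomerular(bands, config: ClassifierConfig = ClassifierConfig()) -> int:
    """Severity grade of an established glomerular component.

    Grade 1: albumin with at most a trace (non-intense) transferrin band;
    grade 2: intense albumin and transferrin bands; grade 3: grade 2 plus
    any band of higher MW than transferrin.
    """
    bands = list(bands)
    fracs = _fractions(bands)
    alb_lo, alb_hi = config.albumin_window
    tf_lo, tf_hi = config.transferrin_window
    alb_frac = sum(f for b, f in zip(bands, fracs) if alb_lo <= _mw(b) <= alb_hi)
    tf_frac = sum(f for b, f in zip(bands, fracs) if tf_lo < _mw(b) <= tf_hi)
    above_tf = any(_mw(b) > tf_hi for b in bands)
    if alb_frac <= config.trace_fraction and not any(_mw(b) > alb_hi for b in bands):
        raise ValueError("no glomerular component to grade")
    if tf_frac >= config.intense_fraction:
        return 3 if above_tf else 2
    return 1


def classify_lane(bands, config: ClassifierConfig = ClassifierConfig()) -> PatternCall:
    """Apply the pattern rules to a lane's MW-annotated bands.

    ``bands`` is any sequence of objects with ``mw_kda`` and
    ``integrated_signal`` attributes (detected bands after calibration,
    or :class:`~uripage.annotation.BandAnnotation` objects).
    """
    bands = list(bands)
    notes: list[str] = []
    if not bands:
        return PatternCall(primary="normal", notes=("no bands detected: zero evidence",))

    fracs = _fractions(bands)
    flags, flagged, overload_notes = detect_overload(bands, config)
    notes.extend(overload_notes)
    alb_lo, alb_hi = config.albumin_window

    albumin_frac = sum(f for b, f in zip(bands, fracs) if alb_lo <= _mw(b) <= alb_hi)
    higher = [b for b in bands if _mw(b) > alb_hi]

    # FLC-pure lanes (dimer+monomer and nothing else below albumin) do not
    # count their signature bands as tubular LMW evidence; lanes with other
    # LMW proteins alongside the FLC pair do.
    lmw_idx = [i for i, b in enumerate(bands) if _mw(b) < alb_lo]
    flc_pure = "flc" in flags and all(i in flagged for i in lmw_idx)
    evidence_lmw = [
        bands[i]
        for i in lmw_idx
        if fracs[i] > config.trace_fraction and not (flc_pure and i in flagged)
    ]
    if flc_pure and lmw_idx:
        notes.append("free-light-chain dimer+monomer signature excluded from LMW evidence")

    lmw_present = bool(evidence_lmw)
    glom_present = albumin_frac > config.trace_fraction and bool(higher)

    evidence = tuple(
        (
            "albumin" if alb_lo <= _mw(b) <= alb_hi else ("hmw" if _mw(b) > alb_hi else "lmw"),
            round(_mw(b), 2),
            round(f, 4),
        )
        for b, f in zip(bands, fracs)
    )

    if glom_present and lmw_present:
        primary = "mixed_glomerular_tubular"
    elif lmw_present:
        primary = "tubular"
    elif glom_present:
        primary = "glomerular"
    else:
        primary = "normal"
        if albumin_frac > config.intense_fraction:
            notes.append("isolated albuminuria: albumin band without higher-MW or LMW bands")

    sublabel = None
    if lmw_present:
        sublabel = (
            "lower"
            if any(_mw(b) < config.lmw_threshold for b in evidence_lmw)
            else "upper"
        )
    if primary == "tubular":
        primary = f"tubular_{sublabel}"

    grade = grade_glomerular(bands, config) if glom_present else None
    return PatternCall(
        primary=primary,
        grade=grade,
        tubular_sublabel=sublabel,
        overload_flags=flags,
        evidence=evidence,
        notes=tuple(notes),
    )
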