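"""Cohort-level contingency and rank statistics.

2x2 tables of diagnosis group vs proteinuria pattern are tested with the
Pearson chi-square test, routed to the Fisher exact test whenever any
expected count falls below 5 (the boundary value 5 itself stays with
Pearson).  The two-sided Fisher p-value follows the probability-mass
convention — the sum of hypergeometric probabilities of all tables with
the observed margins that are no more probable than the observed table —
computed by exact integer enumeration.  Group comparisons of eGFR use
Mann-Whitney (2 groups) or Kruskal-Wallis (>= 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyResult",
    "pearson_chi2",
    "fisher_exact",
    "contingency_test",
    "rank_tests",
    "summarize_cohort",
    "format_p",
]


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple                 # ((a, b), (c, d))
    test: str                    # "pearson_chi2" | "fisher_exact"
    statistic: float | None      # chi-square value (None for Fisher)
    p_value: float
    min_expected: float


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
    return t.astype(np.int64)


def _expected(t: np.ndarray) -> np.ndarray:
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / n


def pearson_chi2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table: (statistic, p).

    The classic sum of (O-E)^2/E with p from chi-square(1 df); no
    continuity correction.  Zero marginals are rejected.
    """
    t = _check_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass rule).

    With fixed margins every candidate table shares the hypergeometric
    denominator C(n, c1), so tables are compared by their exact integer
    numerators C(r1, k) * C(r2, c1 - k): the p-value is the (exact
    rational) sum of probabilities <= the observed one, returned as a
    float.  Degenerate margins give p = 1.
    """
    t = _check_table(table)
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    obs = math.comb(r1, int(t[0, 0])) * math.comb(r2, c1 - int(t[0, 0]))
    num = 0
    for k in range(k_lo, k_hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs:
            num += w
    denom = math.comb(n, c1)
    # exact rational num/denom; Fraction-free float conversion is fine at
    # these magnitudes (both fit in ~60-bit integers for cohort-sized tables)
    return num / denom


def contingency_test(table) -> ContingencyResult:
    """Route a 2x2 table to Pearson chi-square or Fisher exact.

    Fisher is used iff the minimum expected count is < 5; an expected
    count of exactly 5 stays with Pearson.
    """
    t = _check_table(table)
    min_exp = float(_expected(t).min())
    if min_exp < 5.0:
        p = fisher_exact(t)
        return ContingencyResult(
            table=tuple(map(tuple, t.tolist())),
            test="fisher_exact",
            statistic=None,
            p_value=p,
            min_expected=min_exp,
        )
    stat, p = pearson_chi2(t)
    return ContingencyResult(
        table=tuple(map(tuple, t.tolist())),
        test="pearson_chi2",
        statistic=stat,
        p_value=p,
        min_expected=min_exp,
    )


def rank_tests(groups) -> float:
    """Mann-Whitney U (2 groups) or Kruskal-Wallis H (>= 3) p-value.

    Uses the tie-corrected normal / chi-square approximations.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if len(groups) == 2:
        # exact null distribution for small untied samples, tie-corrected
        # normal approximation otherwise
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="auto")
        return float(res.pvalue)
    return float(sps.kruskal(*groups).pvalue)


def format_p(p: float) -> str:
    """Display rounding for report p-values: 1 decimal above 0.2, else 3."""
    if p >= 0.2:
        return f"{p:.1f}"
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def summarize_cohort(calls, meta, code_groups) -> dict:
    """Diagnosis-group and tubular-subtype summaries of a classified cohort.

    ``calls`` maps sample_id -> PatternCall (or an iterable of
    ``(sample_id, PatternCall)``); ``meta`` is an iterable of SampleMeta;
    ``code_groups`` maps a group name to a predicate on ICD-10 codes (a
    callable, or a prefix string / list of prefixes).

    Returns a dict with:

    * ``diagnoses`` — per group: total count/%, counts and % split into
      tubular-or-mixed vs pure-glomerular patterns, and the
      contingency-test p-value of group membership vs pattern class
      (percentages are always recomputed from the counts);
    * ``tubular_egfr`` — per tubular subtype ("upper"/"lower"): n, count
      and % with eGFR < 60, median (Q1; Q3) eGFR, and the rank-test p;
    * ``unmatched`` — sample_ids present on one side of the join only.
    """
    if hasattr(calls, "items"):
        calls = list(calls.items())
    calls = {sid: call for sid, call in calls}
    meta_by_id = {m.sample_id: m for m in meta}
    unmatched = sorted(set(calls) ^ set(meta_by_id))
    ids = sorted(set(calls) & set(meta_by_id))

    rows = []
    for sid in ids:
        call = calls[sid]
        m = meta_by_id[sid]
        tubular_or_mixed = call.primary in (
            "tubular_upper",
            "tubular_lower",
            "mixed_glomerular_tubular",
        )
        rows.append(
            {
                "sample_id": sid,
                "primary": call.primary,
                "sublabel": call.tubular_sublabel,
                "tubular_or_mixed": tubular_or_mixed,
                "pure_glomerular": call.primary == "glomerular",
                "egfr": m.egfr,
                "icd10": m.icd10 or "",
            }
        )
    df = pd.DataFrame(rows)
    out: dict = {"diagnoses": {}, "tubular_egfr": {}, "unmatched": unmatched}
    if df.empty:
        return out

    # diagnosis groups: tubular/mixed vs pure glomerular split, as in the
    # proteinuria-cohort contingency analysis
    sub = df[df["tubular_or_mixed"] | df["pure_glomerular"]]
    n_tub = int(sub["tubular_or_mixed"].sum())
    n_glo = int(sub["pure_glomerular"].sum())
    for group, pred in code_groups.items():
        match = sub["icd10"].map(_as_predicate(pred))
        a = int((match & sub["tubular_or_mixed"]).sum())
        c = int((match & sub["pure_glomerular"]).sum())
        table = [[a, n_tub - a], [c, n_glo - c]]
        entry = {
            "n": a + c,
            "pct": _pct(a + c, len(sub)),
            "tubular_mixed_n": a,
            "tubular_mixed_pct": _pct(a, n_tub),
            "pure_glomerular_n": c,
            "pure_glomerular_pct": _pct(c, n_glo),
        }
        try:
            res = contingency_test(table)
            entry.update(test=res.test, p_value=res.p_value, p_display=format_p(res.p_value))
        except ValueError:
            entry.update(test=None, p_value=None, p_display="")
        out["diagnoses"][group] = entry

    tub = df[df["sublabel"].isin(["upper", "lower"])].dropna(subset=["egfr"])
    groups = []
    for sublabel in ("upper", "lower"):
        g = tub[tub["sublabel"] == sublabel]["egfr"].to_numpy()
        if len(g) == 0:
            continue
        groups.append(g)
        out["tubular_egfr"][sublabel] = {
            "n": int(len(g)),
            "egfr_lt60_n": int((g < 60).sum()),
            "egfr_lt60_pct": _pct(int((g < 60).sum()), len(g)),
            "median": float(np.median(g)),
            "q1": float(np.percentile(g, 25)),
            "q3": float(np.percentile(g, 75)),
        }
    if len(groups) == 2:
        p = rank_tests(groups)
        out["tubular_egfr"]["p_value"] = p
        out["tubular_egfr"]["p_display"] = format_p(p)
    return out


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n else float("nan")


def _as_predicate(pred):
    if callable(pred):
        return pred
    if isinstance(pred, str):
        return lambda code: code.startswith(pred)
    prefixes = tuple(pred)
    return lambda code: any(code.startswith(p) for p in prefixes)
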