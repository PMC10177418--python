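"""Contingency tests against brute-force oracles; cohort summaries."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from uripage.classify import PatternCall
from uripage.stats import (
    contingency_test,
    fisher_exact,
    format_p,
    pearson_chi2,
    rank_tests,
    summarize_cohort,
)
from uripage.synthetic import SampleMeta


def chi2_formula_oracle(table):
    """Direct sum of (O-E)^2/E with p from the 1-df chi-square distribution."""
    t = np.asarray(table, dtype=float)
    e = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    stat = float(((t - e) ** 2 / e).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def fisher_enumeration_oracle(table):
    """Sum hypergeometric pmfs of all margin-fixed tables no more probable
    than the observed one (float pmf with an epsilon for exact ties)."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    pmf = lambda k: sps.hypergeom.pmf(k, n, r1, c1)
    p_obs = pmf(a)
    ks = range(max(0, c1 - r2), min(r1, c1) + 1)
    return float(sum(pmf(k) for k in ks if pmf(k) <= p_obs * (1 + 1e-10)))


class TestPearson:
    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 1000:
            t = rng.integers(0, 60, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            stat, p = pearson_chi2(t)
            stat_o, p_o = chi2_formula_oracle(t)
            assert abs(stat - stat_o) < 1e-10
            assert abs(p - p_o) < 1e-10
            checked += 1

    def test_independence_gives_zero_statistic(self):
        stat, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi2([[0, 0], [5, 7]])


class TestFisher:
    def test_matches_enumeration_on_all_small_tables(self):
        """Every 2x2 table with total <= 30 agrees with full enumeration."""
        total_checked = 0
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        p = fisher_exact(t)
                        p_o = fisher_enumeration_oracle(t)
                        assert abs(p - p_o) < 1e-10, (t, p, p_o)
                        total_checked += 1
        assert total_checked > 40000

    def test_degenerate_margin_p_one(self):
        assert fisher_exact([[0, 5], [0, 9]]) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])

    def test_agrees_with_scipy_on_printed_table(self):
        t = [[2, 202], [7, 89]]
        assert fisher_exact(t) == pytest.approx(
            sps.fisher_exact(t).pvalue, abs=1e-9
        )


class TestRouting:
    def test_large_expected_counts_use_pearson(self):
        res = contingency_test([[91, 113], [26, 70]])
        assert res.test == "pearson_chi2"
        assert res.min_expected == pytest.approx(96 * 117 / 300)

    def test_small_expected_counts_use_fisher(self):
        res = contingency_test([[2, 202], [7, 89]])
        assert res.test == "fisher_exact"
        assert res.min_expected == pytest.approx(96 * 9 / 300)
        assert res.statistic is None

    def test_boundary_exactly_five_stays_pearson(self):
        # margins tuned so the smallest expected count is exactly 5
        t = [[5, 5], [5, 5]]
        res = contingency_test(t)
        assert res.min_expected == 5.0
        assert res.test == "pearson_chi2"
        assert res.p_value == pytest.approx(1.0)


class TestRank:
    def test_identical_groups_p_near_one(self):
        g = list(range(20))
        assert rank_tests([g, g]) >= 0.99

    def test_two_group_matches_exact_permutation(self):
        """Asymptotic Mann-Whitney stays within 0.01 of the exact
        permutation distribution at n=6 vs 6."""
        import itertools

        x = [1.2, 2.3, 3.1, 4.8, 5.5, 6.9]
        y = [2.0, 3.9, 5.1, 6.2, 7.7, 8.4]
        p = rank_tests([x, y])
        pooled = x + y
        ranks = sps.rankdata(pooled)
        obs = sum(ranks[:6])
        count = 0
        total = 0
        mean = sum(ranks) * 6 / 12
        for idx in itertools.combinations(range(12), 6):
            s = sum(ranks[i] for i in idx)
            total += 1
            if abs(s - mean) >= abs(obs - mean) - 1e-9:
                count += 1
        assert p == pytest.approx(count / total, abs=0.01)

    def test_three_group_type_i_error_calibrated(self):
        """Kruskal-Wallis under the null rejects at ~5%: within 3 binomial
        SDs over 500 replicates."""
        rng = np.random.default_rng(12)
        reps = 500
        rej = 0
        for _ in range(reps):
            groups = [rng.normal(size=15) for _ in range(3)]
            rej += rank_tests(groups) < 0.05
        sd = math.sqrt(reps * 0.05 * 0.95)
        assert abs(rej - 0.05 * reps) <= 3 * sd

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests([[1, 2], []])


# --- cohort fixture reproducing the printed diagnosis-group counts ---------
#
# 204 tubular-or-mixed and 96 pure-glomerular samples; per ICD-10 code the
# (tubular, glomerular) counts follow the published cohort table.
CODE_COUNTS = [
    ("C90.0", 87, 25),
    ("D47.2", 3, 1),
    ("C82.9", 1, 0),
    ("N18.1", 37, 22),
    ("Z94.0", 12, 6),
    ("N03.9", 20, 16),
    ("N17.9", 7, 2),
    ("N19", 2, 4),
    ("E11.2", 3, 0),
    ("N28.9", 2, 0),
    ("M31.3", 0, 2),
    ("M35.0", 1, 0),
    ("C50.9", 2, 7),
    ("I10", 5, 0),
    ("R80", 22, 11),
]

GROUPS = {
    "hematologic_lymphoid": lambda c: c.startswith(("C90", "D47.2", "C82")),
    "multiple_myeloma": "C90.0",
    "renal": lambda c: c.startswith(("N18", "Z94.0", "N03", "N17", "N19", "E11.2", "N28")),
    "ckd": "N18",
    "kidney_transplant": "Z94.0",
    "malignant_other": lambda c: c.startswith("C") and not c.startswith(("C90", "C82")),
}


def printed_cohort():
    calls, meta = {}, []
    i = 0
    rng = np.random.default_rng(0)
    for code, n_tub, n_glo in CODE_COUNTS:
        for _ in range(n_tub):
            sid = f"S{i:03d}"; i += 1
            calls[sid] = PatternCall(primary="tubular_lower", tubular_sublabel="lower")
            meta.append(SampleMeta(sample_id=sid, icd10=code, egfr=float(rng.uniform(10, 50))))
        for _ in range(n_glo):
            sid = f"S{i:03d}"; i += 1
            calls[sid] = PatternCall(primary="glomerular", grade=1)
            meta.append(SampleMeta(sample_id=sid, icd10=code, egfr=float(rng.uniform(40, 90))))
    return calls, meta


class TestSummarizeCohort:
    def test_reproduces_printed_p_values(self):
        calls, meta = printed_cohort()
        report = summarize_cohort(calls, meta, GROUPS)
        d = report["diagnoses"]
        assert d["hematologic_lymphoid"]["test"] == "pearson_chi2"
        assert format_p(d["hematologic_lymphoid"]["p_value"]) == "0.004"
        assert format_p(d["multiple_myeloma"]["p_value"]) == "0.006"
        assert format_p(d["renal"]["p_value"]) == "0.064"
        assert format_p(d["ckd"]["p_value"]) == "0.3"
        assert format_p(d["kidney_transplant"]["p_value"]) == "0.9"
        assert d["malignant_other"]["test"] == "fisher_exact"
        assert format_p(d["malignant_other"]["p_value"]) == "0.006"

    def test_counts_and_percentages_recomputed(self):
        calls, meta = printed_cohort()
        report = summarize_cohort(calls, meta, GROUPS)
        mm = report["diagnoses"]["multiple_myeloma"]
        assert mm["tubular_mixed_n"] == 87
        assert mm["pure_glomerular_n"] == 25
        assert mm["tubular_mixed_pct"] == pytest.approx(100 * 87 / 204)
        assert mm["pure_glomerular_pct"] == pytest.approx(100 * 25 / 96)

    def test_empty_cohort(self):
        report = summarize_cohort({}, [], GROUPS)
        assert report["diagnoses"] == {}
        assert report["tubular_egfr"] == {}

    def test_unmatched_ids_reported(self):
        calls = {"A": PatternCall(primary="glomerular", grade=1)}
        meta = [SampleMeta(sample_id="B", icd10="N18.1", egfr=50.0)]
        report = summarize_cohort(calls, meta, {})
        assert set(report["unmatched"]) == {"A", "B"}

    def test_tubular_egfr_summary_from_data(self):
        calls, meta = {}, []
        rng = np.random.default_rng(3)
        upper = rng.uniform(55, 95, size=40)
        lower = rng.uniform(8, 45, size=60)
        i = 0
        for sub, values in (("upper", upper), ("lower", lower)):
            for v in values:
                sid = f"T{i:03d}"; i += 1
                calls[sid] = PatternCall(primary=f"tubular_{sub}", tubular_sublabel=sub)
                meta.append(SampleMeta(sample_id=sid, egfr=float(v), icd10="N18.1"))
        report = summarize_cohort(calls, meta, {})
        te = report["tubular_egfr"]
        assert te["upper"]["n"] == 40
        assert te["upper"]["median"] == pytest.approx(float(np.median(upper)))
        assert te["lower"]["egfr_lt60_n"] == int((lower < 60).sum())
        assert te["lower"]["egfr_lt60_pct"] == pytest.approx(100 * (lower < 60).mean())
        assert te["p_value"] < 0.001


def test_format_p_display_rules():
    assert format_p(0.0037) == "0.004"
    assert format_p(0.33) == "0.3"
    assert format_p(0.9) == "0.9"
    assert format_p(0.0004) == "<0.001"
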