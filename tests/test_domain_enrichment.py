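import math

import numpy as np
import pandas as pd
import pytest

from mycocomp.domain_enrichment import (
    build_count_matrix,
    chisq_2x2,
    DomainCountMatrix,
    enrichment_to_frame,
    fisher_two_sided,
    pairwise_enrichment,
    presence_sets,
)
from mycocomp.io_formats import DataError
from mycocomp.synthetic_data import simulate_domain_tables


def matrix_from_counts(counts: dict[str, dict[str, int]], totals: dict[str, int]):
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    sec = df * 0
    return DomainCountMatrix(df, pd.Series(totals), sec, {})


# ---------------------------------------------------------------------------
# Fisher's exact test


def oracle_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration
    (log-factorials only; independent of the implementation under test)."""
    r1, c1, c2 = a + b, a + c, b + d
    n = a + b + c + d
    lf = [0.0]
    for i in range(1, n + 1):
        lf.append(lf[-1] + math.log(i))
    lo, hi = max(0, r1 - c2), min(r1, c1)
    logpmf = [
        lf[c1] - lf[x] - lf[c1 - x]
        + lf[c2] - lf[r1 - x] - lf[c2 - (r1 - x)]
        - (lf[n] - lf[r1] - lf[n - r1])
        for x in range(lo, hi + 1)
    ]
    pmf = np.exp(logpmf)
    obs = pmf[a - lo]
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


class TestFisher:
    def test_enumerated_example(self):
        # all C(10,5)=252 tables with these margins; only the two extreme
        # tables are as or more extreme
        p, odds = fisher_two_sided(0, 5, 5, 0)
        assert p == pytest.approx(2 / 252)
        assert odds == 0.0

    def test_symmetric_table(self):
        p, odds = fisher_two_sided(1, 1, 1, 1)
        assert p == 1.0 and odds == 1.0

    def test_transposition_symmetry(self):
        assert fisher_two_sided(5, 0, 0, 5)[0] == pytest.approx(
            fisher_two_sided(0, 5, 5, 0)[0]
        )

    def test_infinite_odds_ratio(self):
        _, odds = fisher_two_sided(5, 0, 1, 5)
        assert odds == math.inf

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError, match="zero margin"):
            fisher_two_sided(0, 0, 3, 4)

    def test_exhaustive_enumeration_all_tables_up_to_n40(self):
        """Implementation p equals brute-force hypergeometric enumeration
        for every 2x2 table with positive margins and n <= 40."""
        worst = 0.0
        for n in range(2, 41):
            for r1 in range(1, n):
                for c1 in range(1, n):
                    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
                    for a in range(lo, hi + 1):
                        b, c = r1 - a, c1 - a
                        d = n - r1 - c
                        p_impl, _ = fisher_two_sided(a, b, c, d)
                        p_oracle = oracle_fisher_p(a, b, c, d)
                        worst = max(worst, abs(p_impl - p_oracle))
        assert worst < 1e-9


# ---------------------------------------------------------------------------
# Count matrix


class TestBuildCountMatrix:
    def test_accession_level_counting(self, small_domain_table):
        """A protein with several copies of a domain counts once."""
        m = build_count_matrix(small_domain_table)
        assert m.counts.loc["A", "Lipase_3"] == 2  # A_g1 (x2 copies) + A_g2
        assert m.counts.loc["B", "Lipase_3"] == 1

    def test_absent_domain_is_zero(self, small_domain_table):
        m = build_count_matrix(small_domain_table)
        assert m.counts.loc["A", "BD-FAE"] == 0

    def test_secreted_counts(self, small_domain_table):
        m = build_count_matrix(small_domain_table)
        assert m.secreted_counts.loc["A", "Lipase_3"] == 1  # only A_g1
        assert (m.secreted_counts.values <= m.counts.values).all()

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(DataError, match="exceeds proteome total"):
            matrix_from_counts({"A": {"d": 11}, "B": {"d": 1}}, {"A": 10, "B": 10})


# ---------------------------------------------------------------------------
# Pairwise enrichment


class TestPairwiseEnrichment:
    def test_underrepresented_fold_is_median_over_count(self):
        """The printed seven-genome BD-FAE counts give a 20-fold deficit for
        the count-1 genome (median 20)."""
        species = list("ABCDEFG")
        counts = dict(zip(species, [1, 2, 3, 23, 25, 20, 23]))
        m = matrix_from_counts({s: {"BD-FAE": c} for s, c in counts.items()},
                               {s: 10_000 for s in species})
        res = pairwise_enrichment(m)["BD-FAE"]
        assert res.median == 20
        assert res.per_species["A"].direction == "down"
        assert res.per_species["A"].fold_vs_median == pytest.approx(20.0)

    def test_overrepresented_fold_is_count_over_median(self):
        m = matrix_from_counts(
            {s: {"Lipase_3": c} for s, c in
             zip("ABCDEFG", [348, 132, 190, 66, 40, 55, 60])},
            {s: 20_000 for s in "ABCDEFG"},
        )
        res = pairwise_enrichment(m)["Lipase_3"]
        assert res.median == 66
        e = res.per_species["A"]
        assert e.direction == "up"
        assert e.fold_vs_median == pytest.approx(348 / 66)

    def test_equal_counts_no_signal(self):
        m = matrix_from_counts({s: {"d": 5} for s in "ABC"}, {s: 100 for s in "ABC"})
        res = pairwise_enrichment(m)["d"]
        for e in res.per_species.values():
            assert e.direction == "at_median"
            assert e.fold_vs_median == 1.0
            assert e.n_significant_pairs == 0

    def test_rare_domains_excluded(self):
        m = matrix_from_counts(
            {"A": {"d1": 5, "d2": 3}, "B": {"d1": 0, "d2": 2}, "C": {"d1": 0, "d2": 0}},
            {s: 100 for s in "ABC"},
        )
        res = pairwise_enrichment(m)
        assert "d1" not in res and "d2" in res

    def test_bonferroni_is_min_of_one_and_raw_times_m(self):
        m = matrix_from_counts(
            {"A": {"d": 30}, "B": {"d": 5}, "C": {"d": 6}, "D": {"d": 7}},
            {s: 1000 for s in "ABCD"},
        )
        res = pairwise_enrichment(m)["d"]
        n_pairs = 6
        for (i, j), adj in res.pairwise_p.items():
            a, c = int(m.counts.loc[i, "d"]), int(m.counts.loc[j, "d"])
            raw, _ = fisher_two_sided(a, 1000 - a, c, 1000 - c)
            assert adj == pytest.approx(min(1.0, raw * n_pairs))

    def test_n_significant_pairs_counts_involving_pairs(self):
        m = matrix_from_counts(
            {"A": {"d": 200}, "B": {"d": 5}, "C": {"d": 5}, "D": {"d": 5}},
            {s: 10_000 for s in "ABCD"},
        )
        res = pairwise_enrichment(m)["d"]
        assert res.per_species["A"].n_significant_pairs == 3
        assert res.per_species["B"].n_significant_pairs == 1

    def test_zero_count_fold_is_infinite(self):
        m = matrix_from_counts(
            {"A": {"d": 0}, "B": {"d": 8}, "C": {"d": 10}},
            {s: 100 for s in "ABC"},
        )
        e = pairwise_enrichment(m)["d"].per_species["A"]
        assert e.direction == "down" and e.fold_vs_median == math.inf

    def test_invalid_alpha_rejected(self):
        m = matrix_from_counts({"A": {"d": 1}, "B": {"d": 1}}, {"A": 10, "B": 10})
        with pytest.raises(ValueError):
            pairwise_enrichment(m, alpha=0.0)

    def test_planted_enrichment_power(self):
        """A 5-fold planted enrichment (baseline mean 50, proteomes of
        10,000) is flagged against every other genome in >= 95% of 200
        simulated domains at alpha 0.01."""
        n_domains = 200
        enrichments = {("SP1", f"PF{i + 1:05d}"): 5.0 for i in range(n_domains)}
        table, _ = simulate_domain_tables(
            4, n_domains, totals=10_000, base_mean=50.0,
            enrichments=enrichments, seed=77,
        )
        m = build_count_matrix(table)
        res = pairwise_enrichment(m, alpha=0.01)
        full_hits = sum(
            1 for d in res if res[d].per_species["SP1"].n_significant_pairs == 3
        )
        assert len(res) == n_domains
        assert full_hits / n_domains >= 0.95


# ---------------------------------------------------------------------------
# Chi-squared


class TestChisq:
    def test_secreted_fraction_comparison(self):
        """17/20 vs 45/105 non-secreted families: p = 0.00055."""
        chi2, p = chisq_2x2(17, 3, 45, 60)
        assert p == pytest.approx(0.00055, abs=2e-5)

    def test_independence(self):
        chi2, p = chisq_2x2(5, 5, 5, 5)
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with a=d=10, b=c=0
        chi2, _ = chisq_2x2(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError, match="zero margin"):
            chisq_2x2(0, 0, 5, 5)


# ---------------------------------------------------------------------------
# Presence sets


class TestPresenceSets:
    def test_exact_patterns(self):
        m = matrix_from_counts(
            {"A": {"x": 1, "y": 2}, "B": {"y": 1, "z": 3}},
            {"A": 10, "B": 10},
        )
        sets = presence_sets(m)
        assert sets == {
            frozenset({"A"}): 1,
            frozenset({"A", "B"}): 1,
            frozenset({"B"}): 1,
        }

    def test_counts_sum_to_n_domains(self, small_domain_table):
        m = build_count_matrix(small_domain_table)
        assert sum(presence_sets(m).values()) == len(m.domains)

    def test_ubiquitous_domain_in_full_set(self):
        m = matrix_from_counts(
            {s: {"d": 1} for s in "ABCD"}, {s: 10 for s in "ABCD"}
        )
        assert presence_sets(m) == {frozenset("ABCD"): 1}


def test_enrichment_frame_has_expected_columns(small_domain_table):
    m = build_count_matrix(small_domain_table)
    df = enrichment_to_frame(pairwise_enrichment(m))
    assert set(df.columns) >= {
        "domain_type", "domain_id", "species", "count", "median", "fold",
        "direction", "n_significant_pairs", "min_adjusted_p",
    }
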