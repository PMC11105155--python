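"""Cross-species protein-domain enrichment statistics.

Counts are at the accession (protein) level: a protein carrying k copies of
a domain contributes 1 to that domain's count. Enrichment between genomes
is assessed per domain by two-sided Fisher's exact tests on all unordered
species pairs, Bonferroni-corrected within the domain (family size =
number of pairs), and summarized per species as a fold relative to the
across-species median count with an up/down direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DataError, DomainAnnotationTable


@dataclass
class DomainCountMatrix:
    """Species x domain counts of domain-bearing proteins.

    counts.loc[species, domain] = number of distinct proteins of that
    species containing the domain; totals[species] = proteome size;
    secreted_counts restricted to secreted proteins; domain_types maps
    domain -> PFAM/MEROPS/CAZY.
    """

    counts: pd.DataFrame
    totals: pd.Series
    secreted_counts: pd.DataFrame
    domain_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DataError("negative domain counts")
        over = self.counts.gt(self.totals, axis=0)
        if over.values.any():
            raise DataError("domain count exceeds proteome total")
        if (self.secreted_counts.values > self.counts.values).any():
            raise DataError("secreted counts exceed total counts")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def domains(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SpeciesEnrichment:
    count: int
    fold_vs_median: float  # count/median (up) or median/count (down); inf at 0
    direction: str  # up | down | at_median
    n_significant_pairs: int


@dataclass
class EnrichmentResult:
    domain_id: str
    domain_type: str
    median: float
    per_species: dict[str, SpeciesEnrichment]
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-adjusted, capped at 1


def build_count_matrix(table: DomainAnnotationTable) -> DomainCountMatrix:
    """Count distinct domain-bearing proteins per species and domain."""
    rows = table.rows
    species = table.species
    uniq = rows.drop_duplicates(["species", "gene_id", "domain_id"])
    counts = (
        uniq.pivot_table(index="species", columns="domain_id",
                         values="gene_id", aggfunc="count", fill_value=0)
        .reindex(species, fill_value=0)
        .astype(int)
    )
    sec = (
        uniq[uniq["secreted"]]
        .pivot_table(index="species", columns="domain_id",
                     values="gene_id", aggfunc="count", fill_value=0)
        .reindex(index=species, columns=counts.columns, fill_value=0)
        .astype(int)
    )
    totals = pd.Series(table.proteome_total).reindex(species)
    dtypes = dict(
        rows.drop_duplicates("domain_id")[["domain_id", "domain_type"]].values
    )
    return DomainCountMatrix(counts, totals, sec, dtypes)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    p sums hypergeometric probabilities <= the observed table's probability
    (the classical two-sided rule). The statistic is the sample odds ratio
    a*d/(b*c), infinite when b*c = 0 and a*d > 0.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise DataError("negative cell in 2x2 table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DataError("Fisher test undefined: zero margin")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return float(res.pvalue), odds


def _fold_and_direction(count: int, median: float) -> tuple[float, str]:
    if count > median:
        return (math.inf if median == 0 else count / median), "up"
    if count < median:
        return (math.inf if count == 0 else median / count), "down"
    return 1.0, "at_median"


def pairwise_enrichment(
    m: DomainCountMatrix,
    alpha: float = 0.01,
    global_bonferroni: bool = False,
) -> dict[str, EnrichmentResult]:
    """Pairwise Fisher enrichment of each domain among genomes.

    Domains present (count > 0) in fewer than two genomes are excluded.
    For each retained domain and unordered species pair (i, j), a two-sided
    Fisher test compares domain-bearing vs other proteins between the two
    proteomes; p-values are Bonferroni-adjusted with family size = number
    of pairs per domain (or pairs x domains with ``global_bonferroni``),
    capped at 1. Significance threshold is adjusted p <= alpha.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    species = m.species
    if len(species) < 2:
        raise DataError("pairwise enrichment needs >= 2 species")
    pairs = list(combinations(species, 2))
    retained = [d for d in m.domains if int((m.counts[d] > 0).sum()) >= 2]
    m_factor = len(pairs) * (len(retained) if global_bonferroni else 1)
    results: dict[str, EnrichmentResult] = {}
    for d in retained:
        col = m.counts[d]
        median = float(col.median())
        adj_p: dict[tuple[str, str], float] = {}
        for i, j in pairs:
            a, ti = int(col[i]), int(m.totals[i])
            c, tj = int(col[j]), int(m.totals[j])
            p, _ = fisher_two_sided(a, ti - a, c, tj - c)
            adj_p[(i, j)] = min(1.0, p * m_factor)
        per_species: dict[str, SpeciesEnrichment] = {}
        for s in species:
            fold, direction = _fold_and_direction(int(col[s]), median)
            n_sig = sum(
                1 for (i, j), p in adj_p.items() if s in (i, j) and p <= alpha
            )
            per_species[s] = SpeciesEnrichment(int(col[s]), fold, direction, n_sig)
        results[d] = EnrichmentResult(
            d, m.domain_types.get(d, "PFAM"), median, per_species, adj_p
        )
    return results


def enrichment_to_frame(results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    """Long-format table: one row per (domain, species)."""
    rows = []
    for d, res in results.items():
        for s, e in res.per_species.items():
            pair_ps = [p for pair, p in res.pairwise_p.items() if s in pair]
            rows.append(
                {
                    "domain_type": res.domain_type,
                    "domain_id": d,
                    "species": s,
                    "count": e.count,
                    "median": res.median,
                    "fold": e.fold_vs_median,
                    "direction": e.direction,
                    "n_significant_pairs": e.n_significant_pairs,
                    "min_adjusted_p": min(pair_ps) if pair_ps else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("chi-squared undefined: zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def presence_sets(m: DomainCountMatrix) -> dict[frozenset[str], int]:
    """Count domains by their exact presence pattern across species.

    Every domain lands in exactly one species-subset cell (the set of
    species where its count is > 0), so the counts sum to the number of
    domains — the contract of an UpSet plot.
    """
    out: dict[frozenset[str], int] = {}
    for d in m.domains:
        pattern = frozenset(m.counts.index[m.counts[d] > 0])
        if pattern:
            out[pattern] = out.get(pattern, 0) + 1
    return out


def presence_sets_to_frame(sets: Mapping[frozenset[str], int]) -> pd.DataFrame:
    rows = [
        {"species_set": "&".join(sorted(k)), "n_species": len(k), "n_domains": v}
        for k, v in sorted(sets.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    ]
    return pd.DataFrame(rows)
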