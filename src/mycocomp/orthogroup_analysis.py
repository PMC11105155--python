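"""Post-clustering orthogroup (OG) statistics.

Occupancy: each OG is assigned to exactly one species-subset pattern (the
set of species contributing at least one gene), so pattern counts partition
the OGs; "core" OGs are those occupied by every species. Gene accounting
partitions each species' genes into assigned vs unassigned, with
"potentially species-specific" = unassigned + members of OGs populated by
that species alone, optionally filtered by pooled expression evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .domain_enrichment import fisher_two_sided
from .io_formats import DataError, ExpressionTable, OrthogroupTable

logger = logging.getLogger(__name__)

NO_PFAM = "no_Pfam"


@dataclass
class OccupancySummary:
    pattern_counts: dict[frozenset[str], int]
    pattern_pct: dict[frozenset[str], float]  # percent of all OGs
    pct_ogs_with_gene: dict[str, float]
    pct_species_specific_ogs: dict[str, float]
    total_ogs: int


@dataclass
class SpeciesGeneAccounting:
    n_genes: int
    pct_assigned: float
    pct_not_assigned: float
    pct_in_species_specific_og: float
    pct_potentially_specific: float
    pct_potentially_specific_expressed: Optional[float] = None


def _og_patterns(t: OrthogroupTable) -> dict[str, frozenset[str]]:
    return {
        og: frozenset(sp for sp, genes in by_sp.items() if genes)
        for og, by_sp in t.ogs.items()
    }


def occupancy_summary(t: OrthogroupTable, species: list[str]) -> OccupancySummary:
    """Partition OGs by occupancy pattern and summarize per species."""
    extra = set(t.species) - set(species)
    if extra:
        raise DataError(f"species in table missing from list: {sorted(extra)}")
    patterns = _og_patterns(t)
    total = len(patterns)
    counts: dict[frozenset[str], int] = {}
    for pat in patterns.values():
        counts[pat] = counts.get(pat, 0) + 1
    pct = {pat: 100.0 * n / total for pat, n in counts.items()} if total else {}
    with_gene = {
        sp: 100.0 * sum(n for pat, n in counts.items() if sp in pat) / total
        if total else 0.0
        for sp in species
    }
    specific = {
        sp: 100.0 * counts.get(frozenset([sp]), 0) / total if total else 0.0
        for sp in species
    }
    return OccupancySummary(counts, pct, with_gene, specific, total)


def species_specific_ogs(t: OrthogroupTable, sp: str) -> list[str]:
    return [og for og, pat in _og_patterns(t).items() if pat == frozenset([sp])]


def gene_accounting(
    t: OrthogroupTable,
    species: list[str],
    expr: Optional[ExpressionTable] = None,
    min_count: float = 5,
) -> dict[str, SpeciesGeneAccounting]:
    """Per-species gene partition into OG-assignment classes (percentages).

    The per-species gene universe is assigned ∪ unassigned. When an
    expression table is given, the expressed subset of the potentially
    species-specific genes (pooled count >= min_count) is also reported.
    """
    patterns = _og_patterns(t)
    out: dict[str, SpeciesGeneAccounting] = {}
    for sp in species:
        assigned = t.assigned_genes(sp)
        unassigned = set(t.unassigned.get(sp, []))
        n = len(assigned) + len(unassigned)
        if n == 0:
            out[sp] = SpeciesGeneAccounting(0, 0.0, 100.0, 0.0, 100.0)
            continue
        in_specific = {
            g
            for og, by_sp in t.ogs.items()
            if patterns[og] == frozenset([sp])
            for g in by_sp.get(sp, [])
        }
        pct_assigned = 100.0 * len(assigned) / n
        pct_not = 100.0 * len(unassigned) / n
        pct_spec_og = 100.0 * len(in_specific) / n
        pct_pot = pct_not + pct_spec_og
        pct_expr = None
        if expr is not None:
            pot = unassigned | in_specific
            expressed = {g for g in pot if expr.get(g) >= min_count}
            pct_expr = 100.0 * len(expressed) / n
        out[sp] = SpeciesGeneAccounting(
            n, pct_assigned, pct_not, pct_spec_og, pct_pot, pct_expr
        )
    return out


def potentially_specific_genes(
    t: OrthogroupTable,
    sp: str,
    expr: ExpressionTable,
    min_count: float = 5,
) -> tuple[set[str], set[str]]:
    """Potentially species-specific genes and their expression-filtered subset.

    The set is unassigned(sp) ∪ genes of sp-only OGs. Genes with pooled
    count strictly below ``min_count`` are filtered out; genes absent from
    the expression table count as 0 (no evidence of expression).
    """
    patterns = _og_patterns(t)
    specific = {
        g
        for og, by_sp in t.ogs.items()
        if patterns[og] == frozenset([sp])
        for g in by_sp.get(sp, [])
    }
    full = specific | set(t.unassigned.get(sp, []))
    missing = [g for g in full if g not in expr.counts]
    if missing:
        logger.info(
            "%d/%d potentially specific genes absent from expression table "
            "(treated as count 0)", len(missing), len(full),
        )
    if not expr.counts and full:
        warnings.warn("empty expression table: all genes filtered", stacklevel=2)
    filtered = {g for g in full if expr.get(g) >= min_count}
    return full, filtered


def set_enrichment(
    target_genes: set[str],
    background_genes: set[str],
    annotations: Mapping[str, set[str]],
    alpha: float = 0.001,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-domain Fisher enrichment of a gene subset against its background.

    For every domain seen in the background (plus the pseudo-domain
    ``no_Pfam`` for genes lacking any annotation), tests the 2x2 table of
    target membership vs domain presence with a two-sided Fisher exact
    test. Significance is raw p <= alpha by default (matching a raw-p
    reporting threshold); ``fdr=True`` switches to Benjamini-Hochberg
    adjusted p <= alpha.
    """
    if not target_genes <= background_genes:
        raise DataError("target genes must be a subset of the background")
    domains: dict[str, set[str]] = {}
    for g in background_genes:
        anns = annotations.get(g) or {NO_PFAM}
        for d in anns:
            domains.setdefault(d, set()).add(g)
    rows = []
    n_target = len(target_genes)
    n_bg = len(background_genes)
    for d, genes in sorted(domains.items()):
        a = len(genes & target_genes)  # target with domain
        b = n_target - a
        c = len(genes) - a  # non-target with domain
        dd = (n_bg - n_target) - c
        if a + b == 0 or c + dd == 0 or a + c == 0 or b + dd == 0:
            # a zero margin (empty target, or a ubiquitous domain) carries
            # no enrichment information
            p, odds = 1.0, float("nan")
        else:
            p, odds = fisher_two_sided(a, b, c, dd)
        rows.append({"domain_id": d, "target_with": a, "target_without": b,
                     "rest_with": c, "rest_without": dd,
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["significant"] = []
        return df
    if fdr:
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] <= alpha
    else:
        df["significant"] = df["p"] <= alpha
    return df
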