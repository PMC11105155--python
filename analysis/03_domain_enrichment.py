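#!/usr/bin/env python
"""Cross-species domain enrichment on the simulated tables, plus the
published-count reproductions.

Writes results/enrichment.tsv and results/presence_sets.tsv, reports how
many planted 5-fold enrichments were detected, and reproduces three
numbers computed from printed count tables: the 20-fold BD-FAE deficit,
the 5.3-fold Lipase_3 excess, and the secreted-fraction chi-squared
p = 0.00055 (17/20 vs 45/105 non-secreted families).
"""

from pathlib import Path

import json
import pandas as pd

from mycocomp import domain_enrichment, io_formats

SYN = Path("results/synthetic")
OUT = Path("results")


def main() -> None:
    table = io_formats.read_domain_table(SYN / "domains.tsv", SYN / "totals.tsv")
    truth = json.loads((SYN / "domains.truth.json").read_text())
    matrix = domain_enrichment.build_count_matrix(table)
    results = domain_enrichment.pairwise_enrichment(matrix, alpha=0.01)
    df = domain_enrichment.enrichment_to_frame(results)
    df.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    planted = {k.split(":")[1] for k in truth["enriched_domains"]}
    detected = {
        d for d in planted
        if d in results and results[d].per_species["SP1"].n_significant_pairs == 3
    }
    print(f"planted enrichments detected: {len(detected)}/{len(planted)}")

    sets = domain_enrichment.presence_sets(matrix)
    domain_enrichment.presence_sets_to_frame(sets).to_csv(
        OUT / "presence_sets.tsv", sep="\t", index=False)
    print(f"presence patterns: {len(sets)} subsets over {len(matrix.domains)} domains")

    species = list("ABCDEFG")
    bdfae = pd.DataFrame(
        {"BD-FAE": dict(zip(species, [1, 2, 3, 23, 25, 20, 23]))}
    ).fillna(0).astype(int)
    m = domain_enrichment.DomainCountMatrix(
        bdfae, pd.Series({s: 10_000 for s in species}), bdfae * 0, {})
    fold = domain_enrichment.pairwise_enrichment(m)["BD-FAE"].per_species["A"]
    print(f"BD-FAE: count 1 vs median 20 -> {fold.fold_vs_median:.0f}-fold "
          f"{fold.direction}")

    lip = pd.DataFrame(
        {"Lipase_3": dict(zip(species, [348, 132, 190, 66, 40, 55, 60]))}
    ).astype(int)
    m = domain_enrichment.DomainCountMatrix(
        lip, pd.Series({s: 20_000 for s in species}), lip * 0, {})
    fold = domain_enrichment.pairwise_enrichment(m)["Lipase_3"].per_species["A"]
    print(f"Lipase_3: count 348 vs median 66 -> {fold.fold_vs_median:.1f}-fold "
          f"{fold.direction}")

    chi2, p = domain_enrichment.chisq_2x2(17, 3, 45, 60)
    print(f"secreted-fraction chi-squared: chi2={chi2:.3f}, p={p:.5f}")


if __name__ == "__main__":
    main()
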