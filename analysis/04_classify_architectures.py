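#!/usr/bin/env python
"""Classify proteins by the curated domain-architecture rule sets.

Builds a small demonstration proteome containing known circadian, RNAi
and RID-like architectures, runs every builtin rule set over it, and
writes results/architecture_counts.tsv.
"""

from pathlib import Path

import pandas as pd

from mycocomp.architecture_rules import builtin_rulesets, classify_proteome
from mycocomp.io_formats import DomainAnnotationTable

OUT = Path("results")

# (species, gene, domains) — architectures seen in entomophthoralean
# annotation sets: a WC1-like photoreceptor, a WC2-like partner, a
# rhodopsin, Dicer/Ago/RdRP components and a tandem methyltransferase
DEMO = [
    ("EMU", "wc1_like", ["GATA", "PAS_3", "PAS_9"]),
    ("EMU", "rhodopsin_1", ["7tm_1"]),
    ("EMU", "ago_1", ["PAZ", "Piwi"]),
    ("EMU", "dicer_1", ["Dicer_dimer"]),
    ("EMU", "dicer_alt_1", ["Ribonuclease_3", "DEAD"]),
    ("EMU", "rdrp_1", ["RdRP"]),
    ("EMU", "rid_like", ["DNA_methylase", "DNA_methylase"]),
    ("EMU", "methylase_single", ["DNA_methylase"]),
    ("ZRA", "wc1_like", ["GATA", "PAS_3", "PAS_9"]),
    ("ZRA", "wc2_like", ["GATA", "PAS_3"]),
    ("ZRA", "photolyase_1", ["DNA_photolyase"]),
    ("NTH", "gaf_1", ["GAF"]),
]


def main() -> None:
    rows = [
        (sp, gene, dom, "PFAM", False)
        for sp, gene, doms in DEMO
        for dom in doms
    ]
    table = DomainAnnotationTable(
        pd.DataFrame(rows, columns=["species", "gene_id", "domain_id",
                                    "domain_type", "secreted"]),
        {"EMU": 100, "ZRA": 100, "NTH": 100},
    )
    out_rows = []
    for name, rules in builtin_rulesets().items():
        counts = classify_proteome(table, rules)
        for sp, by_rule in counts.items():
            for rule, n in by_rule.items():
                out_rows.append(
                    {"ruleset": name, "species": sp, "rule": rule, "n_proteins": n}
                )
    df = pd.DataFrame(out_rows)
    df.to_csv(OUT / "architecture_counts.tsv", sep="\t", index=False)
    hits = df[df["n_proteins"] > 0]
    print(hits.to_string(index=False))
    print(f"\n{len(hits)} (ruleset, species, rule) combinations matched")


if __name__ == "__main__":
    main()
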