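#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes, under results/synthetic/: a background genome with RIP planted at
rate 0.3 in 100 windows, four-species domain tables with 5-fold planted
enrichments, an orthogroup table with the published occupancy proportions,
and pooled expression counts with a 20% silent fraction. Truth JSONs sit
next to each output.
"""

from pathlib import Path

from mycocomp import io_formats, synthetic_data

SEED = 1
OUT = Path("results/synthetic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    g = synthetic_data.simulate_genome(1, [600_000], gc=0.5, seed=SEED)
    planted = [("contig_1", s, s + 1000) for s in range(0, 600_000, 6000)]
    mutated, rip_truth = synthetic_data.plant_rip(g, planted, 0.3, seed=SEED + 1)
    io_formats.write_fasta(mutated, OUT / "genome_rip.fa")
    rip_truth.to_json(OUT / "genome_rip.truth.json")
    print(f"genome: 600 kb, {len(planted)} planted RIP windows at rate 0.3")

    enr = {("SP1", f"PF{i + 1:05d}"): 5.0 for i in range(20)}
    table, dom_truth = synthetic_data.simulate_domain_tables(
        4, 200, totals=10_000, base_mean=50.0, enrichments=enr, seed=SEED + 2
    )
    io_formats.write_domain_table(table, OUT / "domains.tsv", OUT / "totals.tsv")
    dom_truth.to_json(OUT / "domains.truth.json")
    print(f"domains: 4 species x 200 domains, {len(enr)} planted 5-fold enrichments")

    species = ["EMU", "EMA", "ZRA", "NTH"]
    patterns = {
        frozenset(species): 688,
        frozenset({"EMU", "EMA"}): 185,
        frozenset({"EMU", "EMA", "ZRA"}): 128,
        frozenset({"EMU"}): 180,
        frozenset({"EMA"}): 120,
        frozenset({"ZRA"}): 150,
        frozenset({"NTH"}): 100,
        frozenset({"ZRA", "NTH"}): 160,
    }
    ogs, og_truth = synthetic_data.simulate_orthogroups(
        patterns, (1, 4), {sp: 50 for sp in species}, seed=SEED + 3
    )
    io_formats.write_orthogroups(
        ogs, OUT / "Orthogroups.tsv", OUT / "Orthogroups_UnassignedGenes.tsv"
    )
    og_truth.to_json(OUT / "orthogroups.truth.json")
    print(f"orthogroups: {sum(patterns.values())} OGs over {len(patterns)} patterns")

    emu_genes = sorted(
        set(ogs.unassigned["EMU"])
        | {g for by_sp in ogs.ogs.values() for g in by_sp["EMU"]}
    )
    expr, expr_truth = synthetic_data.simulate_expression(
        emu_genes, silent_fraction=0.2, active_mean=100.0, seed=SEED + 4
    )
    io_formats.write_expression(expr, OUT / "expression.tsv")
    expr_truth.to_json(OUT / "expression.truth.json")
    print(f"expression: {len(emu_genes)} EMU genes, 20% silent")


if __name__ == "__main__":
    main()
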