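"""Summary statistics over compiled genome-size / gene-count datasets.

Mirrors the convention of reporting the median assembly size and gene
number after excluding giant assemblies (default cutoff 500 Mb, which
removes the repeat-bloated outliers) alongside the mean over all genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MB = 1_000_000


@dataclass
class DatasetSummary:
    n_total: int
    n_after_exclusion: int
    median_genome_size_mb: float  # excluding large assemblies
    median_gene_count: float  # excluding large assemblies
    mean_genome_size_mb: float  # over all genomes


def dataset_summary(
    df: pd.DataFrame,
    size_col: str = "genome_size_bp",
    genes_col: str = "gene_count",
    large_cutoff_bp: float = 500 * MB,
) -> DatasetSummary:
    """Median size/genes excluding assemblies over the cutoff; mean over all."""
    if size_col not in df.columns:
        raise KeyError(size_col)
    kept = df[df[size_col] <= large_cutoff_bp]
    median_genes = float(kept[genes_col].median()) if genes_col in df.columns else float("nan")
    return DatasetSummary(
        n_total=len(df),
        n_after_exclusion=len(kept),
        median_genome_size_mb=float(kept[size_col].median()) / MB,
        median_gene_count=median_genes,
        mean_genome_size_mb=float(df[size_col].mean()) / MB,
    )
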