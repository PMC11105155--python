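"""Readers and writers for the tables and sequences the pipeline consumes.

All coordinates are 0-based, half-open. Sequences are case-normalized to
upper case on read; IUPAC ambiguity codes are mapped to ``N`` (with a logged
count) rather than rejected, because real assemblies contain them.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
# IUPAC nucleotide ambiguity codes (everything standard that is not ACGTN)
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHV")

DOMAIN_TYPES = ("PFAM", "MEROPS", "CAZY")

_ISOFORM_SUFFIX = re.compile(r"-T\d+$")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenomeSequence:
    """Named contigs over {A,C,G,T,N}."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not cid:
                raise DataError("empty contig id")
            if not seq:
                raise DataError(f"contig {cid!r}: empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise DataError(
                    f"contig {cid!r}: illegal characters {sorted(bad)}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeSequence):
            return NotImplemented
        return self.contigs == other.contigs

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class DomainAnnotationTable:
    """Per-gene domain annotations plus per-species proteome sizes.

    ``rows`` has columns species, gene_id, domain_id, domain_type, secreted.
    Rows may repeat a (species, gene_id, domain_id) triple: multi-copy
    domains within one protein are distinct rows. ``proteome_total`` gives
    the number of annotated proteins per species; genes without any domain
    still belong to these denominators.
    """

    rows: pd.DataFrame
    proteome_total: dict[str, int]

    def __post_init__(self) -> None:
        required = ["species", "gene_id", "domain_id", "domain_type", "secreted"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise DataError(f"domain table missing columns: {missing}")
        bad_types = set(self.rows["domain_type"]) - set(DOMAIN_TYPES)
        if bad_types:
            raise DataError(f"unknown domain_type values: {sorted(bad_types)}")
        flags = self.rows.groupby(["species", "gene_id"])["secreted"].nunique()
        inconsistent = flags[flags > 1]
        if len(inconsistent):
            gene = inconsistent.index[0]
            raise DataError(f"inconsistent secreted flag for gene {gene}")
        for sp, grp in self.rows.groupby("species"):
            n_genes = grp["gene_id"].nunique()
            total = self.proteome_total.get(sp)
            if total is None:
                raise DataError(f"no proteome total for species {sp!r}")
            if total < n_genes:
                raise DataError(
                    f"proteome total for {sp!r} ({total}) below distinct "
                    f"annotated genes ({n_genes})"
                )

    @property
    def species(self) -> list[str]:
        return sorted(self.proteome_total)


@dataclass
class OrthogroupTable:
    """Orthogroup membership: og_id -> species -> gene ids, plus unassigned."""

    ogs: dict[str, dict[str, list[str]]]
    unassigned: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for og, by_sp in self.ogs.items():
            if not any(by_sp.values()):
                raise DataError(f"orthogroup {og!r} has no genes")
            for sp, genes in by_sp.items():
                for g in genes:
                    key = (sp, g)
                    if key in seen:
                        raise DataError(
                            f"gene {g!r} ({sp}) in both {seen[key]!r} and {og!r}"
                        )
                    seen[key] = og
        for sp, genes in self.unassigned.items():
            for g in genes:
                if (sp, g) in seen:
                    raise DataError(
                        f"gene {g!r} ({sp}) both assigned ({seen[(sp, g)]!r}) "
                        "and unassigned"
                    )

    @property
    def species(self) -> list[str]:
        out: set[str] = set(self.unassigned)
        for by_sp in self.ogs.values():
            out.update(by_sp)
        return sorted(out)

    def assigned_genes(self, sp: str) -> set[str]:
        return {
            g for by_sp in self.ogs.values() for g in by_sp.get(sp, [])
        }


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat-element occurrence from a masked assembly."""

    class_family: str
    length_bp: int
    kimura_pct: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise DataError(f"non-positive repeat length: {self.length_bp}")
        if not (self.kimura_pct >= 0 and self.kimura_pct == self.kimura_pct):
            raise DataError(f"invalid Kimura divergence: {self.kimura_pct}")


@dataclass
class ExpressionTable:
    """Pooled estimated counts per gene (summed over samples)."""

    counts: dict[str, float]

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0:
                raise DataError(f"negative pooled count for {g!r}: {c}")

    def get(self, gene: str) -> float:
        """Pooled count, with absent genes treated as 0 (no evidence)."""
        return self.counts.get(gene, 0.0)


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(raw: str, contig: str) -> tuple[str, int]:
    seq = raw.upper()
    n_ambig = 0
    if not set(seq) <= VALID_BASES:
        cleaned = []
        for ch in seq:
            if ch in VALID_BASES:
                cleaned.append(ch)
            elif ch in IUPAC_AMBIGUITY:
                cleaned.append("N")
                n_ambig += 1
            else:
                raise DataError(
                    f"contig {contig!r}: illegal character {ch!r} in sequence"
                )
        seq = "".join(cleaned)
    return seq, n_ambig


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA assembly, upper-casing and mapping ambiguity codes to N."""
    path = Path(path)
    contigs: dict[str, str] = {}
    n_ambig = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise DataError(f"{path}: duplicate contig id {rec.id!r}")
        seq, ambig = _clean_sequence(str(rec.seq), rec.id)
        if not seq:
            raise DataError(f"{path}: contig {rec.id!r} has empty sequence")
        contigs[rec.id] = seq
        n_ambig += ambig
    if not contigs:
        raise DataError(f"{path}: no FASTA records")
    if n_ambig:
        logger.info("%s: mapped %d IUPAC ambiguity bases to N", path, n_ambig)
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Domain annotation tables


def read_domain_table(path: str | Path, totals_path: str | Path) -> DomainAnnotationTable:
    """Read the per-gene domain TSV plus its companion proteome-totals TSV.

    The main table has header columns species, gene_id, domain_id,
    domain_type, secreted (true/false). The totals file has columns
    species, total.
    """
    rows = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["species", "gene_id", "domain_id", "domain_type", "secreted"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    rows = rows[required].copy()
    low = rows["secreted"].str.strip().str.lower()
    valid = {"true": True, "false": False, "1": True, "0": False}
    if not low.isin(valid).all():
        bad = rows.loc[~low.isin(valid), "secreted"].iloc[0]
        raise DataError(f"{path}: unparseable secreted flag {bad!r}")
    rows["secreted"] = low.map(valid)
    rows["domain_type"] = rows["domain_type"].str.upper()
    totals_df = pd.read_csv(totals_path, sep="\t", dtype={"species": str, "total": int},
                            comment="#")
    if not {"species", "total"} <= set(totals_df.columns):
        raise DataError(f"{totals_path}: expected columns species, total")
    totals = dict(zip(totals_df["species"], totals_df["total"]))
    return DomainAnnotationTable(rows.reset_index(drop=True), totals)


def write_domain_table(table: DomainAnnotationTable, path: str | Path,
                       totals_path: str | Path) -> None:
    out = table.rows.copy()
    out["secreted"] = out["secreted"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {"species": list(table.proteome_total), "total": list(table.proteome_total.values())}
    ).to_csv(totals_path, sep="\t", index=False)


def warn_if_isoform_ids(table: DomainAnnotationTable) -> bool:
    """Warn when gene ids look like transcript isoforms of the same gene.

    Isoform collapsing (longest peptide per gene) is the caller's job; this
    only flags the smell of ``-T1``/``-T2`` suffixed duplicates.
    """
    ids = table.rows["gene_id"]
    suffixed = ids[ids.str.contains(_ISOFORM_SUFFIX)]
    stems = suffixed.str.replace(_ISOFORM_SUFFIX, "", regex=True)
    dup = stems.duplicated().any() and suffixed.nunique() > stems.nunique()
    if dup:
        warnings.warn(
            "gene ids look like uncollapsed isoforms (-T<N> suffixes with "
            "shared stems); collapse to longest peptide per gene first",
            stacklevel=2,
        )
    return bool(dup)


# ---------------------------------------------------------------------------
# Orthogroups (OrthoFinder Orthogroups.tsv dialect)


def _parse_og_cells(path: Path) -> tuple[list[str], dict[str, dict[str, list[str]]]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    species = list(df.columns[1:])
    ogs: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = row.iloc[0]
        by_sp: dict[str, list[str]] = {}
        for sp in species:
            cell = row[sp]
            genes = [g.strip() for g in cell.split(",") if g.strip()] if cell else []
            by_sp[sp] = genes
        ogs[og] = by_sp
    return species, ogs


def read_orthogroups(path: str | Path,
                     unassigned_path: str | Path | None = None) -> OrthogroupTable:
    """Read Orthogroups.tsv (and optionally Orthogroups_UnassignedGenes.tsv).

    Both files share the dialect: header row of species names after an OG-id
    column, cells holding comma-separated gene lists (possibly empty). The
    unassigned file's singleton "orthogroups" are flattened into per-species
    unassigned gene lists.
    """
    species, ogs = _parse_og_cells(Path(path))
    unassigned: dict[str, list[str]] = {sp: [] for sp in species}
    if unassigned_path is not None:
        u_species, u_ogs = _parse_og_cells(Path(unassigned_path))
        for sp in u_species:
            unassigned.setdefault(sp, [])
        for by_sp in u_ogs.values():
            for sp, genes in by_sp.items():
                unassigned[sp].extend(genes)
    return OrthogroupTable(ogs, unassigned)


def write_orthogroups(table: OrthogroupTable, path: str | Path,
                      unassigned_path: str | Path | None = None) -> None:
    species = table.species
    rows = []
    for og, by_sp in table.ogs.items():
        rows.append([og] + [", ".join(by_sp.get(sp, [])) for sp in species])
    pd.DataFrame(rows, columns=["Orthogroup"] + species).to_csv(
        path, sep="\t", index=False)
    if unassigned_path is not None:
        u_rows = []
        i = 0
        for sp in species:
            for g in table.unassigned.get(sp, []):
                u_rows.append([f"OGU{i:07d}"] + [g if s == sp else "" for s in species])
                i += 1
        pd.DataFrame(u_rows, columns=["Orthogroup"] + species).to_csv(
            unassigned_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Repeat divergence tables


def read_repeat_divergence(path: str | Path) -> list[RepeatRecord]:
    """Read the 3-column TSV (class_family, length_bp, kimura_pct).

    This is a distillation of RepeatMasker's calcDivergence output; parsing
    the raw .align files is upstream of this package.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["class_family", "length_bp", "kimura_pct"], header=None,
        dtype={"class_family": str}, skip_blank_lines=True,
    )
    # tolerate a header line
    if len(df) and df.iloc[0]["class_family"] == "class_family":
        df = df.iloc[1:]
    if df.empty:
        warnings.warn(f"{path}: empty repeat table", stacklevel=2)
        return []
    records = [
        RepeatRecord(str(r.class_family), int(r.length_bp), float(r.kimura_pct))
        for r in df.itertuples(index=False)
    ]
    return records


def write_repeat_divergence(records: Iterable[RepeatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class_family\tlength_bp\tkimura_pct\n")
        for r in records:
            fh.write(f"{r.class_family}\t{r.length_bp}\t{r.kimura_pct}\n")


# ---------------------------------------------------------------------------
# Expression tables


def read_expression(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if not {"gene_id", "pooled_count"} <= set(df.columns):
        raise DataError(f"{path}: expected columns gene_id, pooled_count")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise DataError(f"{path}: duplicate gene_id {dup!r}")
    return ExpressionTable(dict(zip(df["gene_id"], df["pooled_count"].astype(float))))


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(table.counts), "pooled_count": list(table.counts.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED output for window scans


def write_windows_bed(records: Sequence, path: str | Path) -> None:
    """BED5: contig, start, end, 'win', composite index (NA when undefined)."""
    with open(path, "w") as fh:
        for rec in records:
            score = "NA" if rec.composite_index is None else f"{rec.composite_index:.6g}"
            fh.write(f"{rec.contig_id}\t{rec.start}\t{rec.end}\twin\t{score}\n")
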