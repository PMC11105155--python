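"""Synthetic input generators with planted ground truth.

Every generator is a pure function of its parameters and a seed; a single
global seed fans out into independent per-component substreams (keyed by a
component tag), so adding a generator never perturbs existing streams.
Ground truth is returned as a :class:`SimulationTruth` that serializes to
JSON next to the generated tables, letting every downstream stage be
benchmarked against what was planted.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import (
    DataError,
    DomainAnnotationTable,
    ExpressionTable,
    GenomeSequence,
    OrthogroupTable,
)

import pandas as pd


def component_rng(seed: int, tag: str) -> np.random.Generator:
    """An independent substream for one generator component."""
    key = zlib.crc32(tag.encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


@dataclass
class SimulationTruth:
    """What was planted, keyed the way the estimators report it."""

    rip_windows: list[tuple[str, int, int, float]] = field(default_factory=list)
    enriched_domains: dict[str, float] = field(default_factory=dict)  # "sp:dom" -> fold
    og_pattern_counts: dict[str, int] = field(default_factory=dict)  # "A&B" -> n
    silent_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# Genomes and RIP planting


#: default TpA odds ratio of the background model. Genomes universally
#: suppress TpA (the classic dinucleotide bias); a RIP-free background with
#: TpA/ApT below 1 is what makes the composite-index threshold of 0
#: discriminative. 0.65 sits in the range observed across compact
#: eukaryotic genomes.
DEFAULT_TA_ODDS = 0.65

_BASE_ORDER = "ACGT"


def _transition_matrix(p: np.ndarray, ta_odds: float) -> np.ndarray:
    """First-order transitions with TpA down-weighted by ``ta_odds``,
    composition-corrected so the stationary distribution equals ``p``."""
    W = np.ones((4, 4))
    W[_BASE_ORDER.index("T"), _BASE_ORDER.index("A")] = ta_odds
    q = p.copy()
    for _ in range(100):
        P = q[None, :] * W
        P /= P.sum(axis=1, keepdims=True)
        pi = p.copy()
        for _ in range(200):
            pi = pi @ P
        if np.max(np.abs(pi - p)) < 1e-12:
            break
        q *= p / pi
        q /= q.sum()
    return P


def simulate_genome(
    n_contigs: int,
    lengths: Sequence[int],
    gc: float = 0.5,
    seed: int = 0,
    ta_odds: float = DEFAULT_TA_ODDS,
) -> GenomeSequence:
    """Background contigs with the given GC content and TpA suppression.

    Bases follow a first-order Markov chain whose stationary composition is
    exactly the requested GC (split equally G/C and A/T) and whose TpA
    transitions are down-weighted by ``ta_odds``, emulating the TpA
    depletion of real, RIP-free genomic sequence. ``ta_odds=1`` gives
    i.i.d. bases.
    """
    if not 0 < gc < 1:
        raise DataError(f"gc must be in (0, 1), got {gc}")
    if not 0 < ta_odds <= 1:
        raise DataError(f"ta_odds must be in (0, 1], got {ta_odds}")
    if len(lengths) != n_contigs:
        raise DataError("lengths must have one entry per contig")
    if any(L <= 0 for L in lengths):
        raise DataError("contig lengths must be positive")
    rng = component_rng(seed, "genome")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    P = _transition_matrix(p, ta_odds)
    cum_rows = np.cumsum(P, axis=1)
    cum_p = np.cumsum(p)
    contigs: dict[str, str] = {}
    for i, L in enumerate(lengths):
        u = rng.random(L)
        states = np.empty(L, dtype=np.int8)
        s = int(np.searchsorted(cum_p, u[0]))
        states[0] = s
        for j in range(1, L):
            s = int(np.searchsorted(cum_rows[s], u[j]))
            states[j] = s
        seq = "".join(_BASE_ORDER[b] for b in states)
        contigs[f"contig_{i + 1}"] = seq
    return GenomeSequence(contigs)


def plant_rip(
    genome: GenomeSequence,
    windows: Sequence[tuple[str, int, int]],
    rate: float,
    seed: int = 0,
) -> tuple[GenomeSequence, SimulationTruth]:
    """Plant the strand-symmetric RIP signature into chosen windows.

    Within each (contig, start, end) window, every C followed by A mutates
    to T with probability ``rate``, and every G preceded by T mutates to A
    with the same probability (the CpA→TpA / TpG→TpA two-strand
    signature). Sites are chosen on the pre-mutation sequence; bases
    outside the windows are untouched. Overlapping windows are rejected.
    """
    if not 0 <= rate <= 1:
        raise DataError(f"rate must be in [0, 1], got {rate}")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for cid, start, end in windows:
        if cid not in genome.contigs:
            raise DataError(f"unknown contig {cid!r}")
        L = len(genome.contigs[cid])
        if not (0 <= start < end <= L):
            raise DataError(f"window ({cid}, {start}, {end}) out of bounds")
        by_contig.setdefault(cid, []).append((start, end))
    for cid, spans in by_contig.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise DataError(f"overlapping planted windows on {cid}")
    rng = component_rng(seed, "plant_rip")
    contigs = dict(genome.contigs)
    for cid, spans in by_contig.items():
        arr = np.frombuffer(contigs[cid].encode("ascii"), dtype="S1").copy()
        orig = arr.copy()
        for start, end in spans:
            idx = np.arange(start, end)
            # C at i with A at i+1 (context may extend one base past the window)
            c_sites = idx[
                (orig[idx] == b"C")
                & (idx + 1 < len(orig))
                & (orig[np.minimum(idx + 1, len(orig) - 1)] == b"A")
            ]
            g_sites = idx[
                (orig[idx] == b"G")
                & (idx - 1 >= 0)
                & (orig[np.maximum(idx - 1, 0)] == b"T")
            ]
            arr[c_sites[rng.random(len(c_sites)) < rate]] = b"T"
            arr[g_sites[rng.random(len(g_sites)) < rate]] = b"A"
        contigs[cid] = arr.tobytes().decode("ascii")
    truth = SimulationTruth(
        rip_windows=[(cid, s, e, rate) for cid, s, e in windows]
    )
    return GenomeSequence(contigs), truth


# ---------------------------------------------------------------------------
# Domain tables


def simulate_domain_tables(
    n_species: int,
    n_domains: int,
    totals: int | Mapping[str, int],
    base_mean: float,
    enrichments: Mapping[tuple[str, str], float] | None = None,
    secreted_prob: float = 0.2,
    seed: int = 0,
) -> tuple[DomainAnnotationTable, SimulationTruth]:
    """Per-species domain counts with Poisson baselines and planted folds.

    counts[s][d] ~ Poisson(base_mean * fold(s, d)) capped at the proteome
    total; each counted protein is a distinct gene drawn uniformly from the
    species' gene pool, so multi-domain proteins arise by overlap. Secreted
    flags are Bernoulli per gene.
    """
    enrichments = dict(enrichments or {})
    species = [f"SP{i + 1}" for i in range(n_species)]
    if isinstance(totals, Mapping):
        totals_map = dict(totals)
        species = list(totals_map)
    else:
        totals_map = {sp: int(totals) for sp in species}
    domains = [f"PF{i + 1:05d}" for i in range(n_domains)]
    for (sp, dom), fold in enrichments.items():
        if fold <= 0:
            raise DataError(f"fold must be positive, got {fold}")
        if base_mean * fold > totals_map[sp]:
            raise DataError(
                f"expected count {base_mean * fold} exceeds proteome total "
                f"of {sp}"
            )
    rng = component_rng(seed, "domain_tables")
    rows = []
    secreted_flags: dict[tuple[str, str], bool] = {}
    for sp in species:
        total = totals_map[sp]
        gene_ids = np.array([f"{sp}_g{j + 1:06d}" for j in range(total)])
        for dom in domains:
            fold = enrichments.get((sp, dom), 1.0)
            count = min(int(rng.poisson(base_mean * fold)), total)
            if count == 0:
                continue
            genes = rng.choice(gene_ids, size=count, replace=False)
            for g in genes:
                key = (sp, g)
                if key not in secreted_flags:
                    secreted_flags[key] = bool(rng.random() < secreted_prob)
                rows.append((sp, g, dom, "PFAM", secreted_flags[key]))
    table = DomainAnnotationTable(
        pd.DataFrame(
            rows, columns=["species", "gene_id", "domain_id", "domain_type", "secreted"]
        ),
        totals_map,
    )
    truth = SimulationTruth(
        enriched_domains={f"{sp}:{dom}": fold for (sp, dom), fold in enrichments.items()}
    )
    return table, truth


# ---------------------------------------------------------------------------
# Orthogroups


def simulate_orthogroups(
    pattern_counts: Mapping[frozenset[str] | tuple[str, ...], int],
    genes_per_og_range: tuple[int, int] = (1, 4),
    unassigned_per_species: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[OrthogroupTable, SimulationTruth]:
    """Orthogroup tables with exactly the requested occupancy patterns."""
    unassigned_per_species = dict(unassigned_per_species or {})
    patterns = {frozenset(k): v for k, v in pattern_counts.items()}
    if any(not p for p in patterns):
        raise DataError("pattern keys must be non-empty species subsets")
    lo, hi = genes_per_og_range
    if not (1 <= lo <= hi):
        raise DataError(f"bad genes_per_og_range {genes_per_og_range}")
    rng = component_rng(seed, "orthogroups")
    species = sorted(set().union(*patterns) if patterns else set()) or sorted(
        unassigned_per_species
    )
    ogs: dict[str, dict[str, list[str]]] = {}
    counters = {sp: 0 for sp in species}
    i = 0
    for pat in sorted(patterns, key=lambda p: (len(p), sorted(p))):
        for _ in range(patterns[pat]):
            og = f"OG{i:07d}"
            i += 1
            by_sp: dict[str, list[str]] = {sp: [] for sp in species}
            for sp in sorted(pat):
                n = int(rng.integers(lo, hi + 1))
                for _ in range(n):
                    counters[sp] += 1
                    by_sp[sp].append(f"{sp}_g{counters[sp]:06d}")
            ogs[og] = by_sp
    unassigned = {}
    for sp in species:
        k = unassigned_per_species.get(sp, 0)
        genes = []
        for _ in range(k):
            counters[sp] = counters.get(sp, 0) + 1
            genes.append(f"{sp}_u{counters[sp]:06d}")
        unassigned[sp] = genes
    truth = SimulationTruth(
        og_pattern_counts={"&".join(sorted(p)): n for p, n in patterns.items()}
    )
    return OrthogroupTable(ogs, unassigned), truth


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    genes: Sequence[str],
    silent_fraction: float,
    active_mean: float = 100.0,
    sigma: float = 0.75,
    seed: int = 0,
) -> tuple[ExpressionTable, SimulationTruth]:
    """Pooled counts: silent genes uniform on [0, 5), active genes log-normal.

    The log-normal is parameterized so its arithmetic mean is
    ``active_mean``; the default log-scale spread (sigma = 0.75, moderate
    biological variability) keeps the chance of an active gene at mean 100
    falling under the 5-count filter negligible (~1.5e-4). The silent set
    is recorded as truth.
    """
    if not 0 <= silent_fraction <= 1:
        raise DataError(f"silent_fraction must be in [0, 1], got {silent_fraction}")
    if active_mean <= 0:
        raise DataError("active_mean must be positive")
    if sigma <= 0:
        raise DataError("sigma must be positive")
    rng = component_rng(seed, "expression")
    genes = list(genes)
    n_silent = int(round(silent_fraction * len(genes)))
    silent_idx = set(rng.choice(len(genes), size=n_silent, replace=False).tolist())
    mu = float(np.log(active_mean)) - sigma**2 / 2
    counts = {}
    for i, g in enumerate(genes):
        if i in silent_idx:
            counts[g] = float(rng.uniform(0, 5))
        else:
            counts[g] = float(rng.lognormal(mu, sigma))
    truth = SimulationTruth(silent_genes=[genes[i] for i in sorted(silent_idx)])
    return ExpressionTable(counts), truth
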