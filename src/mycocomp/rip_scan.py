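"""Sliding-window RIP (repeat-induced point mutation) detection.

RIP converts C to T at (mostly) CpA dinucleotides within duplicated
sequence, leaving an excess of TpA and a deficit of CpA/TpG. The composite
RIP index per window is

    composite = TpA/ApT - (CpA + TpG)/(ApC + GpT)

where TpA/ApT is the *product* index (RIP products accumulate TpA) and
(CpA+TpG)/(ApC+GpT) the *substrate* index (RIP depletes its substrate
dinucleotides). A window with composite > 0 is scored as RIPped; the
fraction of such windows over a 1 kb / 500 bp sliding scan summarizes the
percent of the genome RIPped.

Indices with zero denominators are undefined; undefined is a value, not an
error, and such windows by default stay in the denominator of the percent
(conservative: gaps never inflate the RIP estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np

from .io_formats import GenomeSequence

BASES = "ACGT"
_BASE_CODE = {ord(b): i for i, b in enumerate(BASES)}
_N_CODE = 4

#: dinucleotide labels in (first*4 + second) order over ACGT
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T,N -> 0..4 as a uint8 array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _N_CODE, dtype=np.uint8)
    for byte, code in _BASE_CODE.items():
        out[arr == byte] = code
    return out


@dataclass(frozen=True)
class DinucCounts:
    """Overlapping dinucleotide counts of one window (N-containing skipped)."""

    counts: tuple[int, ...]  # length 16, (first*4 + second) over ACGT

    def __getitem__(self, dinuc: str) -> int:
        return self.counts[DINUCLEOTIDES.index(dinuc)]

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class WindowIndexRecord:
    contig_id: str
    start: int  # 0-based, half-open
    end: int
    product_index: Optional[float]
    substrate_index: Optional[float]
    composite_index: Optional[float]

    @property
    def ripped(self) -> bool:
        return self.composite_index is not None and self.composite_index > 0


@dataclass(frozen=True)
class RipSummary:
    total_windows: int
    defined_windows: int
    ripped_windows: int
    pct_ripped: Optional[float]  # percent; None when no windows
    denominator: Literal["all", "defined"] = "all"


def count_dinucleotides(seq: str) -> DinucCounts:
    """Count the 16 overlapping dinucleotides; pairs containing N are skipped."""
    if len(seq) < 2:
        return DinucCounts((0,) * 16)
    code = _encode(seq.upper())
    first, second = code[:-1], code[1:]
    valid = (first != _N_CODE) & (second != _N_CODE)
    pair = first[valid].astype(np.int16) * 4 + second[valid]
    counts = np.bincount(pair, minlength=16)
    return DinucCounts(tuple(int(c) for c in counts))


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def rip_indices(
    d: DinucCounts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Product, substrate and composite RIP indices (None when undefined)."""
    product = _ratio(d["TA"], d["AT"])
    substrate = _ratio(d["CA"] + d["TG"], d["AC"] + d["GT"])
    composite = (
        None if product is None or substrate is None else product - substrate
    )
    return product, substrate, composite


def _window_starts(contig_len: int, window_bp: int, step_bp: int) -> range:
    if contig_len < window_bp:
        return range(0)
    return range(0, contig_len - window_bp + 1, step_bp)


def scan_windows(
    genome: GenomeSequence, window_bp: int = 1000, step_bp: int = 500
) -> list[WindowIndexRecord]:
    """Compute RIP indices in sliding windows over every contig.

    Windows start at 0, step, 2*step, ... and must fit entirely within the
    contig; trailing partial windows are skipped (index variance explodes in
    short windows). Records are ordered by (contig, start) with contigs in
    input order.
    """
    if window_bp < 2:
        raise ValueError(f"window_bp must be >= 2, got {window_bp}")
    if not (1 <= step_bp <= window_bp):
        raise ValueError(f"step_bp must be in [1, window_bp], got {step_bp}")
    records: list[WindowIndexRecord] = []
    for cid, seq in genome.contigs.items():
        code = _encode(seq)
        first, second = code[:-1].astype(np.int64), code[1:].astype(np.int64)
        valid = (first != _N_CODE) & (second != _N_CODE)
        pair = np.where(valid, first * 4 + second, -1)
        # prefix sums of the six index dinucleotides: O(len) per contig
        needed = {
            lab: np.concatenate(
                ([0], np.cumsum(pair == DINUCLEOTIDES.index(lab)))
            )
            for lab in ("TA", "AT", "CA", "TG", "AC", "GT")
        }

        def window_count(lab: str, s: int, e: int) -> int:
            # dinucleotide start positions s .. e-2 inclusive
            cs = needed[lab]
            return int(cs[e - 1] - cs[s])

        for s in _window_starts(len(seq), window_bp, step_bp):
            e = s + window_bp
            ta, at = window_count("TA", s, e), window_count("AT", s, e)
            ca, tg = window_count("CA", s, e), window_count("TG", s, e)
            ac, gt = window_count("AC", s, e), window_count("GT", s, e)
            product = _ratio(ta, at)
            substrate = _ratio(ca + tg, ac + gt)
            composite = (
                None if product is None or substrate is None
                else product - substrate
            )
            records.append(
                WindowIndexRecord(cid, s, e, product, substrate, composite)
            )
    return records


def genome_rip_summary(
    records: Iterable[WindowIndexRecord],
    denominator: Literal["all", "defined"] = "all",
) -> RipSummary:
    """Summarize a scan into the percent of windows scored as RIPped.

    With ``denominator="all"`` (default) undefined-index windows count in
    the denominator but never the numerator; ``"defined"`` excludes them.
    """
    records = list(records)
    total = len(records)
    defined = sum(1 for r in records if r.composite_index is not None)
    ripped = sum(1 for r in records if r.ripped)
    denom = total if denominator == "all" else defined
    pct = None if denom == 0 else 100.0 * ripped / denom
    return RipSummary(total, defined, ripped, pct, denominator)
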