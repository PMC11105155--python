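"""Repeat composition and Kimura-divergence landscape summaries.

Inputs are per-element records (class/family, aligned bp, Kimura %
divergence to family consensus) distilled from a RepeatMasker run; the
landscape bins each element's bp by integer divergence (width-1,
left-closed right-open, as in createRepeatLandscape) so older copies sit in
higher bins. Percentages are of genome bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DataError, RepeatRecord

OTHER_CLASS = "Other"


def kimura2p(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions.

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)); P is the transition
    proportion, Q the transversion proportion. Raises outside the model's
    domain (saturation).
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance undefined (saturation)")
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class LandscapeMatrix:
    """classes x divergence bins -> percent of genome bp."""

    matrix: pd.DataFrame  # index: class, columns: int bin
    genome_size_bp: int

    def total_repeat_pct(self) -> float:
        return float(self.matrix.values.sum())


def composition_table(
    records: Sequence[RepeatRecord] | Mapping[str, tuple[Sequence[RepeatRecord], int]],
    genome_size: int | None = None,
    show_threshold: float = 0.001,
) -> pd.DataFrame:
    """Per-class genome fractions, flagging classes under the display cutoff.

    Single-species: pass a record list and genome_size. Multi-species: pass
    ``{species: (records, genome_size)}``. A class is ``hidden`` when its
    fraction is <= show_threshold (default 0.1% of the genome) in every
    species — the display rule for composition bar plots.
    """
    if isinstance(records, Mapping):
        tables = records
    else:
        if genome_size is None:
            raise DataError("genome_size required for a single-species call")
        tables = {"genome": (records, genome_size)}
    rows = []
    for sp, (recs, gsize) in tables.items():
        if gsize <= 0:
            raise DataError(f"genome size must be positive, got {gsize}")
        bp: dict[str, int] = {}
        for r in recs:
            bp[r.class_family] = bp.get(r.class_family, 0) + r.length_bp
        for cls, total in bp.items():
            rows.append({"species": sp, "class_family": cls,
                         "fraction": total / gsize})
    df = pd.DataFrame(rows, columns=["species", "class_family", "fraction"])
    if df.empty:
        df["pct"] = []
        df["hidden"] = []
        return df
    max_frac = df.groupby("class_family")["fraction"].max()
    df["pct"] = 100.0 * df["fraction"]
    df["hidden"] = df["class_family"].map(max_frac <= show_threshold)
    return df.drop(columns="fraction")


def landscape_bins(
    records: Iterable[RepeatRecord],
    genome_size: int,
    bin_width: float = 1.0,
    other_threshold: float = 0.01,
) -> LandscapeMatrix:
    """Bin repeat bp by Kimura divergence per class, merging rare classes.

    Each record's bp goes to bin floor(kimura_pct / bin_width) of its
    class. Classes holding less than ``other_threshold`` (default 1%) of
    total repeat bp are merged into "Other". Total bp is conserved exactly
    regardless of binning or merging.
    """
    if genome_size <= 0:
        raise DataError(f"genome size must be positive, got {genome_size}")
    records = list(records)
    if not records:
        return LandscapeMatrix(pd.DataFrame(dtype=float), genome_size)
    bp_by_class: dict[str, int] = {}
    for r in records:
        bp_by_class[r.class_family] = bp_by_class.get(r.class_family, 0) + r.length_bp
    total_bp = sum(bp_by_class.values())
    keep = {c for c, bp in bp_by_class.items() if bp >= other_threshold * total_bp}

    cells: dict[tuple[str, int], int] = {}
    max_bin = 0
    for r in records:
        cls = r.class_family if r.class_family in keep else OTHER_CLASS
        b = int(np.floor(r.kimura_pct / bin_width))
        max_bin = max(max_bin, b)
        cells[(cls, b)] = cells.get((cls, b), 0) + r.length_bp
    classes = sorted({c for c, _ in cells})
    mat = pd.DataFrame(
        0.0, index=classes, columns=range(max_bin + 1)
    )
    for (cls, b), bp in cells.items():
        mat.loc[cls, b] += 100.0 * bp / genome_size
    return LandscapeMatrix(mat, genome_size)


def landscape_to_frame(lm: LandscapeMatrix) -> pd.DataFrame:
    """Long format (class, bin, pct) for plotting or export."""
    if lm.matrix.empty:
        return pd.DataFrame(columns=["class_family", "bin", "pct"])
    long = lm.matrix.stack().reset_index()
    long.columns = ["class_family", "bin", "pct"]
    return long
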