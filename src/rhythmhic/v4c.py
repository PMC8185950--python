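"""Virtual 4C: one-viewpoint extraction of raw contact counts.

A promoter (bait) fragment is used as a fixed viewpoint and the summed raw
counts to every other fragment within a genomic window are reported, together
with arcs for the records flagged significant (exportable as washU longrange).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import RestrictionMap
from .io import InteractionTable, write_longrange
from .matrix import ContactMatrix

__all__ = ["V4CResult", "virtual_4c"]


@dataclass
class V4CResult:
    """Per-fragment (or per-bin) raw counts around a viewpoint, plus arcs."""

    viewpoint: int                 # fragment id or bin index
    track: pd.DataFrame            # chrom, start, end, count
    arcs: pd.DataFrame             # bait_frag, other_frag, score

    def write_arcs(self, fragmap: RestrictionMap, path) -> None:
        write_longrange(self.arcs, fragmap, path)


def virtual_4c(source: InteractionTable | ContactMatrix, bait,
               window_bp: int, timepoint: int | None = None,
               score_threshold: float = 5.0) -> V4CResult:
    """Extract a virtual-4C profile around ``bait``.

    For an interaction table ``bait`` is a fragment id (or ``(chrom, pos)``
    resolved through the table's fragment map); counts are summed over the
    replicates of ``timepoint`` (all timepoints when None). For a contact
    matrix ``bait`` is a bin index. Raw counts are emitted; any normalisation
    is the caller's choice.
    """
    if isinstance(source, ContactMatrix):
        return _v4c_matrix(source, bait, window_bp)
    return _v4c_table(source, bait, window_bp, timepoint, score_threshold)


def _v4c_table(table: InteractionTable, bait, window_bp, timepoint,
               score_threshold) -> V4CResult:
    fm = table.fragmap
    if fm is None:
        raise ValueError("interaction table has no fragment map")
    if isinstance(bait, tuple):
        bait = fm.fragment_at(*bait)
    bait = int(bait)
    if not (0 <= bait < fm.n_fragments):
        raise ValueError(f"bait fragment {bait} not in fragment map")
    bait_iv = fm.interval(bait)
    bait_mid = bait_iv.midpoint

    recs = table.df[table.df["bait_frag"] == bait]
    if timepoint is not None:
        cols = [c for c in table.count_columns if f"_ZT{timepoint}_" in c]
    else:
        cols = table.count_columns

    sums: dict[int, float] = {}
    arc_rows = []
    for _, r in recs.iterrows():
        other = int(r["other_frag"])
        iv = fm.interval(other)
        cis = iv.chrom == bait_iv.chrom
        if cis and abs(iv.midpoint - bait_mid) > window_bp:
            continue
        if not cis:
            continue
        count = float(sum(r[c] for c in cols)) if cols else 0.0
        sums[other] = sums.get(other, 0.0) + count
        score = (r[f"score_ZT{timepoint}"]
                 if timepoint is not None and f"score_ZT{timepoint}" in r.index
                 else r.get("score", 0.0))
        if score >= score_threshold:
            arc_rows.append((bait, other, float(score)))

    rows = []
    for frag, count in sorted(sums.items()):
        iv = fm.interval(frag)
        rows.append((iv.chrom, iv.start, iv.end, count))
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    arcs = pd.DataFrame(arc_rows, columns=["bait_frag", "other_frag", "score"])
    return V4CResult(bait, track, arcs)


def _v4c_matrix(matrix: ContactMatrix, bait_bin: int, window_bp: int) -> V4CResult:
    bait_bin = int(bait_bin)
    if not (0 <= bait_bin < matrix.n_bins):
        raise ValueError(f"bait bin {bait_bin} outside matrix")
    w = window_bp // matrix.bin_size
    lo, hi = max(0, bait_bin - w), min(matrix.n_bins, bait_bin + w + 1)
    rows = [
        (matrix.chrom, b * matrix.bin_size, (b + 1) * matrix.bin_size,
         float(matrix.counts[bait_bin, b]))
        for b in range(lo, hi)
    ]
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    arcs = pd.DataFrame(columns=["bait_frag", "other_frag", "score"])
    return V4CResult(bait_bin, track, arcs)
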