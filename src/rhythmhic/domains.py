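"""Insulation scores, TAD calling, cross-timepoint sharing and metaplots.

The insulation score of bin ``i`` is the mean contact count in the square
window straddling the diagonal at ``i`` (rows ``[i-w, i)`` x columns
``(i, i+w]`` with ``w = window_bp / bin_size``). Boundaries are strict local
minima of the score below a threshold; TADs are the intervals between
consecutive boundaries, filtered by size. TAD structure is expected to be
time-invariant: sharing between timepoints uses the >80%-overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomicInterval
from .matrix import BalancedMatrix, ContactMatrix

__all__ = ["InsulationTrack", "TAD", "MetaplotResult", "insulation_score",
           "find_boundaries", "call_tads", "shared_tads", "tad_metaplot",
           "point_metaplot", "boundary_positions"]


@dataclass
class InsulationTrack:
    chrom: str
    bin_size: int
    window_bp: int
    score: np.ndarray             # NaN within window_bp of chromosome ends
    normalized_score: np.ndarray  # log2(score / chromosome mean score)

    @property
    def window_bins(self) -> int:
        return self.window_bp // self.bin_size


@dataclass
class TAD:
    interval: GenomicInterval
    timepoint: int | None = None
    params: dict = field(default_factory=dict)
    n_genes: int | None = None

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class MetaplotResult:
    grid: np.ndarray
    n_features: int
    n_skipped: int = 0


def _counts_of(matrix) -> tuple[str, int, np.ndarray]:
    if isinstance(matrix, BalancedMatrix):
        return matrix.chrom, matrix.bin_size, matrix.balanced
    if isinstance(matrix, ContactMatrix):
        return matrix.chrom, matrix.bin_size, matrix.counts
    raise TypeError("expected ContactMatrix or BalancedMatrix")


def insulation_score(matrix, window_bp: int) -> InsulationTrack:
    """Mean contact in the off-diagonal square window at each bin."""
    chrom, bin_size, M = _counts_of(matrix)
    if window_bp % bin_size:
        raise ValueError("window_bp must be a multiple of bin_size")
    w = window_bp // bin_size
    if w < 2:
        raise ValueError("window must span >= 2 bins")
    n = M.shape[0]
    if 2 * w >= n:
        raise ValueError("window larger than chromosome")
    score = np.full(n, np.nan)
    for i in range(w, n - w):
        sub = M[i - w:i, i + 1:i + w + 1]
        score[i] = np.nanmean(sub) if np.isfinite(sub).any() else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.nanmean(score)
        normalized = np.log2(score / mean) if mean and mean > 0 else np.full(n, np.nan)
    return InsulationTrack(chrom, bin_size, window_bp, score, normalized)


def find_boundaries(track: InsulationTrack, threshold: float) -> list[int]:
    """Boundary bins: local minima of the raw score within +/- w bins that
    lie below ``threshold``.

    Minima are strict against the left neighbourhood and non-strict against
    the right, so exact ties resolve deterministically to the leftmost bin.
    """
    s = track.score
    w = track.window_bins
    n = len(s)
    boundaries = []
    for i in range(n):
        if np.isnan(s[i]) or s[i] >= threshold:
            continue
        left = s[max(0, i - w):i]
        right = s[i + 1:min(n, i + w + 1)]
        left = left[~np.isnan(left)]
        right = right[~np.isnan(right)]
        if (left.size + right.size
                and np.all(s[i] < left) and np.all(s[i] <= right)):
            boundaries.append(i)
    return boundaries


def call_tads(track: InsulationTrack, threshold: float,
              min_size_bp: int = 150_000, max_size_bp: int = 1_500_000,
              timepoint: int | None = None) -> list[TAD]:
    """TADs between insulation-score boundary minima.

    A boundary bin is a strict local minimum of the raw score within +/- w
    bins whose score is below ``threshold`` (leftmost bin wins exact ties by
    the strictness rule). TADs never span masked gaps.
    """
    boundaries = find_boundaries(track, threshold)
    s = track.score
    params = {"bin_size": track.bin_size, "window_bp": track.window_bp,
              "threshold": threshold}
    tads = []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        if np.isnan(s[b0 + 1:b1]).any():  # masked gap between boundaries
            continue
        start, end = b0 * track.bin_size, b1 * track.bin_size
        size = end - start
        if size < max(min_size_bp, 2 * track.bin_size) or size > max_size_bp:
            continue
        tads.append(TAD(GenomicInterval(track.chrom, start, end),
                        timepoint, dict(params)))
    return tads


def boundary_positions(tads: list[TAD]) -> np.ndarray:
    """All distinct TAD edge positions in bp."""
    pos = {t.interval.start for t in tads} | {t.interval.end for t in tads}
    return np.array(sorted(pos), dtype=np.int64)


@dataclass
class SharedTADResult:
    pairs: list[tuple[TAD, TAD, float]]
    shared: list[TAD]
    unshared: list[TAD]

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def shared_tads(a: list[TAD], b: list[TAD], min_frac: float = 0.8) -> SharedTADResult:
    """A TAD in ``a`` is shared when some TAD in ``b`` covers > min_frac of it."""
    pairs, shared, unshared = [], [], []
    for x in a:
        best, best_frac = None, 0.0
        for y in b:
            if y.interval.chrom != x.interval.chrom:
                continue
            ov = (min(x.interval.end, y.interval.end)
                  - max(x.interval.start, y.interval.start))
            frac = max(ov, 0) / x.length
            if frac > best_frac:
                best, best_frac = y, frac
        if best is not None and best_frac > min_frac:  # strict >
            pairs.append((x, best, best_frac))
            shared.append(x)
        else:
            unshared.append(x)
    return SharedTADResult(pairs, shared, unshared)


# ---------------------------------------------------------------------------
# Metaplots

def _rebin_cuts(f: float, span: float, n_core: int, flank_bins: int) -> np.ndarray:
    """Target-cell cuts in source-bin coordinates: flank | core | flank."""
    return np.concatenate([
        np.linspace(0.0, f, flank_bins + 1)[:-1],
        np.linspace(f, f + span, n_core + 1)[:-1],
        np.linspace(f + span, 2 * f + span, flank_bins + 1),
    ])


def _weight_matrix(cuts: np.ndarray, n_src: int) -> np.ndarray:
    """Area overlap of each target cell with each source bin, rows normalized."""
    G = len(cuts) - 1
    W = np.zeros((G, n_src))
    for g in range(G):
        lo, hi = cuts[g], cuts[g + 1]
        for j in range(int(np.floor(lo)), min(int(np.ceil(hi)), n_src)):
            W[g, j] = min(hi, j + 1) - max(lo, j)
    rowsum = W.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return W / rowsum


def _rebin_2d(sub: np.ndarray, W: np.ndarray) -> np.ndarray:
    """NaN-aware area-weighted rebinning of a square matrix onto W's grid."""
    finite = np.isfinite(sub)
    num = W @ np.where(finite, sub, 0.0) @ W.T
    den = W @ finite.astype(float) @ W.T
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def tad_metaplot(oe: np.ndarray, tads: list[TAD], bin_size: int,
                 flank_bins: int = 5, n_core: int = 5,
                 sample_n: int | None = None,
                 seed: int | None = None) -> MetaplotResult:
    """Median O/E pileup of TADs rescaled onto a fixed grid.

    Each TAD (plus flanks of half its length on each side) is rescaled by
    area-weighted averaging so the domain occupies the ``n_core`` central
    bins; the grid cell is the median across TADs.
    """
    if not tads:
        raise ValueError("need at least one TAD")
    if sample_n is not None and sample_n < len(tads):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(tads), size=sample_n, replace=False)
        tads = [tads[i] for i in sorted(idx)]

    n = oe.shape[0]
    G = n_core + 2 * flank_bins
    stacks, skipped = [], 0
    for tad in tads:
        b0 = tad.interval.start // bin_size
        b1 = -(-tad.interval.end // bin_size)
        span = b1 - b0
        if span < n_core:
            skipped += 1
            continue
        f = span / 2.0
        lo = int(np.floor(b0 - f))
        hi = int(np.ceil(b1 + f))
        if lo < 0 or hi > n:
            skipped += 1
            continue
        sub = oe[lo:hi, lo:hi]
        cuts = _rebin_cuts(f, span, n_core, flank_bins) + (b0 - f - lo)
        W = _weight_matrix(cuts, hi - lo)
        stacks.append(_rebin_2d(sub, W))
    if not stacks:
        return MetaplotResult(np.full((G, G), np.nan), 0, skipped)
    grid = np.nanmedian(np.stack(stacks), axis=0)
    return MetaplotResult(grid, len(stacks), skipped)


def point_metaplot(oe: np.ndarray, points, bin_size: int, window_bins: int,
                   sample_n: int | None = None,
                   seed: int | None = None) -> MetaplotResult:
    """Median O/E in (2k+1)^2 neighborhoods centred on point features."""
    k = window_bins
    n = oe.shape[0]
    bins = [p.midpoint // bin_size if isinstance(p, GenomicInterval) else int(p)
            for p in points]
    if sample_n is not None and sample_n < len(bins):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(bins), size=sample_n, replace=False)
        bins = [bins[i] for i in sorted(idx)]
    stacks, skipped = [], 0
    for b in bins:
        if b - k < 0 or b + k + 1 > n:
            skipped += 1
            continue
        stacks.append(oe[b - k:b + k + 1, b - k:b + k + 1])
    if not stacks:
        return MetaplotResult(np.full((2 * k + 1, 2 * k + 1), np.nan), 0, skipped)
    grid = np.nanmedian(np.stack(stacks), axis=0)
    return MetaplotResult(grid, len(stacks), skipped)
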