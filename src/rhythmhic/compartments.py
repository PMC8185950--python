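"""A/B compartment eigenvectors and oscillatory chromatin compartments (OCCs).

The leading eigenvector (PC1) of the Pearson correlation matrix of the
observed/expected contact map partitions a chromosome into A (PC1 > 0) and B
(PC1 < 0) compartments at 100-kb resolution. The sign is anchored to an
activity covariate (an active-chromatin coverage track): PC1 is flipped so it
correlates positively with activity.

An OCC is a run of bins whose compartment assignment switches between
timepoints: a bin qualifies when a one-way ANOVA of its replicate PC1 values
grouped by timepoint is significant after Benjamini-Hochberg correction AND
its merged-replicate sign differs between at least one timepoint pair. Each
OCC carries a 4-letter category string over (ZT0, ZT6, ZT12, ZT18), e.g.
"AABA" = A at ZT0/6/18 and B at ZT12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import CoverageTrack, GenomicInterval, ZT_TIMEPOINTS
from .matrix import BalancedMatrix, oe_transform

__all__ = ["EigenTrack", "CompartmentSegment", "OCCRegion", "compute_pc1",
           "segment_compartments", "detect_occ", "quantify_in_regions",
           "group_test"]


@dataclass
class EigenTrack:
    """Per-bin PC1 values per (timepoint, replicate) and merged per timepoint."""

    chrom: str
    bin_size: int
    merged: dict[int, np.ndarray] = field(default_factory=dict)
    replicates: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    orientation_covariate: str = "activity"

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.merged)

    @property
    def n_bins(self) -> int:
        return len(next(iter(self.merged.values())))


@dataclass(frozen=True)
class CompartmentSegment:
    interval: GenomicInterval
    timepoint: int
    label: str  # "A" or "B"


@dataclass(frozen=True)
class OCCRegion:
    interval: GenomicInterval
    category: str     # e.g. "AABA" over (ZT0, ZT6, ZT12, ZT18)
    anova_p: float    # minimum adjusted p over the region's bins
    n_bins: int


def compute_pc1(balanced: BalancedMatrix, activity: CoverageTrack,
                min_bins: int = 10) -> np.ndarray:
    """Leading eigenvector of the O/E Pearson correlation matrix, sign-anchored.

    Masked bins come back NaN. Raises on < ``min_bins`` unmasked bins or a
    zero-variance correlation input.
    """
    if len(activity) != balanced.n_bins:
        raise ValueError("activity track not on the matrix bin grid")
    oe = oe_transform(balanced)
    active = ~balanced.mask
    if active.sum() < min_bins:
        raise ValueError(f"only {int(active.sum())} unmasked bins (< {min_bins})")
    sub = oe[np.ix_(active, active)]
    sub = np.nan_to_num(sub, nan=1.0)  # masked diagonals carry no signal
    if np.any(np.std(sub, axis=1) == 0):
        raise ValueError("zero-variance row in correlation input")
    corr = np.corrcoef(sub)
    w, v = np.linalg.eigh(corr)
    pc1_active = v[:, -1]  # eigenvector of the largest eigenvalue

    pc1 = np.full(balanced.n_bins, np.nan)
    pc1[active] = pc1_active
    act = activity.values[active]
    if np.std(act) > 0 and np.std(pc1_active) > 0:
        r = np.corrcoef(pc1_active, act)[0, 1]
        if r < 0:
            pc1 = -pc1
    return pc1


def _sign_label(v: float) -> str:
    """A for PC1 > 0; exact zero treated as A (tie)."""
    return "A" if v >= 0 else "B"


def segment_compartments(track: EigenTrack, timepoint: int,
                         chrom_length: int | None = None) -> list[CompartmentSegment]:
    """Maximal same-sign runs of merged PC1; zero bins join the preceding run;
    masked bins break runs."""
    pc1 = track.merged[timepoint]
    n = len(pc1)
    segments: list[CompartmentSegment] = []
    run_start, run_label = None, None
    for b in range(n + 1):
        v = pc1[b] if b < n else np.nan
        if b == n or np.isnan(v):
            if run_start is not None:
                segments.append(_make_segment(track, run_start, b, run_label,
                                              timepoint, chrom_length))
                run_start = run_label = None
            continue
        label = run_label if (v == 0 and run_label is not None) else _sign_label(v)
        if run_label is None:
            run_start, run_label = b, label
        elif label != run_label:
            segments.append(_make_segment(track, run_start, b, run_label,
                                          timepoint, chrom_length))
            run_start, run_label = b, label
    return segments


def _make_segment(track, b0, b1, label, timepoint, chrom_length):
    start = b0 * track.bin_size
    end = b1 * track.bin_size
    if chrom_length is not None:
        end = min(end, chrom_length)
    return CompartmentSegment(GenomicInterval(track.chrom, start, end), timepoint, label)


def detect_occ(track: EigenTrack, alpha: float = 0.05, adjust: str = "fdr_bh",
               chrom_length: int | None = None):
    """Call oscillatory chromatin compartments from replicate PC1 tracks.

    Returns (regions, per_bin) where per_bin is a dict with the per-bin
    adjusted p-values, oscillatory flags, category strings and the count of
    bins skipped for missing replicate values.
    """
    tps = track.timepoints
    reps = sorted({r for (_, r) in track.replicates})
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates per timepoint")
    n = track.n_bins

    pvals = np.full(n, np.nan)
    skipped = 0
    for b in range(n):
        groups = []
        ok = True
        for t in tps:
            g = [track.replicates[(t, r)][b] for r in reps if (t, r) in track.replicates]
            g = [x for x in g if not np.isnan(x)]
            if len(g) < 2:
                ok = False
                break
            groups.append(g)
        if not ok or any(np.isnan(track.merged[t][b]) for t in tps):
            skipped += 1
            continue
        pooled = np.concatenate(groups)
        if np.allclose(pooled, pooled[0]):
            pvals[b] = 1.0
            continue
        _, p = stats.f_oneway(*groups)
        pvals[b] = 1.0 if np.isnan(p) else p

    tested = ~np.isnan(pvals)
    qvals = np.full(n, np.nan)
    if tested.any():
        if adjust == "none":
            qvals[tested] = pvals[tested]
        else:
            _, q, _, _ = multipletests(pvals[tested], method=adjust)
            qvals[tested] = q

    categories = np.array([
        "".join(_sign_label(track.merged[t][b]) for t in tps) if tested[b] else ""
        for b in range(n)
    ])
    switches = np.array([len(set(c)) > 1 if c else False for c in categories])
    tie = np.array([
        tested[b] and any(track.merged[t][b] == 0 for t in tps) for b in range(n)
    ])
    oscillatory = tested & (qvals < alpha) & switches

    regions: list[OCCRegion] = []
    b = 0
    while b < n:
        if not oscillatory[b]:
            b += 1
            continue
        cat = categories[b]
        b1 = b
        while b1 + 1 < n and oscillatory[b1 + 1] and categories[b1 + 1] == cat:
            b1 += 1
        start = b * track.bin_size
        end = (b1 + 1) * track.bin_size
        if chrom_length is not None:
            end = min(end, chrom_length)
        regions.append(OCCRegion(
            GenomicInterval(track.chrom, start, end), cat,
            float(np.nanmin(qvals[b:b1 + 1])), b1 - b + 1,
        ))
        b = b1 + 1

    per_bin = {"q": qvals, "p": pvals, "oscillatory": oscillatory,
               "category": categories, "tie_flag": tie, "skipped": skipped}
    return regions, per_bin


# ---------------------------------------------------------------------------
# Signal quantification within compartments

def quantify_in_regions(track: CoverageTrack, regions, library_total: float,
                        pseudocount: float = 1.0) -> np.ndarray:
    """log2(RPM + pseudocount) of summed raw counts per region.

    ``track`` holds raw read counts per bin; RPM = count / library_total * 1e6.
    """
    if library_total <= 0:
        raise ValueError("zero library total")
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        iv = region.interval if hasattr(region, "interval") else region
        b0 = iv.start // track.bin_size
        b1 = -(-iv.end // track.bin_size)
        count = np.nansum(track.values[b0:b1])
        out[i] = np.log2(count / library_total * 1e6 + pseudocount)
    return out


def group_test(groups: list[np.ndarray], test: str = "kruskal"):
    """Group-comparison test selector. Returns (statistic, p).

    ``kruskal`` (>= 2 groups), ``mannwhitney`` (2 groups),
    ``wilcoxon-paired`` (2 paired groups), ``anova+tukey`` (returns the ANOVA
    F/p; Tukey honest significant differences attached as ``.tukey``).
    """
    if test == "kruskal":
        return stats.kruskal(*groups)
    if test == "mannwhitney":
        a, b = groups
        if np.array_equal(np.sort(a), np.sort(b)):
            return np.nan, 1.0  # identical samples: maximal p
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return res.statistic, res.pvalue
    if test == "wilcoxon-paired":
        a, b = groups
        if np.allclose(a, b):
            return np.nan, 1.0
        res = stats.wilcoxon(a, b)
        return res.statistic, res.pvalue
    if test == "anova+tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        f, p = stats.f_oneway(*groups)
        values = np.concatenate(groups)
        labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
        result = (f, p)
        group_test.tukey = pairwise_tukeyhsd(values, labels)
        return result
    raise ValueError(f"unknown test {test!r}")
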