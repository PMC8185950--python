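"""Promoter-contact dynamics: differential interactions, matched-null
enrichment, phase coherence and core-clock comparisons.

Differential (dynamic vs stable) calling fits a negative-binomial model per
interaction with library-size offsets and tests the timepoint factor by a
likelihood-ratio test (3 df over four ZTs). Dispersion is a 50/50 shrinkage
of the per-interaction method-of-moments estimate toward the trimmed-mean
common dispersion. Interactions are split into near (<= 150 kb) and far
distance regimes, FDR-corrected within each, and a contact is dynamic when
q < fdr AND |log2 fold change| (max vs min timepoint normalised mean)
exceeds the cutoff.

Feature enrichment at promoter-interacting regions uses a matched
permutation null: every observed other-end is re-placed with its original
fragment length at its original bait distance (random side, random bait), so
the empirical (length, distance) joint distribution is preserved exactly in
every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import CircadianCalls, DIURNAL_ZTS
from .genome import FeatureSet, RestrictionMap
from .io import InteractionTable

__all__ = ["DynamicCalls", "EnrichmentResult", "ContactPeakResult",
           "PhaseCoherenceResult", "CoreClockComparison", "classify_dynamic",
           "contacts_per_timepoint", "matched_null_enrichment",
           "erna_contact_enrichment", "phase_coherence", "coreclock_comparison",
           "CORE_CLOCK_GENES", "nb_loglik", "fit_nb_mean"]

#: The canonical core transcription-translation feedback loop genes.
CORE_CLOCK_GENES = ("Npas2", "Clock", "Arntl", "Cry1", "Cry2",
                    "Per1", "Per2", "Rorc", "Nr1d1", "Nr1d2")


# ---------------------------------------------------------------------------
# Negative-binomial likelihood machinery

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood (variance mu + phi*mu^2); Poisson at phi = 0."""
    from scipy.special import gammaln

    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    if phi <= 0:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(phi * mu / (1 + phi * mu)), 0.0)
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + term - r * np.log1p(phi * mu)))


def fit_nb_mean(y: np.ndarray, offsets: np.ndarray, phi: float,
                tol: float = 1e-12, max_iter: int = 100) -> float:
    """MLE of a common mean m with means mu_s = offsets_s * m at fixed phi.

    Newton iteration on the 1-D score; the Poisson limit has the closed form
    sum(y) / sum(offsets).
    """
    y = np.asarray(y, float)
    s = np.asarray(offsets, float)
    if y.sum() == 0:
        return 0.0
    m = y.sum() / s.sum()
    if phi <= 0:
        return float(m)
    for _ in range(max_iter):
        denom = 1.0 + phi * s * m
        score = np.sum(y / m - (y + 1.0 / phi) * phi * s / denom)
        hess = np.sum(-y / m**2 + (y + 1.0 / phi) * (phi * s / denom) ** 2)
        if hess == 0:
            break
        step = score / hess
        m_new = m - step
        if m_new <= 0:
            m_new = m / 2.0
        if abs(m_new - m) < tol * max(m, 1.0):
            m = m_new
            break
        m = m_new
    return float(m)


# ---------------------------------------------------------------------------
# Dynamic / stable classification

@dataclass
class DynamicCalls:
    """Per-interaction LRT results; ``df`` is aligned to the tested subset."""

    df: pd.DataFrame  # index into table.df; regime, lrt_stat, p, q, log2fc, klass
    fdr: float
    min_lfc: float

    @property
    def n_dynamic(self) -> int:
        return int((self.df["klass"] == "dynamic").sum())

    @property
    def n_stable(self) -> int:
        return int((self.df["klass"] == "stable").sum())

    def class_of(self, idx) -> str:
        return self.df.loc[idx, "klass"]


def _size_factors(counts: pd.DataFrame) -> np.ndarray:
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    totals[totals == 0] = 1.0
    return totals / totals.mean()


def _mom_dispersion(y: np.ndarray, s: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments dispersion from within-timepoint normalised counts."""
    num = den = 0.0
    z = y / s
    for g in groups:
        zg = z[g]
        m = zg.mean()
        if m <= 0 or len(zg) < 2:
            continue
        num += max(zg.var(ddof=1) - m, 0.0)
        den += m ** 2
    return num / den if den > 0 else 0.0


def classify_dynamic(table: InteractionTable, distance_cut: float = 150_000,
                     fdr: float = 0.05, min_lfc: float = 1.0,
                     bait_filter: set[int] | None = None,
                     dispersion: float | None = None) -> DynamicCalls:
    """NB likelihood-ratio test of the timepoint factor per interaction.

    ``dispersion`` pins a single NB dispersion for every interaction (used by
    oracle comparisons); by default the moment/shrinkage estimate is used.
    The near regime includes distances == distance_cut; trans interactions
    fall in the far regime.
    """
    tps = table.timepoints
    count_cols = table.count_columns
    if not count_cols:
        raise ValueError("interaction table has no count columns")
    sub = table.df
    if bait_filter is not None:
        sub = sub[sub["bait_frag"].isin(bait_filter)]
    counts = sub[count_cols]
    Y = counts.to_numpy(dtype=float)
    s = _size_factors(table.df[count_cols])
    groups = [np.array([i for i, c in enumerate(count_cols)
                        if f"_ZT{t}_" in c]) for t in tps]
    if min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 replicates per timepoint")

    n = len(sub)
    if dispersion is None:
        phi_i = np.array([_mom_dispersion(Y[i], s, groups) for i in range(n)])
        positive = phi_i[phi_i > 0]
        common = float(stats.trim_mean(phi_i, 0.1)) if n >= 5 else \
            (float(positive.mean()) if len(positive) else 0.0)
        common = max(common, 0.0)
        phis = 0.5 * phi_i + 0.5 * common
    else:
        phis = np.full(n, float(dispersion))

    lrt = np.zeros(n)
    pvals = np.ones(n)
    log2fc = np.zeros(n)
    df_test = len(tps) - 1
    for i in range(n):
        y = Y[i]
        if y.sum() == 0:
            continue  # all-zero: stable, p = 1
        phi = phis[i]
        m0 = fit_nb_mean(y, s, phi)
        ll0 = nb_loglik(y, s * m0, phi)
        ll1 = 0.0
        means_t = []
        for g in groups:
            mt = fit_nb_mean(y[g], s[g], phi)
            means_t.append(mt)
            ll1 += nb_loglik(y[g], s[g] * mt, phi)
        lrt[i] = max(2.0 * (ll1 - ll0), 0.0)
        pvals[i] = stats.chi2.sf(lrt[i], df_test)
        hi, lo = max(means_t), min(means_t)
        log2fc[i] = (np.inf if lo == 0 else np.log2(hi / lo)) if hi > 0 else 0.0

    dist = sub["distance_bp"].to_numpy(dtype=float)
    near = np.isfinite(dist) & (dist <= distance_cut)
    regime = np.where(near, "near", "far")
    qvals = np.ones(n)
    for reg in ("near", "far"):
        m = regime == reg
        if m.any():
            _, q, _, _ = multipletests(pvals[m], method="fdr_bh")
            qvals[m] = q

    klass = np.where((qvals < fdr) & (np.abs(log2fc) >= min_lfc),
                     "dynamic", "stable")
    out = pd.DataFrame({
        "bait_frag": sub["bait_frag"].to_numpy(),
        "other_frag": sub["other_frag"].to_numpy(),
        "regime": regime, "lrt_stat": lrt, "p": pvals, "q": qvals,
        "log2fc": log2fc, "klass": klass,
    }, index=sub.index)
    return DynamicCalls(out, fdr, min_lfc)


# ---------------------------------------------------------------------------
# Contacts per timepoint vs acrophase

@dataclass
class ContactPeakResult:
    per_promoter: pd.DataFrame  # gene_id, acrophase, peak_zt, tie_flag, offset
    chi2: float
    p: float
    n_excluded: int

    def offset_counts(self) -> dict[int, int]:
        ok = self.per_promoter[~self.per_promoter["tie_flag"]]
        return {o: int((ok["offset"] == o).sum()) for o in (0, 6, 12)}


def _circular_offset(a: int, b: int) -> int:
    d = abs(a - b) % 24
    return min(d, 24 - d)


def contacts_per_timepoint(table: InteractionTable, calls: CircadianCalls,
                           gene_baits: dict[str, int],
                           score_threshold: float = 5.0) -> ContactPeakResult:
    """Peak contact timepoint per circadian promoter vs its acrophase.

    contacts(t) = number of interactions significant at t for the gene's bait
    fragment. The cohort chi-square compares the observed {0, 6, 12}-hour
    offset distribution with the expectation under independence of peak time
    and acrophase (product of the two marginals).
    """
    tps = table.timepoints
    sig = {t: table.significant_at(t, score_threshold).to_numpy() for t in tps}
    baits = table.df["bait_frag"].to_numpy()

    rows, excluded = [], 0
    circ = calls.df[calls.df["circadian"]]
    for _, g in circ.iterrows():
        frag = gene_baits.get(g["gene_id"])
        if frag is None:
            continue
        mask = baits == frag
        counts = np.array([int((sig[t] & mask).sum()) for t in tps])
        if counts.sum() == 0:
            excluded += 1
            continue
        best = counts.max()
        winners = [t for t, c in zip(tps, counts) if c == best]
        tie = len(winners) > 1
        peak = winners[0]
        rows.append({"gene_id": g["gene_id"], "acrophase": int(g["phase"]),
                     "peak_zt": peak, "tie_flag": tie,
                     "offset": _circular_offset(peak, int(g["phase"])),
                     **{f"contacts_ZT{t}": c for t, c in zip(tps, counts)}})
    per = pd.DataFrame(rows)

    chi2 = p = np.nan
    if len(per):
        ok = per[~per["tie_flag"]]
        if len(ok) >= 3:
            peak_marg = ok["peak_zt"].value_counts(normalize=True)
            acro_marg = ok["acrophase"].value_counts(normalize=True)
            exp = {0: 0.0, 6: 0.0, 12: 0.0}
            for pk, ppk in peak_marg.items():
                for ac, pac in acro_marg.items():
                    exp[_circular_offset(int(pk), int(ac))] += ppk * pac
            n = len(ok)
            obs = np.array([(ok["offset"] == o).sum() for o in (0, 6, 12)], float)
            expected = np.array([exp[o] * n for o in (0, 6, 12)])
            keep = expected > 0
            chi2, p = stats.chisquare(obs[keep], expected[keep] *
                                      obs[keep].sum() / expected[keep].sum())
    return ContactPeakResult(per, float(chi2), float(p), excluded)


# ---------------------------------------------------------------------------
# Matched-permutation feature enrichment

@dataclass
class EnrichmentResult:
    feature_set: str
    observed: int
    expected: np.ndarray
    ratio: float
    t_p: float
    n_iter: int
    n_skipped: int = 0
    degenerate: bool = False

    @property
    def expected_mean(self) -> float:
        return float(self.expected.mean())

    @property
    def expected_sd(self) -> float:
        return float(self.expected.std(ddof=1)) if len(self.expected) > 1 else 0.0

    @property
    def z(self) -> float:
        sd = self.expected_sd
        return (self.observed - self.expected_mean) / sd if sd > 0 else np.nan


class _FeatureIndex:
    """Merged-interval overlap index per chromosome."""

    def __init__(self, features: FeatureSet):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for f in features:
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        self.starts, self.ends = {}, {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self.starts[chrom] = np.array([s for s, _ in merged])
            self.ends[chrom] = np.array([e for _, e in merged])

    def overlaps(self, chrom: str, start, end) -> np.ndarray:
        """Vectorised: does [start_i, end_i) overlap any feature on chrom?"""
        start = np.atleast_1d(start)
        end = np.atleast_1d(end)
        if chrom not in self.starts:
            return np.zeros(len(start), dtype=bool)
        ends = self.ends[chrom]
        starts = self.starts[chrom]
        idx = np.searchsorted(ends, start, side="right")
        ok = idx < len(starts)
        res = np.zeros(len(start), dtype=bool)
        res[ok] = starts[idx[ok]] < end[ok]
        return res


def matched_null_enrichment(table: InteractionTable, features: FeatureSet,
                            baits: set[int], fragmap: RestrictionMap,
                            n_iter: int = 100, seed: int | None = None,
                            max_attempts: int = 100,
                            capture_placements: list | None = None) -> EnrichmentResult:
    """Feature overlap of other-ends vs a length- and distance-matched null.

    Observed counts unique other-end fragments overlapping >= 1 feature. Each
    null iteration re-places every observed (length L, bait distance D) pair
    as an interval of length L at signed distance +/-D from a uniformly drawn
    bait, redrawing out-of-bounds placements (after ``max_attempts`` the pair
    is skipped for that iteration).

    When ``capture_placements`` is a list, every iteration appends a DataFrame
    of the placements actually used (length, distance, bait midpoint,
    interval), so the preservation of the empirical (length, distance) joint
    distribution is externally checkable.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    idx = _FeatureIndex(features)
    genome = fragmap.genome
    bait_list = np.array(sorted(baits))
    bait_mid = np.array([fragmap.midpoint(int(b)) for b in bait_list])
    bait_chrom = np.array([fragmap.chrom_of(int(b)) for b in bait_list])
    chrom_len = {c: genome.length(c) for c in genome.names}

    # unique cis other-ends with their (length, distance)
    cis = table.df[np.isfinite(table.df["distance_bp"])]
    uniq = cis.drop_duplicates(subset="other_frag")
    Ls, Ds, obs_flags = [], [], []
    for _, r in uniq.iterrows():
        iv = fragmap.interval(int(r["other_frag"]))
        Ls.append(iv.length)
        Ds.append(float(r["distance_bp"]))
        obs_flags.append(bool(idx.overlaps(iv.chrom, iv.start, iv.end)[0]))
    Ls = np.array(Ls, float)
    Ds = np.array(Ds, float)
    observed = int(np.sum(obs_flags))
    m = len(Ls)
    if len(features) == 0 or m == 0:
        return EnrichmentResult(features.name, observed, np.zeros(n_iter),
                                np.nan, np.nan, n_iter, degenerate=True)

    rng = np.random.default_rng(seed)
    expected = np.zeros(n_iter)
    skipped_total = 0
    chrom_len_arr = np.array([chrom_len[c] for c in bait_chrom])
    for it in range(n_iter):
        placed_chrom = np.empty(m, dtype=object)
        placed_start = np.zeros(m)
        placed_end = np.zeros(m)
        placed_baitmid = np.zeros(m)
        unplaced = np.arange(m)
        attempts = 0
        while len(unplaced) and attempts < max_attempts:
            pick = rng.integers(len(bait_list), size=len(unplaced))
            side = np.where(rng.random(len(unplaced)) < 0.5, 1.0, -1.0)
            mid = bait_mid[pick] + side * Ds[unplaced]
            start = mid - Ls[unplaced] / 2.0
            end = start + Ls[unplaced]
            ok = (start >= 0) & (end <= chrom_len_arr[pick])
            done = unplaced[ok]
            placed_chrom[done] = bait_chrom[pick[ok]]
            placed_start[done] = start[ok]
            placed_end[done] = end[ok]
            placed_baitmid[done] = bait_mid[pick[ok]]
            unplaced = unplaced[~ok]
            attempts += 1
        skipped_total += len(unplaced)
        hits = 0
        placed = np.setdiff1d(np.arange(m), unplaced)
        if capture_placements is not None:
            capture_placements.append(pd.DataFrame({
                "length": Ls[placed], "distance": Ds[placed],
                "chrom": placed_chrom[placed],
                "start": placed_start[placed], "end": placed_end[placed],
                "bait_mid": placed_baitmid[placed],
            }))
        for chrom in set(placed_chrom[placed]):
            sel = placed[placed_chrom[placed] == chrom]
            hits += int(idx.overlaps(chrom, placed_start[sel],
                                     placed_end[sel]).sum())
        expected[it] = hits

    t_p = float(stats.ttest_1samp(expected, observed).pvalue) \
        if expected.std(ddof=1) > 0 else (1.0 if expected.mean() == observed else 0.0)
    mean = expected.mean()
    ratio = observed / mean if mean > 0 else np.nan
    return EnrichmentResult(features.name, observed, expected, float(ratio),
                            t_p, n_iter, skipped_total)


def erna_contact_enrichment(table: InteractionTable, osc: FeatureSet,
                            nonosc: FeatureSet, circadian_baits: set[int],
                            fragmap: RestrictionMap, n_iter: int = 100,
                            seed: int | None = None) -> EnrichmentResult:
    """Contacts between circadian baits and oscillatory enhancers vs
    equal-size draws from the non-oscillatory enhancer set."""
    if len(nonosc) < len(osc):
        raise ValueError("need at least as many non-oscillatory as oscillatory features")
    df = table.df[table.df["bait_frag"].isin(circadian_baits)]

    uniq = df["other_frag"].value_counts()
    o_frags = uniq.index.to_numpy()
    o_counts = uniq.to_numpy(dtype=float)
    o_chrom = np.array([fragmap.chrom_of(int(f)) for f in o_frags])
    o_start = np.array([fragmap.interval(int(f)).start for f in o_frags])
    o_end = np.array([fragmap.interval(int(f)).end for f in o_frags])

    def count_contacts(feats: list) -> int:
        fidx = _FeatureIndex(FeatureSet("tmp", list(feats)))
        hits = 0.0
        for chrom in set(o_chrom):
            sel = o_chrom == chrom
            ov = fidx.overlaps(chrom, o_start[sel], o_end[sel])
            hits += o_counts[sel][ov].sum()
        return int(hits)

    observed = count_contacts(osc.features)
    if len(circadian_baits) == 0 or len(df) == 0:
        return EnrichmentResult(osc.name, observed, np.zeros(n_iter),
                                np.nan, np.nan, n_iter, degenerate=True)
    rng = np.random.default_rng(seed)
    pool = list(nonosc.features)
    expected = np.zeros(n_iter)
    for it in range(n_iter):
        draw = rng.choice(len(pool), size=len(osc), replace=False)
        expected[it] = count_contacts([pool[i] for i in draw])
    t_p = float(stats.ttest_1samp(expected, observed).pvalue) \
        if expected.std(ddof=1) > 0 else (1.0 if expected.mean() == observed else 0.0)
    mean = expected.mean()
    ratio = observed / mean if mean > 0 else np.nan
    return EnrichmentResult(osc.name, observed, expected, float(ratio), t_p, n_iter)


# ---------------------------------------------------------------------------
# Phase coherence

@dataclass
class PhaseCoherenceResult:
    distributions: dict[str, np.ndarray]   # per anchor group, binned counts
    phases: dict[str, np.ndarray]          # raw contacted phases (hours)
    bin_labels: list[str]
    wilcoxon_p: float
    degenerate: bool = False


def _phase_bin(hour: float, binning: str) -> int:
    if binning == "hr8x3":
        return int(hour // 3) % 8
    return {0: 0, 6: 1, 12: 2, 18: 3}[int(hour)]


def phase_coherence(table: InteractionTable, anchors: CircadianCalls,
                    gene_baits: dict[str, int],
                    target_phases: dict[int, float],
                    target_binning: str = "zt4",
                    score_threshold: float = 5.0) -> PhaseCoherenceResult:
    """Contacted-phase distributions for diurnal vs nocturnal anchor promoters.

    ``target_phases`` maps target fragment id -> phase (ZT hours for
    promoters, hours for eRNAs). hr8x3 bins hour h into floor(h/3); zt4 uses
    the four sampled ZTs. The rank-sum test compares contacted phases (hours)
    between the two anchor groups.
    """
    n_bins = 8 if target_binning == "hr8x3" else 4
    labels = ([f"{3 * b}-{3 * b + 3}h" for b in range(8)]
              if target_binning == "hr8x3" else [f"ZT{t}" for t in (0, 6, 12, 18)])
    sig_any = table.significant_any(score_threshold).to_numpy()
    baits = table.df["bait_frag"].to_numpy()
    others = table.df["other_frag"].to_numpy()

    circ = anchors.df[anchors.df["circadian"]]
    groups = {"diurnal": [], "nocturnal": []}
    for _, g in circ.iterrows():
        frag = gene_baits.get(g["gene_id"])
        if frag is None:
            continue
        group = "diurnal" if int(g["phase"]) in DIURNAL_ZTS else "nocturnal"
        mask = (baits == frag) & sig_any
        for other in others[mask]:
            ph = target_phases.get(int(other))
            if ph is not None:
                groups[group].append(float(ph))

    dists, phases = {}, {}
    for name, vals in groups.items():
        arr = np.array(vals)
        counts = np.zeros(n_bins, dtype=int)
        for v in arr:
            counts[_phase_bin(v, target_binning)] += 1
        dists[name] = counts
        phases[name] = arr
    degenerate = any(len(v) == 0 for v in phases.values())
    if degenerate:
        p = np.nan
    else:
        p = float(stats.ranksums(phases["diurnal"], phases["nocturnal"]).pvalue)
    return PhaseCoherenceResult(dists, phases, labels, p, degenerate)


# ---------------------------------------------------------------------------
# Core clock vs output circadian genes

@dataclass
class CoreClockComparison:
    core_contacts: pd.Series        # per-gene unique significant interactions
    core_dynamic_frac: pd.Series
    null_contacts: np.ndarray       # pooled over iterations
    null_dynamic_frac: np.ndarray
    p_contacts: float
    p_dynamic: float
    n_iter: int


def coreclock_comparison(table: InteractionTable, calls: CircadianCalls,
                         gene_baits: dict[str, int],
                         dynamic_calls: DynamicCalls,
                         core_list=CORE_CLOCK_GENES,
                         n_iter: int = 100, seed: int | None = None,
                         resample_size: int | None = None,
                         score_threshold: float = 5.0) -> CoreClockComparison:
    """Contact counts and dynamic fractions: core clock vs resampled circadian genes."""
    circadian = set(calls.circadian_genes)
    core = [g for g in core_list if g in circadian and g in gene_baits]
    if not core:
        raise ValueError("no core-clock genes present in the data")
    pool = sorted((circadian - set(core)) & set(gene_baits))
    k = resample_size or len(core)

    sig_any = table.significant_any(score_threshold).to_numpy()
    baits = table.df["bait_frag"].to_numpy()
    dyn = dynamic_calls.df

    def metrics(gene: str) -> tuple[int, float]:
        frag = gene_baits[gene]
        mask = (baits == frag) & sig_any
        n_contacts = len(set(table.df.loc[mask, "other_frag"]))
        sub = dyn[dyn["bait_frag"] == frag]
        frac = float((sub["klass"] == "dynamic").mean()) if len(sub) else np.nan
        return n_contacts, frac

    core_vals = {g: metrics(g) for g in core}
    core_contacts = pd.Series({g: v[0] for g, v in core_vals.items()})
    core_frac = pd.Series({g: v[1] for g, v in core_vals.items()}).dropna()

    rng = np.random.default_rng(seed)
    null_c, null_f = [], []
    for _ in range(n_iter):
        draw = rng.choice(pool, size=min(k, len(pool)), replace=False)
        for g in draw:
            c, f = metrics(g)
            null_c.append(c)
            if not np.isnan(f):
                null_f.append(f)
    null_c = np.array(null_c, float)
    null_f = np.array(null_f, float)

    def mw(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if len(a) == 0 or len(b) == 0:
            return np.nan
        if np.array_equal(np.sort(np.unique(a)), np.sort(np.unique(b))) and \
                len(np.unique(np.concatenate([a, b]))) == 1:
            return 1.0
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    return CoreClockComparison(core_contacts, core_frac, null_c, null_f,
                               mw(core_contacts, null_c), mw(core_frac, null_f),
                               n_iter)
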