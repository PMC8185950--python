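"""Circadian TADs: gene assignment, phase sharing, and OCC-overlap enrichment.

A circadian TAD (cTAD) contains at least one circadian gene (gene-in-TAD by
TSS, half-open interval semantics). For TADs holding exactly k circadian
genes, the chance that all k share an acrophase under independent assignment
is sum_i p_i^k, with p the acrophase frequencies over the circadian-gene
universe; observed vs expected (same, not-same) counts are compared by a
1-df chi-square. cTAD enrichment over oscillatory compartments is scored
against resampled equal-size sets of non-cTADs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .domains import TAD

__all__ = ["CTADRecord", "PhaseSharingResult", "OCCOverlapResult",
           "assign_genes_to_tads", "make_ctads", "phase_sharing",
           "expected_same_phase", "occ_overlap_test"]


@dataclass
class CTADRecord:
    tad: TAD
    genes: list[str]
    circadian_genes: list[str]
    phases: list[int]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_circadian(self) -> int:
        return len(self.circadian_genes)

    @property
    def all_same_phase(self) -> bool:
        return len(set(self.phases)) == 1


@dataclass
class PhaseSharingResult:
    k: int
    n_tads: int
    observed_same: int
    observed_prop: float
    expected_prop: float
    chi2: float
    p: float
    low_count: bool = False


@dataclass
class OCCOverlapResult:
    observed: int
    null_draws: np.ndarray
    z: float
    empirical_p: float
    degenerate: bool = False
    wilcoxon_p: float | None = None


def assign_genes_to_tads(genes: pd.DataFrame, tads: list[TAD]):
    """Per-TAD gene lists; a gene belongs to a TAD iff its TSS is in [start, end).

    ``genes`` columns: gene_id, chrom, tss, and optionally circadian, phase.
    Returns (assignments, unassigned_gene_ids); ``TAD.n_genes`` is filled in.
    """
    has_circ = "circadian" in genes.columns
    assignments = []
    assigned: set[str] = set()
    for tad in tads:
        iv = tad.interval
        sub = genes[(genes["chrom"] == iv.chrom)
                    & (genes["tss"] >= iv.start) & (genes["tss"] < iv.end)]
        gene_ids = list(sub["gene_id"])
        assigned.update(gene_ids)
        if has_circ:
            circ = sub[sub["circadian"].astype(bool)]
            circ_ids = list(circ["gene_id"])
            phases = [int(p) for p in circ["phase"]]
        else:
            circ_ids, phases = [], []
        tad.n_genes = len(gene_ids)
        assignments.append(CTADRecord(tad, gene_ids, circ_ids, phases))
    unassigned = [g for g in genes["gene_id"] if g not in assigned]
    return assignments, unassigned


def make_ctads(assignments: list[CTADRecord]):
    """Split assignments into cTADs (>= 1 circadian gene) and non-cTADs."""
    ctads = [a for a in assignments if a.n_circadian >= 1]
    non_ctads = [a for a in assignments if a.n_circadian == 0]
    return ctads, non_ctads


def expected_same_phase(phase_freqs, k: int) -> float:
    """P(all k genes share one acrophase) = sum_i p_i^k under independence."""
    p = np.asarray(list(phase_freqs.values())
                   if isinstance(phase_freqs, dict) else phase_freqs, float)
    if abs(p.sum() - 1) > 1e-9:
        raise ValueError("phase frequencies must sum to 1")
    return float(np.sum(p ** k))


def phase_sharing(ctads: list[CTADRecord], phase_freqs,
                  min_expected: float = 5.0) -> list[PhaseSharingResult]:
    """Observed vs expected all-same-phase proportions per circadian-gene count k."""
    results = []
    ks = sorted({c.n_circadian for c in ctads if c.n_circadian >= 2})
    for k in ks:
        group = [c for c in ctads if c.n_circadian == k]
        n = len(group)
        obs_same = sum(c.all_same_phase for c in group)
        exp_prop = expected_same_phase(phase_freqs, k)
        exp_counts = np.array([n * exp_prop, n * (1 - exp_prop)])
        obs_counts = np.array([obs_same, n - obs_same])
        low = bool((exp_counts < min_expected).any())
        if exp_counts.min() > 0:
            chi2, p = stats.chisquare(obs_counts, exp_counts)
        else:
            chi2, p = np.nan, np.nan
        results.append(PhaseSharingResult(k, n, obs_same, obs_same / n,
                                          exp_prop, float(chi2), float(p), low))
    return results


def _overlaps_any(tad: TAD, occs) -> bool:
    iv = tad.interval
    for occ in occs:
        o = occ.interval if hasattr(occ, "interval") else occ
        if iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end:
            return True
    return False


def occ_overlap_test(ctads, non_ctads, occs, n_iter: int = 1000,
                     seed: int | None = None) -> OCCOverlapResult:
    """cTAD-over-OCC enrichment vs equal-size resamples of non-cTADs.

    One-sided empirical p = (1 + #{null >= observed}) / (n_iter + 1); a
    per-chromosome paired Wilcoxon between observed and mean-null overlap
    counts is attached when computable.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ctad_tads = [c.tad if isinstance(c, CTADRecord) else c for c in ctads]
    pool = [c.tad if isinstance(c, CTADRecord) else c for c in non_ctads]
    if len(pool) < len(ctad_tads):
        raise ValueError("need at least as many non-cTADs as cTADs")

    obs_flags = np.array([_overlaps_any(t, occs) for t in ctad_tads])
    observed = int(obs_flags.sum())
    pool_flags = np.array([_overlaps_any(t, occs) for t in pool])

    rng = np.random.default_rng(seed)
    null = np.array([
        pool_flags[rng.choice(len(pool), size=len(ctad_tads), replace=False)].sum()
        for _ in range(n_iter)
    ])
    sd = null.std(ddof=1) if n_iter > 1 else 0.0
    degenerate = observed == 0 and not null.any()
    z = (observed - null.mean()) / sd if sd > 0 else np.nan
    emp_p = (1 + int((null >= observed).sum())) / (n_iter + 1)

    wilcox_p = None
    chroms = sorted({t.interval.chrom for t in ctad_tads})
    if len(chroms) >= 2 and not degenerate:
        obs_per = [sum(f for t, f in zip(ctad_tads, obs_flags)
                       if t.interval.chrom == c) for c in chroms]
        exp_per = []
        for c in chroms:
            flags_c = [f for t, f in zip(pool, pool_flags) if t.interval.chrom == c]
            n_c = sum(1 for t in ctad_tads if t.interval.chrom == c)
            exp_per.append(np.mean(flags_c) * n_c if flags_c else 0.0)
        diff = np.array(obs_per, float) - np.array(exp_per, float)
        if np.any(diff != 0):
            wilcox_p = float(stats.wilcoxon(diff).pvalue)

    return OCCOverlapResult(observed, null, float(z), float(emp_p),
                            degenerate, wilcox_p)
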