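"""Circadian classification of gene expression sampled at four Zeitgeber times.

A gene is called circadian when its expression differs between at least one
pair of timepoints: a per-gene one-way ANOVA on log2(FPKM+1) across the four
ZTs, Benjamini-Hochberg corrected across genes, thresholded at q < 0.01 by
default. Each circadian gene is assigned an acrophase — the sampled ZT with
the highest mean FPKM — and a diel class (diurnal for ZT0/ZT6 acrophases,
nocturnal for ZT12/ZT18).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import ZT_TIMEPOINTS

__all__ = ["ExpressionMatrix", "CircadianCalls", "classify_circadian", "assign_phase"]

_FPKM_RE = re.compile(r"^fpkm_ZT(\d+)_R(\d+)$")

DIURNAL_ZTS = frozenset({0, 6})


@dataclass
class ExpressionMatrix:
    """Genes x (timepoint, replicate) FPKM values with TSS metadata.

    DataFrame columns: gene_id, tss_chrom, tss_pos, strand, plus
    ``fpkm_ZT<t>_R<r>`` value columns. FPKM values must be non-negative.
    """

    df: pd.DataFrame

    def __post_init__(self):
        cols = self.fpkm_columns
        if not cols:
            raise ValueError("no fpkm_ZT<t>_R<r> columns found")
        if (self.df[cols] < 0).any().any():
            raise ValueError("negative FPKM")

    @property
    def fpkm_columns(self) -> list[str]:
        return [c for c in self.df.columns if _FPKM_RE.match(c)]

    @property
    def timepoints(self) -> list[int]:
        return sorted({int(_FPKM_RE.match(c).group(1)) for c in self.fpkm_columns})

    def replicate_values(self, timepoint: int) -> pd.DataFrame:
        cols = [c for c in self.fpkm_columns
                if int(_FPKM_RE.match(c).group(1)) == timepoint]
        return self.df[cols]

    def timepoint_means(self) -> pd.DataFrame:
        """Per-gene mean FPKM per timepoint (columns = ZTs)."""
        return pd.DataFrame(
            {t: self.replicate_values(t).mean(axis=1) for t in self.timepoints}
        )

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class CircadianCalls:
    """Per-gene circadian test results and phase assignments.

    Columns: gene_id, p, q, circadian, phase, diel, tie_flag.
    """

    df: pd.DataFrame
    q_threshold: float = 0.01

    @property
    def circadian_genes(self) -> list[str]:
        return list(self.df.loc[self.df["circadian"], "gene_id"])

    def phase_of(self, gene_id: str) -> int:
        row = self.df[self.df["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return int(row["phase"].iloc[0])

    def phase_frequencies(self, circadian_only: bool = True) -> dict[int, float]:
        sub = self.df[self.df["circadian"]] if circadian_only else self.df
        counts = sub["phase"].value_counts()
        total = counts.sum()
        return {int(t): counts.get(t, 0) / total for t in ZT_TIMEPOINTS}


def assign_phase(means: np.ndarray, timepoints=ZT_TIMEPOINTS) -> tuple[int, bool]:
    """Acrophase = timepoint of highest mean; ties take the smallest ZT.

    Returns (phase, tie_flag).
    """
    means = np.asarray(means, dtype=float)
    best = float(means.max())
    winners = [t for t, m in zip(timepoints, means) if m == best]
    return winners[0], len(winners) > 1


def classify_circadian(expr: ExpressionMatrix, q_threshold: float = 0.01) -> CircadianCalls:
    """One-way ANOVA per gene on log2(FPKM+1) across timepoints, BH across genes."""
    tps = expr.timepoints
    groups_by_t = {t: np.log2(expr.replicate_values(t).to_numpy() + 1.0) for t in tps}
    if min(g.shape[1] for g in groups_by_t.values()) < 2:
        raise ValueError("need >= 2 replicates per timepoint")

    n_genes = len(expr.df)
    pvals = np.ones(n_genes)
    for i in range(n_genes):
        samples = [groups_by_t[t][i] for t in tps]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            pvals[i] = 1.0  # zero variance everywhere: never circadian
            continue
        _, p = stats.f_oneway(*samples)
        pvals[i] = 1.0 if np.isnan(p) else p

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    means = expr.timepoint_means().to_numpy()
    phases, ties = zip(*(assign_phase(m, tps) for m in means))

    out = pd.DataFrame({
        "gene_id": expr.df["gene_id"].to_numpy(),
        "p": pvals,
        "q": qvals,
        "circadian": qvals < q_threshold,
        "phase": phases,
        "tie_flag": ties,
    })
    out["diel"] = np.where(out["phase"].isin(list(DIURNAL_ZTS)), "diurnal", "nocturnal")
    return CircadianCalls(out, q_threshold)
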