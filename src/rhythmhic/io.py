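"""Readers and writers for the plain-text formats the pipeline consumes.

Supported dialects
------------------
* BED3/BED6, with an optional seventh column carrying a circadian phase in
  hours (used for phased enhancer sets).
* bedGraph for binned coverage tracks.
* ibed interaction tables (tab-separated, header
  ``bait_chr bait_start bait_end bait_name otherEnd_chr otherEnd_start
  otherEnd_end otherEnd_name N_reads score``) with optional per-replicate
  count columns ``count_ZT<t>_R<r>`` and per-timepoint score columns
  ``score_ZT<t>``.
* washU longrange arcs: ``chrom start end chrom2:start2-end2,score``.
* COO contact matrices (``bin_i bin_j count``) with a sidecar bins table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    CoverageTrack,
    FeatureSet,
    GenomeDef,
    GenomeError,
    GenomicInterval,
    RestrictionMap,
    ZT_TIMEPOINTS,
)
from .matrix import ContactMatrix

__all__ = [
    "InteractionTable",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_interactions",
    "write_ibed",
    "write_longrange",
    "read_coo_matrix",
    "write_coo_matrix",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BED

def read_bed(path, genome: GenomeDef, name: str | None = None) -> FeatureSet:
    """Read BED3/BED6 (+optional phase_hr 7th column), validated against genome."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                iname = f[3] if len(f) > 3 and f[3] != "." else None
                strand = f[5] if len(f) > 5 else "."
                phase = float(f[6]) if len(f) > 6 and f[6] != "." else None
                iv = GenomicInterval(chrom, start, end, iname, strand, phase)
            except (ValueError, IndexError, GenomeError) as e:
                raise ParseError(f"{path}:{lineno}: malformed BED line ({e})") from e
            iv.validate(genome)
            feats.append(iv)
    return FeatureSet(name or str(path), feats)


def write_bed(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        for f in features:
            cols = [f.chrom, str(f.start), str(f.end)]
            if f.name is not None or f.strand != "." or f.phase_hr is not None:
                cols += [f.name or ".", "0", f.strand]
            if f.phase_hr is not None:
                cols.append(f"{f.phase_hr:g}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: CoverageTrack, path, mode: str = "w") -> None:
    with open(path, mode) as fh:
        for i, v in enumerate(track.values):
            if np.isnan(v):
                continue
            fh.write(
                f"{track.chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:g}\n"
            )


def read_bedgraph(path, genome: GenomeDef, bin_size: int,
                  units: str = "raw") -> dict[str, CoverageTrack]:
    """Read a bedGraph of bin-aligned intervals into per-chromosome tracks."""
    tracks = {
        chrom: np.full(genome.n_bins(chrom, bin_size), np.nan)
        for chrom in genome.names
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
            except (ValueError, IndexError) as e:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from e
            if chrom not in genome:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            for b in range(start // bin_size, min((end - 1) // bin_size + 1,
                                                  len(tracks[chrom]))):
                tracks[chrom][b] = val
    return {c: CoverageTrack(c, bin_size, v, units) for c, v in tracks.items()}


# ---------------------------------------------------------------------------
# Interaction tables

_COUNT_RE = re.compile(r"^count_ZT(\d+)_R(\d+)$")
_SCORE_RE = re.compile(r"^score_ZT(\d+)$")

IBED_HEADER = [
    "bait_chr", "bait_start", "bait_end", "bait_name",
    "otherEnd_chr", "otherEnd_start", "otherEnd_end", "otherEnd_name",
    "N_reads", "score",
]


@dataclass
class InteractionTable:
    """Bait/other-end records with per-(timepoint, replicate) counts.

    The underlying DataFrame has columns ``bait_frag``, ``other_frag``,
    ``is_bait_bait``, ``distance_bp`` (NaN for trans), ``score`` plus any
    ``score_ZT<t>`` / ``count_ZT<t>_R<r>`` columns present.
    """

    df: pd.DataFrame
    fragmap: RestrictionMap | None = None
    baits: set[int] = field(default_factory=set)

    def __post_init__(self):
        required = {"bait_frag", "other_frag"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        for col in self.count_columns:
            if (self.df[col] < 0).any():
                raise ValueError(f"negative count in column {col}")
        if "is_bait_bait" not in self.df.columns:
            self.df["is_bait_bait"] = self.df["other_frag"].isin(self.baits)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def count_columns(self) -> list[str]:
        return [c for c in self.df.columns if _COUNT_RE.match(c)]

    @property
    def timepoints(self) -> list[int]:
        ts = sorted({int(_COUNT_RE.match(c).group(1)) for c in self.count_columns})
        return ts or list(ZT_TIMEPOINTS)

    @property
    def replicates(self) -> list[int]:
        return sorted({int(_COUNT_RE.match(c).group(2)) for c in self.count_columns})

    def counts_at(self, timepoint: int) -> pd.DataFrame:
        cols = [c for c in self.count_columns
                if int(_COUNT_RE.match(c).group(1)) == timepoint]
        return self.df[cols]

    def score_at(self, timepoint: int) -> pd.Series:
        col = f"score_ZT{timepoint}"
        return self.df[col] if col in self.df.columns else self.df["score"]

    def significant_at(self, timepoint: int, threshold: float = 5.0) -> pd.Series:
        return self.score_at(timepoint) >= threshold

    def significant_any(self, threshold: float = 5.0) -> pd.Series:
        sig = pd.Series(False, index=self.df.index)
        for t in self.timepoints:
            sig |= self.significant_at(t, threshold)
        return sig


def read_interactions(path, dialect: str, fragmap: RestrictionMap,
                      baits: set[int] | None = None) -> InteractionTable:
    """Read an interaction table; fragment IDs resolved via the fragment map."""
    if dialect == "ibed":
        df = _read_ibed(path, fragmap)
    elif dialect == "longrange":
        df = _read_longrange(path, fragmap)
    elif dialect == "tsv_counts":
        df = pd.read_csv(path, sep="\t")
        if "score" not in df.columns:
            df["score"] = 0.0
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    baits = set(baits) if baits is not None else set(df["bait_frag"])
    df["is_bait_bait"] = df["other_frag"].isin(baits)
    if "distance_bp" not in df.columns:
        df["distance_bp"] = [
            np.nan if (d := fragmap.distance(b, o)) is None else float(d)
            for b, o in zip(df["bait_frag"], df["other_frag"])
        ]
    return InteractionTable(df.reset_index(drop=True), fragmap, baits)


def _read_ibed(path, fragmap: RestrictionMap) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    if raw.empty:
        return pd.DataFrame(columns=["bait_frag", "other_frag", "distance_bp",
                                     "score", "bait_name", "other_name"])
    for col in IBED_HEADER[:3]:
        if col not in raw.columns:
            raise ParseError(f"{path}: missing ibed column {col!r}")
    out = pd.DataFrame()
    out["bait_frag"] = [
        fragmap.resolve(c, s, e)
        for c, s, e in zip(raw["bait_chr"], raw["bait_start"], raw["bait_end"])
    ]
    out["other_frag"] = [
        fragmap.resolve(c, s, e)
        for c, s, e in zip(raw["otherEnd_chr"], raw["otherEnd_start"],
                           raw["otherEnd_end"])
    ]
    out["bait_name"] = raw.get("bait_name", ".")
    out["other_name"] = raw.get("otherEnd_name", ".")
    out["score"] = raw.get("score", 0.0)
    for col in raw.columns:
        if _COUNT_RE.match(col) or _SCORE_RE.match(col):
            out[col] = raw[col]
    out["distance_bp"] = [
        np.nan if (d := fragmap.distance(b, o)) is None else float(d)
        for b, o in zip(out["bait_frag"], out["other_frag"])
    ]
    return out


def _read_longrange(path, fragmap: RestrictionMap) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip()
            if not line:
                continue
            f = line.split("\t")
            try:
                chrom1, s1, e1 = f[0], int(f[1]), int(f[2])
                target, score = f[3].rsplit(",", 1)
                chrom2, rng = target.split(":")
                s2, e2 = (int(x) for x in rng.split("-"))
                rows.append((fragmap.resolve(chrom1, s1, e1),
                             fragmap.resolve(chrom2, s2, e2), float(score)))
            except (ValueError, IndexError) as e:
                raise ParseError(f"{path}:{lineno}: malformed longrange line") from e
    return pd.DataFrame(rows, columns=["bait_frag", "other_frag", "score"])


def write_ibed(table: InteractionTable, path) -> None:
    fm = table.fragmap
    if fm is None:
        raise ValueError("fragment map required to write ibed")
    extra = [c for c in table.df.columns
             if _COUNT_RE.match(c) or _SCORE_RE.match(c)]
    with open(path, "w") as fh:
        fh.write("\t".join(IBED_HEADER + extra) + "\n")
        for _, r in table.df.iterrows():
            b, o = fm.interval(int(r["bait_frag"])), fm.interval(int(r["other_frag"]))
            n_reads = int(sum(r[c] for c in table.count_columns)) if table.count_columns else 0
            cols = [b.chrom, b.start, b.end, r.get("bait_name", "."),
                    o.chrom, o.start, o.end, r.get("other_name", "."),
                    n_reads, r.get("score", 0.0)]
            cols += [r[c] for c in extra]
            fh.write("\t".join(str(c) for c in cols) + "\n")


def write_longrange(records: pd.DataFrame, fragmap: RestrictionMap, path) -> None:
    """Write (bait_frag, other_frag, score) records as washU longrange arcs."""
    with open(path, "w") as fh:
        for _, r in records.iterrows():
            b = fragmap.interval(int(r["bait_frag"]))
            o = fragmap.interval(int(r["other_frag"]))
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t"
                     f"{o.chrom}:{o.start}-{o.end},{r['score']:g}\n")


# ---------------------------------------------------------------------------
# COO matrices

def write_coo_matrix(matrix: ContactMatrix, path, bins_path) -> None:
    n = matrix.n_bins
    iu = np.triu_indices(n)
    with open(path, "w") as fh:
        fh.write("bin_i\tbin_j\tcount\n")
        for i, j in zip(*iu):
            c = matrix.counts[i, j]
            if c != 0:
                fh.write(f"{i}\t{j}\t{c:g}\n")
    with open(bins_path, "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for i in range(n):
            fh.write(f"{matrix.chrom}\t{i * matrix.bin_size}"
                     f"\t{(i + 1) * matrix.bin_size}\n")


def read_coo_matrix(path, bins_path, timepoint: int | None = None,
                    replicate: str | None = None) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t")
    n = len(bins)
    chrom = bins["chrom"].iloc[0]
    bin_size = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    coo = pd.read_csv(path, sep="\t")
    M = np.zeros((n, n))
    for i, j, c in zip(coo["bin_i"], coo["bin_j"], coo["count"]):
        M[i, j] = c
        M[j, i] = c
    return ContactMatrix(chrom, bin_size, M, timepoint, replicate)
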