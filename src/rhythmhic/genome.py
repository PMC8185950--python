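"""Genome coordinate frame, intervals, restriction fragments and coverage tracks.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
1-based coordinates appear only at display boundaries (e.g. washU region
strings), never internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomeDef",
    "GenomicInterval",
    "RestrictionMap",
    "FeatureSet",
    "CoverageTrack",
    "ZT_TIMEPOINTS",
]

#: The four sampled Zeitgeber times (hours after lights-on).
ZT_TIMEPOINTS = (0, 6, 12, 18)


class GenomeError(ValueError):
    """Raised on coordinate-frame violations."""


@dataclass(frozen=True)
class GenomeDef:
    """An ordered set of chromosomes with lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise GenomeError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeDef":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally named/stranded/phased.

    ``phase_hr`` carries a circadian phase in hours within [0, 24) for phased
    features (e.g. enhancers with oscillatory eRNA production).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."
    phase_hr: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeError(f"invalid strand {self.strand!r}")
        if self.phase_hr is not None and not (0 <= self.phase_hr < 24):
            raise GenomeError(f"phase_hr {self.phase_hr} outside [0, 24)")

    def validate(self, genome: GenomeDef) -> "GenomicInterval":
        if self.chrom not in genome:
            raise GenomeError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise GenomeError(
                f"interval {self.chrom}:{self.start}-{self.end} beyond "
                f"chromosome end {genome.length(self.chrom)}"
            )
        return self

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class FeatureSet:
    """A named list of genomic intervals (order preserved)."""

    name: str
    features: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.features)

    def validate(self, genome: GenomeDef) -> "FeatureSet":
        for f in self.features:
            f.validate(genome)
        return self


class RestrictionMap:
    """Restriction fragments tiling each chromosome, with stable integer IDs.

    Fragments are non-overlapping, contiguous and tile ``[0, length)``;
    IDs increase strictly in genomic order across chromosomes in genome order.
    """

    def __init__(self, genome: GenomeDef, boundaries: dict[str, np.ndarray]):
        self.genome = genome
        self._bounds: dict[str, np.ndarray] = {}
        self._first_id: dict[str, int] = {}
        next_id = 0
        for chrom in genome.names:
            b = np.asarray(boundaries[chrom], dtype=np.int64)
            if b[0] != 0 or b[-1] != genome.length(chrom):
                raise GenomeError(f"fragments do not tile chromosome {chrom}")
            if np.any(np.diff(b) <= 0):
                raise GenomeError(f"fragment boundaries not increasing on {chrom}")
            self._bounds[chrom] = b
            self._first_id[chrom] = next_id
            next_id += len(b) - 1
        self.n_fragments = next_id

    @classmethod
    def tile(cls, genome: GenomeDef, fragment_size: int) -> "RestrictionMap":
        """Uniform tiling with fragments of ``fragment_size`` bp (last one shorter)."""
        bounds = {}
        for chrom in genome.names:
            length = genome.length(chrom)
            b = np.arange(0, length, fragment_size, dtype=np.int64)
            bounds[chrom] = np.append(b, length)
        return cls(genome, bounds)

    @classmethod
    def from_random_sizes(
        cls, genome: GenomeDef, mean_size: int, rng: np.random.Generator
    ) -> "RestrictionMap":
        """Fragments with sizes uniform in [mean/2, 3*mean/2], tiling each chromosome."""
        bounds = {}
        for chrom in genome.names:
            length = genome.length(chrom)
            n_guess = int(length / mean_size * 2) + 4
            sizes = rng.integers(mean_size // 2, mean_size * 3 // 2 + 1, size=n_guess)
            cum = np.cumsum(sizes)
            cum = cum[cum < length]
            bounds[chrom] = np.concatenate([[0], cum, [length]])
        return cls(genome, bounds)

    def chrom_of(self, frag_id: int) -> str:
        for chrom in reversed(self.genome.names):
            if frag_id >= self._first_id[chrom]:
                return chrom
        raise GenomeError(f"fragment id {frag_id} out of range")

    def interval(self, frag_id: int) -> GenomicInterval:
        if not (0 <= frag_id < self.n_fragments):
            raise GenomeError(f"fragment id {frag_id} out of range")
        chrom = self.chrom_of(frag_id)
        i = frag_id - self._first_id[chrom]
        b = self._bounds[chrom]
        return GenomicInterval(chrom, int(b[i]), int(b[i + 1]))

    def midpoint(self, frag_id: int) -> int:
        return self.interval(frag_id).midpoint

    def fragment_at(self, chrom: str, pos: int) -> int:
        """ID of the fragment containing position ``pos`` on ``chrom``."""
        if chrom not in self._bounds:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        b = self._bounds[chrom]
        if not (0 <= pos < b[-1]):
            raise GenomeError(f"position {chrom}:{pos} outside chromosome")
        i = int(np.searchsorted(b, pos, side="right")) - 1
        return self._first_id[chrom] + i

    def resolve(self, chrom: str, start: int, end: int) -> int:
        """ID of the fragment matching interval coordinates (midpoint lookup)."""
        return self.fragment_at(chrom, (start + end) // 2)

    def fragments_on(self, chrom: str) -> range:
        first = self._first_id[chrom]
        return range(first, first + len(self._bounds[chrom]) - 1)

    def distance(self, frag_a: int, frag_b: int) -> int | None:
        """Midpoint-to-midpoint distance for cis pairs; None for trans."""
        if self.chrom_of(frag_a) != self.chrom_of(frag_b):
            return None
        return abs(self.midpoint(frag_a) - self.midpoint(frag_b))


@dataclass
class CoverageTrack:
    """Per-bin numeric signal on one chromosome.

    units is one of {"raw", "RPM", "log2RPM"}; NaN marks undefined bins.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    units: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.units not in ("raw", "RPM", "log2RPM"):
            raise ValueError(f"unknown units {self.units!r}")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("signal must be finite where defined")

    def __len__(self) -> int:
        return len(self.values)


def bin_index(pos: int, bin_size: int) -> int:
    """Bin membership of a point feature: floor(pos / bin_size)."""
    return pos // bin_size


def bins_overlapping(start: int, end: int, bin_size: int) -> range:
    """All bins an interval overlaps (half-open interval semantics)."""
    return range(start // bin_size, (end - 1) // bin_size + 1)
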