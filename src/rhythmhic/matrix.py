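"""Binned contact matrices, matrix balancing and observed/expected transforms.

Balancing enforces the equal-row-sum contract by a symmetric diagonal
scaling (iterative correction): ``B = D M D`` with positive per-bin factors
``D`` such that every unmasked row of ``B`` has the same sum. Bins whose raw
row is entirely zero are masked and excluded from the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContactMatrix", "BalancedMatrix", "balance", "oe_transform"]


class BalanceError(RuntimeError):
    """Raised when balancing fails to reach the requested tolerance."""


@dataclass
class ContactMatrix:
    """Symmetric binned cis contact counts for one chromosome at one timepoint."""

    chrom: str
    bin_size: int
    counts: np.ndarray
    timepoint: int | None = None
    replicate: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def merged_with(self, *others: "ContactMatrix") -> "ContactMatrix":
        """Sum counts across replicates (same chrom/bin_size/timepoint)."""
        total = self.counts.copy()
        for o in others:
            if (o.chrom, o.bin_size, o.n_bins) != (self.chrom, self.bin_size, self.n_bins):
                raise ValueError("cannot merge matrices on different grids")
            total += o.counts
        return ContactMatrix(self.chrom, self.bin_size, total,
                             timepoint=self.timepoint, replicate="merged")


@dataclass
class BalancedMatrix:
    """A bias-scaled contact matrix with equal unmasked row sums."""

    source: ContactMatrix
    bias: np.ndarray          # per-bin factor; NaN where masked
    balanced: np.ndarray      # bias-scaled matrix; NaN rows/cols where masked
    mask: np.ndarray = field(default=None)  # True where bin is masked

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.isnan(self.bias)

    @property
    def chrom(self) -> str:
        return self.source.chrom

    @property
    def bin_size(self) -> int:
        return self.source.bin_size

    @property
    def n_bins(self) -> int:
        return self.source.n_bins


def balance(matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 500) -> BalancedMatrix:
    """Diagonal-scale a symmetric matrix to equal row sums.

    Alternating symmetric scaling: at each sweep the biases are multiplied by
    the square root of target/rowsum, which converges for symmetric
    non-negative matrices with support. Row sums of the result equal their
    mean within relative tolerance ``tol``; all-zero rows are masked.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    M = matrix.counts
    n = matrix.n_bins
    rowsum = M.sum(axis=1)
    mask = rowsum == 0
    active = ~mask
    if not active.any():
        raise BalanceError("all bins masked (zero matrix)")

    A = M[np.ix_(active, active)].astype(float)
    b = np.ones(A.shape[0])
    target = 1.0
    residual = np.inf
    for _ in range(max_iter):
        s = (A * b).sum(axis=1) * b
        residual = float(np.max(np.abs(s - target)) / target)
        if residual < tol:
            break
        b *= np.sqrt(target / s)
    else:
        raise BalanceError(
            f"balancing did not converge in {max_iter} iterations "
            f"(achieved residual {residual:.3e} > tol {tol:.1e})"
        )

    bias = np.full(n, np.nan)
    bias[active] = b
    balanced = np.full((n, n), np.nan)
    balanced[np.ix_(active, active)] = A * b[:, None] * b[None, :]
    return BalancedMatrix(matrix, bias, balanced)


def oe_transform(balanced: BalancedMatrix | np.ndarray) -> np.ndarray:
    """Observed/expected transform with a per-diagonal expected model.

    expected(d) is the mean of entries on diagonal offset ``d`` over unmasked
    bins; each entry is divided by the expectation at its offset. Diagonals
    whose expected value is zero (or entirely masked) come back NaN.
    """
    B = balanced.balanced if isinstance(balanced, BalancedMatrix) else np.asarray(balanced, float)
    n = B.shape[0]
    if not np.isfinite(B).any():
        raise ValueError("all-masked matrix")
    oe = np.full_like(B, np.nan)
    for d in range(n):
        diag = np.diagonal(B, offset=d)
        finite = np.isfinite(diag)
        if not finite.any():
            continue
        exp_d = diag[finite].mean()
        if exp_d == 0:
            continue
        vals = diag / exp_d
        idx = np.arange(n - d)
        oe[idx, idx + d] = vals
        oe[idx + d, idx] = vals
    return oe
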