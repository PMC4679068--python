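"""Core data containers shared across the package.

The central objects are the observed z-vector, the jackknife pseudo-matrix
``C`` whose row means reproduce it, fold partitions of the samples, and the
rank-ordered corrected estimates produced by the resampling estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_ids(ids, m: int) -> tuple[str, ...]:
    if ids is None:
        width = max(4, len(str(m)))
        return tuple(f"f{i + 1:0{width}d}" for i in range(m))
    ids = tuple(str(i) for i in ids)
    if len(ids) != m:
        raise ValueError(f"expected {m} ids, got {len(ids)}")
    if len(set(ids)) != m:
        seen: set[str] = set()
        dups = {i for i in ids if i in seen or seen.add(i)}
        raise ValueError(f"duplicate feature ids: {sorted(dups)}")
    return ids


@dataclass(frozen=True)
class ZVector:
    """A vector of per-feature z-statistics on the Wald scale.

    Parameters
    ----------
    z
        Length-``m`` array of finite z values.
    ids
        Optional unique feature identifiers; synthesized if omitted.
    """

    z: np.ndarray
    ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float).ravel()
        if z.size < 1:
            raise ValueError("z-vector must contain at least one feature")
        if not np.all(np.isfinite(z)):
            raise ValueError("z-vector contains non-finite values")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "ids", _as_ids(self.ids, z.size))

    @property
    def m(self) -> int:
        return self.z.size


@dataclass(frozen=True)
class PseudoMatrix:
    """m x n matrix of jackknife pseudo-values.

    Each element has per-element variance of roughly ``n`` so that row means
    behave like N(mu_i, 1); row means reproduce the z-statistics the matrix
    was built from (exactly so for the one-sample mean statistic).
    """

    values: np.ndarray
    ids: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("pseudo-matrix must be two-dimensional")
        if v.shape[1] < 2:
            raise ValueError("pseudo-matrix needs n >= 2 columns")
        if not np.all(np.isfinite(v)):
            raise ValueError("pseudo-matrix contains non-finite values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", _as_ids(self.ids, v.shape[0]))

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FoldPartition:
    """Assignment of ``n`` sample columns to ``K`` folds of near-equal size."""

    assignments: np.ndarray
    K: int

    def __post_init__(self):
        a = np.asarray(self.assignments, dtype=int).ravel()
        n = a.size
        if not (2 <= self.K <= n):
            raise ValueError(f"need 2 <= K <= n, got K={self.K}, n={n}")
        sizes = np.bincount(a, minlength=self.K)
        if a.min() < 0 or a.max() >= self.K:
            raise ValueError("fold labels must lie in 0..K-1")
        if sizes.min() == 0:
            raise ValueError("every fold must receive at least one column")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes may differ by at most 1")
        object.__setattr__(self, "assignments", a)

    @property
    def n(self) -> int:
        return self.assignments.size

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.K)

    def fold_columns(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)


@dataclass(frozen=True)
class RankedEstimates:
    """Rank-ordered corrected effect estimates.

    ``delta_hat[i]`` estimates delta_(i+1) = E[mu_(i+1)], the expected effect
    attached to the (i+1)-th smallest observed statistic.  ``rank_to_feature``
    maps each rank (ascending, 0-based) to the feature index realized by the
    observed z ordering, so ``delta_hat`` can be re-attached to features.
    """

    delta_hat: np.ndarray
    rank_to_feature: np.ndarray
    K: float
    n_partitions: int
    seed: int | None = None
    ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        d = np.asarray(self.delta_hat, dtype=float).ravel()
        r = np.asarray(self.rank_to_feature, dtype=int).ravel()
        if d.size != r.size:
            raise ValueError("delta_hat and rank_to_feature lengths differ")
        if not np.array_equal(np.sort(r), np.arange(d.size)):
            raise ValueError("rank_to_feature must be a permutation of 0..m-1")
        object.__setattr__(self, "delta_hat", d)
        object.__setattr__(self, "rank_to_feature", r)
        object.__setattr__(self, "ids", _as_ids(self.ids, d.size))

    @property
    def m(self) -> int:
        return self.delta_hat.size

    def per_feature(self) -> np.ndarray:
        """Corrected estimate aligned back to original feature order."""
        out = np.empty(self.m)
        out[self.rank_to_feature] = self.delta_hat
        return out
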