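"""Matrix-based projack: pseudo-matrix construction, the re-ordered
jackknife, and K-fold stabilization over random partitions.

The estimator targets delta_(i) = E[mu_(i)], the expected effect size of the
i-th ranked feature, for a set of m possibly correlated z-statistics.  The
raw data (an m x n feature matrix X, outcome y) are condensed into an m x n
pseudo-matrix C with elements

    c_ij = n * z_i - (n - 1) * sqrt(n / (n - 1)) * z_i[-j],

where z_i[-j] is the statistic recomputed without sample j.  Row means of C
approximate z, each element has variance ~ n, and the column structure lets
a held-out column serve as a ranking-bias-free read-out: ranking on the
remaining columns and reading the held-out value at each rank (the
re-ordered jackknife) is exactly unbiased when all mu_i are equal.
Collapsing columns into K fold-means before re-ordering, averaged over many
random partitions, trades a little bias for much lower variance.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .containers import FoldPartition, PseudoMatrix, RankedEstimates

__all__ = [
    "row_means",
    "build_pseudo_matrix",
    "reordered_jackknife",
    "random_partition",
    "kfold_collapse",
    "projack",
    "STATISTICS",
]


class DegenerateSubsetError(ValueError):
    """A leave-one-out subset had zero variance in x or y.

    Raised instead of silently emitting NaN, because a NaN pseudo-value
    corrupts every downstream ranking.
    """

    def __init__(self, feature: str, sample: int, what: str):
        self.feature = feature
        self.sample = sample
        super().__init__(
            f"zero variance in {what} after removing sample {sample} "
            f"(feature {feature!r}); statistic undefined on this subset"
        )


def row_means(C: PseudoMatrix | np.ndarray) -> np.ndarray:
    """Vector of row means r(C), the working z-statistics of the matrix."""
    v = C.values if isinstance(C, PseudoMatrix) else np.asarray(C, dtype=float)
    if v.size == 0:
        raise ValueError("empty matrix has no row means")
    return v.mean(axis=1)


# ---------------------------------------------------------------------------
# Built-in statistics.  Each entry provides the full-sample z and a
# closed-form leave-one-out z (recomputed from downdated sufficient
# statistics, never by m*n refits).


def _one_sample_full(X: np.ndarray, y: np.ndarray | None) -> np.ndarray:
    n = X.shape[1]
    return np.sqrt(n) * X.mean(axis=1)


def _one_sample_loo(X: np.ndarray, y: np.ndarray | None, ids=None) -> np.ndarray:
    n = X.shape[1]
    S = X.sum(axis=1, keepdims=True)
    return np.sqrt(n - 1) * (S - X) / (n - 1)


def _score_loo_core(X: np.ndarray, y: np.ndarray, ids=None) -> np.ndarray:
    """LOO score z for the slope of y on each row of X: z = sqrt(n) * r."""
    n = X.shape[1]
    Sx = X.sum(axis=1, keepdims=True)
    Sy = y.sum()
    Sxx = (X * X).sum(axis=1, keepdims=True)
    Syy = float(y @ y)
    Sxy = (X * y).sum(axis=1, keepdims=True)

    nn = n - 1
    sx = Sx - X
    sy = Sy - y
    sxx = Sxx - X * X
    syy = Syy - y * y
    sxy = Sxy - X * y

    vx = sxx - sx * sx / nn
    vy = syy - sy * sy / nn
    _check_degenerate(vx, ids, "x")
    if np.any(vy <= 1e-12 * max(1.0, abs(Syy))):
        j = int(np.argmax(vy.ravel() <= 1e-12 * max(1.0, abs(Syy))))
        raise DegenerateSubsetError("(all)", j, "y")
    r = (sxy - sx * sy / nn) / np.sqrt(vx * vy)
    return np.sqrt(nn) * r


def _check_degenerate(vx: np.ndarray, ids, what: str) -> None:
    bad = vx <= 1e-12 * np.maximum(1.0, np.abs(vx).max())
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        name = ids[i] if ids is not None else str(i)
        raise DegenerateSubsetError(name, int(j), what)


def _score_full(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    vx = (xc * xc).sum(axis=1)
    vy = float(yc @ yc)
    if vy <= 0:
        raise ValueError("outcome y is constant; score statistic undefined")
    if np.any(vx <= 0):
        i = int(np.argmax(vx <= 0))
        raise ValueError(f"feature row {i} is constant; score statistic undefined")
    return np.sqrt(n) * (xc @ yc) / np.sqrt(vx * vy)


def _require_binary(y: np.ndarray) -> None:
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))) or vals.size != 2:
        raise ValueError("trend statistic requires a binary 0/1 outcome with both classes")


STATISTICS: dict[str, dict] = {
    # z_i = sqrt(n) * mean(x_i.), known unit SD
    "one_sample_z": {"full": _one_sample_full, "loo": _one_sample_loo, "needs_y": False},
    # score statistic for the slope in simple linear association, z = sqrt(n)*r
    "linear_score_z": {"full": _score_full, "loo": _score_loo_core, "needs_y": True},
    # Cochran-Armitage trend for binary y; identical to the score form because
    # p(1-p) equals the (1/n-scaled) sample variance of a 0/1 outcome
    "trend_z": {"full": _score_full, "loo": _score_loo_core, "needs_y": True, "binary_y": True},
}


def _residualize(M: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Project out an intercept plus covariate rows V (p x n) from each row of M."""
    n = M.shape[-1] if M.ndim > 1 else M.size
    design = np.vstack([np.ones(n), np.atleast_2d(V)]).T  # n x (p+1)
    coef, *_ = np.linalg.lstsq(design, np.atleast_2d(M).T, rcond=None)
    res = np.atleast_2d(M) - (design @ coef).T
    return res if M.ndim > 1 else res.ravel()


def build_pseudo_matrix(
    X: np.ndarray,
    y: np.ndarray | None = None,
    statistic: str | Callable[[np.ndarray, np.ndarray | None], np.ndarray] = "one_sample_z",
    covariates: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
) -> PseudoMatrix:
    """Build the jackknife pseudo-matrix C from raw data.

    Parameters
    ----------
    X
        m x n data matrix (features by samples).
    y
        Length-n outcome, required by ``linear_score_z`` and ``trend_z``.
    statistic
        Name of a built-in statistic, or a callable ``f(X_sub, y_sub) -> z``
        applied to arbitrary column subsets (explicit leave-one-out
        recomputation; slower but fully general).
    covariates
        Optional p x n nuisance covariates.  x-rows and y are residualized
        on them (plus an intercept) once, on the full sample, before the
        statistic is computed.

    Returns
    -------
    PseudoMatrix with ``c_ij = n z_i - (n-1) sqrt(n/(n-1)) z_i[-j]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, n = X.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != n:
            raise ValueError(f"y has length {y.size}, expected {n}")

    if callable(statistic):
        full_fn = statistic
        loo_fn = None
    else:
        try:
            entry = STATISTICS[statistic]
        except KeyError:
            raise ValueError(
                f"unknown statistic {statistic!r}; choose from {sorted(STATISTICS)}"
            ) from None
        if entry["needs_y"] and y is None:
            raise ValueError(f"statistic {statistic!r} requires an outcome y")
        if entry.get("binary_y"):
            _require_binary(y)
        full_fn, loo_fn = entry["full"], entry["loo"]

    if covariates is not None:
        X = _residualize(X, covariates)
        if y is not None:
            y = _residualize(y, covariates)

    ids_t = tuple(ids) if ids is not None else None

    z = np.asarray(full_fn(X, y), dtype=float).ravel()
    if z.size != m:
        raise ValueError("statistic returned wrong number of values")

    if loo_fn is not None:
        z_loo = loo_fn(X, y, ids_t)
    else:
        z_loo = np.empty((m, n))
        cols = np.arange(n)
        for j in range(n):
            keep = cols != j
            zj = np.asarray(full_fn(X[:, keep], y[keep] if y is not None else None), dtype=float)
            if not np.all(np.isfinite(zj)):
                bad = int(np.argmax(~np.isfinite(zj)))
                name = ids_t[bad] if ids_t else str(bad)
                raise DegenerateSubsetError(name, j, "statistic")
            z_loo[:, j] = zj

    C = n * z[:, None] - (n - 1) * np.sqrt(n / (n - 1)) * z_loo
    return PseudoMatrix(values=C, ids=ids_t)


# ---------------------------------------------------------------------------
# Re-ordered jackknife and K-fold stabilization


def _stable_order(values: np.ndarray) -> np.ndarray:
    """Ascending argsort with ties broken by lower original index."""
    return np.argsort(values, axis=0, kind="stable")


def reordered_jackknife(C: PseudoMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Re-order each held-out column by the leave-one-out ranking.

    For every column j, rows are ranked (ascending, stable) by the row means
    of C with column j removed; ``D[i, j]`` is the held-out value of the row
    ranked i.  Because column j never participates in its own ranking, each
    d_ij is free of ranking bias.

    Returns
    -------
    (D, delta_hat) : the re-ordered matrix and its row means.
    """
    v = C.values if isinstance(C, PseudoMatrix) else np.asarray(C, dtype=float)
    m, n = v.shape
    if n < 2:
        raise ValueError("re-ordered jackknife needs at least two columns")
    loo_means = (v.sum(axis=1, keepdims=True) - v) / (n - 1)  # (m, n)
    order = _stable_order(loo_means)
    D = np.take_along_axis(v, order, axis=0)
    return D, D.mean(axis=1)


def random_partition(
    n: int, K: int, seed: int | np.random.Generator | None = None
) -> FoldPartition:
    """Uniformly random K-fold partition with fold sizes differing by <= 1."""
    if not (2 <= K <= n):
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.repeat(np.arange(K), np.diff(np.linspace(0, n, K + 1).astype(int)))
    assignments = labels[rng.permutation(n)]
    return FoldPartition(assignments=assignments, K=K)


def kfold_collapse(C: PseudoMatrix | np.ndarray, partition: FoldPartition) -> np.ndarray:
    """Collapse columns to their K fold means, giving the m x K matrix C†.

    For folds of exactly n/K columns this equals (K/n) * sum over the fold;
    for unequal folds the fold mean is used, which keeps E[c†_ik] = E[c_ij].
    Row means of C† remain approximately N(mu_i, 1).
    """
    v = C.values if isinstance(C, PseudoMatrix) else np.asarray(C, dtype=float)
    if partition.n != v.shape[1]:
        raise ValueError("partition does not cover the matrix columns")
    K = partition.K
    sums = np.zeros((v.shape[0], K))
    np.add.at(sums.T, partition.assignments, v.T)
    return sums / partition.sizes


def projack(
    C: PseudoMatrix | np.ndarray,
    K: int = 5,
    n_partitions: int = 50,
    seed: int | np.random.Generator | None = None,
    ids: Sequence[str] | None = None,
) -> RankedEstimates:
    """Matrix projack: K-fold re-ordered jackknife averaged over partitions.

    For each of ``n_partitions`` random K-fold partitions the matrix is
    collapsed to C†, the re-ordered jackknife applied, and the re-ordered
    row means accumulated; the final delta_hat averages all Π*K held-out
    fold values per rank.

    Defaults K=5 and n_partitions=50 follow the reference simulation
    settings; K in 5-10 balances bias against variance.
    """
    if isinstance(C, PseudoMatrix):
        v, cids = C.values, C.ids
    else:
        v, cids = np.asarray(C, dtype=float), (tuple(ids) if ids is not None else None)
    m, n = v.shape
    if not (2 <= K <= n):
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    acc = np.zeros(m)
    for _ in range(n_partitions):
        part = random_partition(n, K, rng)
        collapsed = kfold_collapse(v, part)
        _, d = reordered_jackknife(collapsed)
        acc += d
    delta_hat = acc / n_partitions

    rank_to_feature = _stable_order(row_means(v))
    return RankedEstimates(
        delta_hat=delta_hat,
        rank_to_feature=rank_to_feature,
        K=K,
        n_partitions=n_partitions,
        seed=seed_val,
        ids=cids,
    )
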