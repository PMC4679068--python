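"""Synthetic-data generation and evaluation harness.

Generates pseudo-matrices and z-vectors under the benchmark mean
configurations (null, sparse, normal-quantile, box), provides a Monte-Carlo
oracle for the true expected ranked effects delta_(i) = E[mu_(i)], runs
scenario studies comparing estimators per rank (bias, MSE), and includes a
scaled-down GWAS-like generator in which effects propagate to correlated
neighbors as mu_i' = r_{i,i'} mu_i, mimicking linkage disequilibrium.

The benchmark conditions are m=100 features, n=50 samples, inter-row
correlation rho in {0, 0.4}, Pi=50 partitions and K in {5, 10}, with 1000
simulation replicates for bias curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .condlike import cond_mle_vector
from .containers import PseudoMatrix, ZVector
from .independent import augment_z, independent_projack
from .resampling import projack, row_means
from .scaling import EffectTable, rescale_estimates, squared_error_vs_replication

__all__ = [
    "ScenarioSpec",
    "TrueDelta",
    "make_mu",
    "simulate_pseudo_matrix",
    "simulate_z",
    "true_delta",
    "run_scenario",
    "amse",
    "simulate_gwas_like",
    "psoriasis_k_sweep",
]

SCENARIOS = ("null", "sparse", "normal_quantile", "box", "custom")


def make_mu(name: str, m: int, mu: Sequence[float] | None = None) -> np.ndarray:
    """Sorted mean vector for a named scenario.

    null: all zero.  sparse: (-6, -3, 0...0, 2) — two strong negative
    outliers, one moderate positive, the rest null.  normal_quantile:
    mu_i = Phi^-1(i/(m+1)).  box: equally spaced on [-2, 2].  custom:
    caller-supplied, sorted ascending.
    """
    if name == "null":
        return np.zeros(m)
    if name == "sparse":
        if m < 3:
            raise ValueError("sparse scenario needs m >= 3")
        out = np.zeros(m)
        out[0], out[1], out[-1] = -6.0, -3.0, 2.0
        return out
    if name == "normal_quantile":
        return norm.ppf(np.arange(1, m + 1) / (m + 1))
    if name == "box":
        return np.linspace(-2.0, 2.0, m)
    if name == "custom":
        if mu is None:
            raise ValueError("custom scenario requires an explicit mu vector")
        out = np.sort(np.asarray(mu, dtype=float))
        if out.size != m:
            raise ValueError("custom mu has wrong length")
        return out
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation configuration: mean vector, sample size, correlation."""

    name: str = "null"
    m: int = 100
    n: int = 50
    rho: float = 0.0
    n_sims: int = 1000
    seed: int = 0
    mu: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        mu = make_mu(self.name, self.m, self.mu)
        if np.any(np.diff(mu) < 0):
            raise ValueError("mu must be sorted ascending")
        object.__setattr__(self, "mu", mu)


@dataclass(frozen=True)
class TrueDelta:
    """Monte-Carlo estimate of delta_(i) = E[mu_(i)] with per-rank SEs."""

    delta: np.ndarray
    n_sims: int
    mc_se: np.ndarray


def simulate_pseudo_matrix(
    mu: np.ndarray,
    n: int,
    rho: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> PseudoMatrix:
    """Idealized pseudo-matrix: columns iid, rows equicorrelated.

    Within each column the m entries are jointly normal with mean mu_i,
    variance n, and common pairwise correlation rho, so row means are
    N(mu_i, 1) with inter-row correlation rho.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float).ravel()
    m = mu.size
    e = rng.standard_normal((m, n))
    if rho > 0:
        w = rng.standard_normal(n)
        e = np.sqrt(rho) * w + np.sqrt(1.0 - rho) * e
    return PseudoMatrix(values=mu[:, None] + np.sqrt(n) * e)


def simulate_z(
    mu: np.ndarray, rho: float = 0.0, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw z ~ N(mu, 1) with common pairwise correlation rho."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float).ravel()
    e = rng.standard_normal(mu.size)
    if rho > 0:
        e = np.sqrt(rho) * rng.standard_normal() + np.sqrt(1.0 - rho) * e
    return mu + e


def true_delta(
    mu: np.ndarray,
    n_sims: int = 10000,
    seed: int | np.random.Generator | None = None,
    rho: float = 0.0,
) -> TrueDelta:
    """Monte-Carlo oracle for the expected ranked effects.

    Draws z ~ N(mu, I) (optionally equicorrelated), sorts ascending, and
    records the mu attached to each rank; the average over draws estimates
    delta_(i).  mc_se is the per-rank standard error of that average.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(mu, dtype=float).ravel()
    m = mu.size
    s1 = np.zeros(m)
    s2 = np.zeros(m)
    done = 0
    batch = max(1, int(5e6 // max(m, 1)))
    while done < n_sims:
        b = min(batch, n_sims - done)
        e = rng.standard_normal((b, m))
        if rho > 0:
            e = np.sqrt(rho) * rng.standard_normal((b, 1)) + np.sqrt(1.0 - rho) * e
        order = np.argsort(mu + e, axis=1, kind="stable")
        ranked_mu = mu[order]
        s1 += ranked_mu.sum(axis=0)
        s2 += (ranked_mu**2).sum(axis=0)
        done += b
    delta = s1 / n_sims
    var = np.maximum(s2 / n_sims - delta**2, 0.0)
    return TrueDelta(delta=delta, n_sims=n_sims, mc_se=np.sqrt(var / n_sims))


METHODS = ("projack", "independent_projack", "cond_mle", "naive")


def run_scenario(
    spec: ScenarioSpec,
    method: str = "projack",
    method_params: Mapping | None = None,
    truth: TrueDelta | None = None,
    truth_sims: int = 20000,
) -> pd.DataFrame:
    """Scenario study: per-rank expectation, bias and MSE of one estimator.

    For each simulated dataset the estimator's rank-ordered estimates are
    recorded alongside the naive order statistics z_(i); the table reports
    their Monte-Carlo means against the true delta_(i) from the
    :func:`true_delta` oracle.

    method_params: K / n_partitions (projack), K / B (independent_projack),
    c (cond_mle).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    params = dict(method_params or {})
    rng = np.random.default_rng(spec.seed)
    mu = spec.mu
    m = spec.m

    if truth is None:
        truth = true_delta(mu, n_sims=truth_sims, seed=rng, rho=spec.rho)

    z_sum = np.zeros(m)
    est_sum = np.zeros(m)
    est_sq = np.zeros(m)
    for _ in range(spec.n_sims):
        if method == "projack":
            C = simulate_pseudo_matrix(mu, spec.n, spec.rho, rng)
            z_obs = row_means(C)
            est = projack(
                C,
                K=int(params.get("K", 5)),
                n_partitions=int(params.get("n_partitions", 50)),
                seed=rng,
            ).delta_hat
        else:
            z_obs = simulate_z(mu, spec.rho, rng)
            order = np.argsort(z_obs, kind="stable")
            if method == "independent_projack":
                est = independent_projack(
                    z_obs,
                    K=float(params.get("K", 5.0)),
                    B=int(params.get("B", 1000)),
                    seed=rng,
                ).delta_hat
            elif method == "cond_mle":
                est = cond_mle_vector(z_obs, float(params.get("c", 1.96)))[order]
            else:  # naive
                est = z_obs[order]
        z_sum += np.sort(z_obs)
        est_sum += est
        est_sq += (est - truth.delta) ** 2

    e_z = z_sum / spec.n_sims
    e_est = est_sum / spec.n_sims
    mse = est_sq / spec.n_sims
    return pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "e_z_naive": e_z,
            "e_delta_hat": e_est,
            "true_delta": truth.delta,
            "bias": e_est - truth.delta,
            "mse": mse,
        }
    )


def amse(delta_hat_by_sim: np.ndarray, true_delta_vec: np.ndarray, T: int) -> float:
    """Average MSE over the T/2 lowest and T/2 highest ranks.

    delta_hat_by_sim: S x m array of rank-ordered estimates, one row per
    simulation; true_delta_vec: length-m truth.
    """
    est = np.atleast_2d(np.asarray(delta_hat_by_sim, dtype=float))
    truth = np.asarray(true_delta_vec, dtype=float).ravel()
    m = truth.size
    if est.shape[1] != m:
        raise ValueError("estimate rows not aligned with truth")
    if T % 2 != 0 or not (0 < T <= m):
        raise ValueError(f"T must be even and in 1..m, got T={T}")
    h = T // 2
    idx = np.r_[0:h, m - h : m]
    err = (est[:, idx] - truth[idx]) ** 2
    return float(err.sum(axis=1).mean() / T)


def simulate_gwas_like(
    m: int,
    n_blocks: int,
    block_rho: float,
    causal_spec: Mapping[int, float],
    seed: int | np.random.Generator | None = None,
    r2_cutoff: float = 0.05,
) -> tuple[ZVector, np.ndarray]:
    """GWAS-like z-vector with block-correlated features and LD proxy effects.

    Features are split into ``n_blocks`` contiguous blocks; within a block
    the correlation decays as r_{i,i'} = block_rho**|i - i'| (AR(1)).  Each
    causal position carries its specified mu; a non-causal neighbor i' in
    the same block inherits mu_i' = r_{i,i'} * mu_i, zeroed when r^2 falls
    at or below ``r2_cutoff``.  z is drawn N(mu, Sigma_block).

    At most one causal SNP per block (proxy effects would otherwise
    overlap ambiguously).
    """
    if not (0.0 <= block_rho < 1.0):
        raise ValueError("block_rho must lie in [0, 1)")
    if m % n_blocks != 0:
        raise ValueError("m must be divisible by n_blocks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    block_size = m // n_blocks
    blocks_used: dict[int, int] = {}
    mu = np.zeros(m)
    for pos, effect in causal_spec.items():
        if not (0 <= pos < m):
            raise ValueError(f"causal position {pos} outside 0..{m - 1}")
        blk = pos // block_size
        if blk in blocks_used:
            raise ValueError(
                f"causal positions {blocks_used[blk]} and {pos} fall in the same "
                f"block {blk}; one causal SNP per block"
            )
        blocks_used[blk] = pos
        lo, hi = blk * block_size, (blk + 1) * block_size
        lags = np.abs(np.arange(lo, hi) - pos)
        r = block_rho**lags
        prox = np.where(r * r > r2_cutoff, r * float(effect), 0.0)
        prox[lags == 0] = float(effect)
        mu[lo:hi] = prox

    # AR(1) draw per block via the standard recursion
    e = rng.standard_normal(m)
    z = np.empty(m)
    innov = np.sqrt(1.0 - block_rho**2)
    for blk in range(n_blocks):
        lo, hi = blk * block_size, (blk + 1) * block_size
        acc = e[lo]
        z[lo] = acc
        for t in range(lo + 1, hi):
            acc = block_rho * acc + innov * e[t]
            z[t] = acc
    return ZVector(z=mu + z), mu


def psoriasis_k_sweep(
    effect_table: EffectTable,
    K_grid: Sequence[float],
    m_total: int = 480000,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Squared beta-error of the independent projack as a function of K.

    The observed top-SNP z values are augmented with artificial null
    quantiles up to the scan size ``m_total``, the independent projack run
    for each K, rank estimates mapped back to the observed SNPs, rescaled
    to the log-OR scale via the Wald-implied SEs, and scored against the
    replication log odds ratios.
    """
    if effect_table.or_repl is None:
        raise ValueError("K sweep needs replication odds ratios")
    K_grid = [float(k) for k in K_grid]
    if any(k <= 1 for k in K_grid):
        raise ValueError("all K values must exceed 1")
    m_top = effect_table.m
    z_obs = ZVector(z=effect_table.z, ids=effect_table.ids)
    z_full = augment_z(z_obs, m_total) if m_total > m_top else z_obs
    se = effect_table.se

    ss = np.random.SeedSequence(seed)
    rows = []
    for K, child in zip(K_grid, ss.spawn(len(K_grid))):
        rng = np.random.default_rng(child)
        est = independent_projack(z_full, K=K, B=B, seed=rng)
        per_feature = est.per_feature()[:m_top]
        beta_hat, _ = rescale_estimates(per_feature, se)
        err = squared_error_vs_replication(beta_hat, effect_table)
        rows.append({"K": K, "squared_beta_error": err})
    return pd.DataFrame(rows)
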