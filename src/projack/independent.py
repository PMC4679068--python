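"""Independent projack: ranking-bias correction from a bare z-vector.

When only z is observed, a hypothetical pseudo-matrix can be emulated by
splitting each z_i into an artificial "training" and "test" part.  Per
repetition:

    gamma_i ~ N(0, 1/(K-1))      (iid)
    z'  = z + gamma              (training copy, ranks the features)
    c   = K z - (K-1) z'         (= z - (K-1) gamma; the test copy)
    d   = c re-ordered by the ascending ranking of z'

The construction makes z'_i and c_i uncorrelated (for unit-variance z),
so reading c at the ranks of z' is free of ranking bias, exactly as a
held-out fold is in the matrix procedure.  Averaging d over many
repetitions gives delta_hat; each repetition corresponds to one random
K-fold split of the matrix projack.  K need not be an integer here — any
K > 1 is valid, with values in 5-10 advisable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .containers import RankedEstimates, ZVector

__all__ = ["IndepConfig", "independent_projack", "augment_z"]


@dataclass(frozen=True)
class IndepConfig:
    """Settings for the independent projack.

    K is the fold-equivalent (any real > 1); B the number of Monte-Carlo
    repetitions (>= 1000 recommended to tame stochastic variation).
    """

    K: float = 5.0
    B: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if not self.K > 1:
            raise ValueError(f"K must exceed 1 (gamma variance 1/(K-1)), got {self.K}")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def independent_projack(
    z: ZVector | np.ndarray,
    config: IndepConfig | None = None,
    *,
    K: float | None = None,
    B: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> RankedEstimates:
    """Estimate the expected ranked effects delta_(.) from z alone.

    Either pass an :class:`IndepConfig` or override ``K``/``B``/``seed``
    directly.  Deterministic given the seed.
    """
    zv = z if isinstance(z, ZVector) else ZVector(z=np.asarray(z, dtype=float))
    if config is None:
        config = IndepConfig(
            K=5.0 if K is None else float(K),
            B=1000 if B is None else int(B),
            seed=seed if isinstance(seed, (int, np.integer)) else None,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(config.seed)

    m = zv.m
    scale = 1.0 / np.sqrt(config.K - 1.0)
    acc = np.zeros(m)
    # moderate batches keep memory flat for large m * B
    batch = max(1, min(config.B, max(1, int(2e7 // max(m, 1)))))
    done = 0
    idx = np.arange(m)
    while done < config.B:
        b = min(batch, config.B - done)
        gamma = rng.normal(0.0, scale, size=(b, m))
        z_prime = zv.z + gamma
        c = zv.z - (config.K - 1.0) * gamma
        # re-ordering uses z' of the current repetition, never the observed z
        order = np.argsort(z_prime, axis=1, kind="stable")
        acc += np.take_along_axis(c, order, axis=1).sum(axis=0)
        done += b
        del gamma, z_prime, c, order
    delta_hat = acc / config.B

    rank_to_feature = np.argsort(zv.z, kind="stable")
    return RankedEstimates(
        delta_hat=delta_hat,
        rank_to_feature=rank_to_feature,
        K=config.K,
        n_partitions=config.B,
        seed=config.seed,
        ids=zv.ids,
    )


def augment_z(z_top: ZVector | np.ndarray, m_total: int) -> ZVector:
    """Pad a small set of top statistics out to the full scan size.

    A genome scan reports z only for its top hits, yet the ranking bias
    depends on how many features competed.  The missing m_total - m_top
    features are filled in with standard-normal quantiles on an evenly
    spaced grid, Phi^-1(i / (n_art + 1)) for i = 1..n_art — the null
    empirical quantiles a scan of that size would produce.  Artificial
    features get synthetic ids prefixed ``art``.
    """
    zv = z_top if isinstance(z_top, ZVector) else ZVector(z=np.asarray(z_top, dtype=float))
    m_top = zv.m
    if m_total <= m_top:
        raise ValueError(f"m_total ({m_total}) must exceed the observed count ({m_top})")
    n_art = m_total - m_top
    grid = np.arange(1, n_art + 1) / (n_art + 1)
    z_art = norm.ppf(grid)
    width = len(str(n_art))
    art_ids = tuple(f"art{i + 1:0{width}d}" for i in range(n_art))
    return ZVector(z=np.concatenate([zv.z, z_art]), ids=zv.ids + art_ids)
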