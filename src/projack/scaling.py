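"""Mapping between the z/mu scale and the reporting (log odds-ratio) scale.

A Wald statistic is z = beta_hat / SE with mu = beta / SE, where beta is the
natural log of the odds ratio.  Correction happens on the z scale; results
convert back to the beta scale by multiplying by the original estimated
standard errors.  Replication odds ratios, when available, act as a gold
standard for evaluating corrected estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EffectTable",
    "se_from_wald",
    "rescale_estimates",
    "squared_error_vs_replication",
]


@dataclass(frozen=True)
class EffectTable:
    """Per-feature association records: z, naive OR, optional replication OR."""

    ids: tuple[str, ...]
    z: np.ndarray
    or_naive: np.ndarray
    or_repl: np.ndarray | None = None
    p: np.ndarray | None = None
    annotations: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float).ravel()
        orn = np.asarray(self.or_naive, dtype=float).ravel()
        m = len(self.ids)
        if len(set(self.ids)) != m:
            raise ValueError("feature ids must be unique")
        if z.size != m or orn.size != m:
            raise ValueError("column lengths differ")
        if np.any(orn <= 0):
            raise ValueError("odds ratios must be positive")
        bad = np.sign(np.log(orn)) * np.sign(z) < 0
        if np.any(bad):
            names = [self.ids[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"sign(ln OR) disagrees with sign(z) for {names}")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "or_naive", orn)
        if self.or_repl is not None:
            orr = np.asarray(self.or_repl, dtype=float).ravel()
            if orr.size != m or np.any(orr <= 0):
                raise ValueError("replication ORs must be positive and aligned")
            object.__setattr__(self, "or_repl", orr)
        if self.p is not None:
            p = np.asarray(self.p, dtype=float).ravel()
            if p.size != m or np.any((p <= 0) | (p > 1)):
                raise ValueError("p-values must lie in (0, 1]")
            object.__setattr__(self, "p", p)

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def beta_naive(self) -> np.ndarray:
        return np.log(self.or_naive)

    @property
    def beta_repl(self) -> np.ndarray:
        if self.or_repl is None:
            raise ValueError("no replication odds ratios available")
        return np.log(self.or_repl)

    @property
    def se(self) -> np.ndarray:
        return se_from_wald(self.beta_naive, self.z)


def se_from_wald(beta_naive, z):
    """Implied standard error SE = beta_hat / z from a Wald statistic."""
    beta_naive = np.asarray(beta_naive, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z == 0):
        raise ValueError("z = 0 carries no standard-error information")
    return beta_naive / z


def rescale_estimates(delta_hat_per_feature, se) -> tuple[np.ndarray, np.ndarray]:
    """Convert corrected z-scale estimates back to (beta_hat, or_hat)."""
    d = np.asarray(delta_hat_per_feature, dtype=float).ravel()
    s = np.asarray(se, dtype=float).ravel()
    if d.size != s.size:
        raise ValueError(f"length mismatch: {d.size} estimates vs {s.size} SEs")
    beta_hat = d * s
    return beta_hat, np.exp(beta_hat)


def squared_error_vs_replication(beta_hat, effect_table: EffectTable) -> float:
    """Mean of (beta_hat_i - ln OR_repl_i)^2 over the table's features."""
    b = np.asarray(beta_hat, dtype=float).ravel()
    if effect_table.or_repl is None:
        raise ValueError(
            f"replication ORs missing for all features: {list(effect_table.ids)}"
        )
    if b.size != effect_table.m:
        raise ValueError("beta_hat not aligned with the effect table")
    return float(np.mean((b - effect_table.beta_repl) ** 2))
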