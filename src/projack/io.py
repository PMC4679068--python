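"""TSV readers/writers and the bundled psoriasis fixture.

All exchange files are tab-delimited UTF-8 with a header row.  Output files
carry ``#`` comment lines recording the seed, K and repetition count so any
run can be reproduced from its artifact.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import RankedEstimates, ZVector
from .scaling import EffectTable

__all__ = [
    "read_z_table",
    "read_effect_table",
    "load_psoriasis_table",
    "read_matrix",
    "write_matrix",
    "read_y",
    "write_ranked_estimates",
]

_EFFECT_COLUMNS = {"z", "or_naive"}


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def _id_column(df: pd.DataFrame) -> str:
    for cand in ("id", "snp", "feature"):
        if cand in df.columns:
            return cand
    return df.columns[0]


def _check_ids(ids, path) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    dup = pd.Series(ids).duplicated()
    if dup.any():
        bad = sorted({ids[i] for i in np.flatnonzero(dup.to_numpy())})
        raise ValueError(f"{path}: duplicate feature ids {bad}")
    return ids


def read_z_table(path) -> ZVector:
    """Read a TSV of per-feature z-statistics (columns: id, z)."""
    df = _read_tsv(path)
    if "z" not in df.columns:
        raise ValueError(f"{path}: missing required column 'z'")
    z = pd.to_numeric(df["z"], errors="coerce")
    if z.isna().any():
        rows = (z.isna().to_numpy().nonzero()[0] + 2).tolist()
        raise ValueError(f"{path}: non-numeric z at file line(s) {rows}")
    ids = _check_ids(df[_id_column(df)], path)
    return ZVector(z=z.to_numpy(float), ids=ids)


def read_effect_table(path) -> EffectTable:
    """Read an effect table (columns: id/snp, z, or_naive, optional p, or_repl)."""
    df = _read_tsv(path)
    missing = _EFFECT_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    ids = _check_ids(df[_id_column(df)], path)
    extra = [c for c in df.columns if c not in {"z", "p", "or_naive", "or_repl"}]
    return EffectTable(
        ids=ids,
        z=df["z"].to_numpy(float),
        or_naive=df["or_naive"].to_numpy(float),
        or_repl=df["or_repl"].to_numpy(float) if "or_repl" in df.columns else None,
        p=df["p"].to_numpy(float) if "p" in df.columns else None,
        annotations=df[extra].copy() if extra else None,
    )


def load_psoriasis_table() -> EffectTable:
    """The bundled 10-SNP psoriasis case study table.

    Ten SNPs from a 480,000-SNP case-control scan (1350 cases / 1400
    controls) with replication odds ratios from an independent 5000/5000
    sample — a textbook display of the winner's curse: every replication
    OR sits closer to 1 than its naive counterpart.
    """
    with resources.as_file(
        resources.files("projack").joinpath("data/psoriasis_table1.tsv")
    ) as p:
        return read_effect_table(p)


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...], list[str]]:
    """Read an m x n matrix TSV (first column feature ids, header sample ids)."""
    df = _read_tsv(path)
    ids = _check_ids(df.iloc[:, 0], path)
    body = df.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: non-numeric value for feature {ids[i]!r}, column {body.columns[j]!r}"
        )
    return values, ids, list(body.columns)


def write_matrix(path, values: np.ndarray, ids, sample_ids=None) -> None:
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, columns=sample_ids)
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_y(path) -> tuple[np.ndarray, list[str]]:
    """Read an outcome TSV with two columns: sample id, value."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: outcome file needs two columns (sample id, value)")
    y = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if y.isna().any():
        raise ValueError(f"{path}: non-numeric outcome values")
    return y.to_numpy(float), [str(s) for s in df.iloc[:, 0]]


def _header_comment(est: RankedEstimates) -> str:
    seed = "none" if est.seed is None else est.seed
    return (
        f"# projack v{__version__} | K={est.K:g} reps={est.n_partitions} seed={seed}\n"
    )


def write_ranked_estimates(
    path,
    est: RankedEstimates,
    z: np.ndarray,
    full_precision: bool = False,
) -> None:
    """Write the rank table: rank, feature_id, z, delta_hat (ascending)."""
    z = np.asarray(z, dtype=float).ravel()
    order = est.rank_to_feature
    df = pd.DataFrame(
        {
            "rank": np.arange(1, est.m + 1),
            "feature_id": [est.ids[i] for i in order],
            "z": z[order],
            "delta_hat": est.delta_hat,
        }
    )
    fmt = "%.17g" if full_precision else "%.6g"
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(est))
        df.to_csv(fh, sep="\t", index=False, float_format=fmt)
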