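"""Mutual-information estimation for sparse, censored abundance vectors.

The hybrid-partitioning estimator (hpMI) decomposes the joint space of two
peptide rank vectors into four observed/missing quadrants. Jointly observed
points are scored by the adaptive-partitioning MI estimator; the
observed/missing structure itself is scored as a discrete 2x2 cell system,
so informative censoring below the limit of detection (co-missingness of an
enzyme and its substrate) contributes to the dependence estimate instead of
being discarded.

MI is reported in nats. Significance thresholds come from a permutation
null in which values and missingness are permuted together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._mi_core import adaptive_mi, batch_mi, hpmi_ranks
from .pvm import PhosphoMatrix

__all__ = [
    "MiResult",
    "rank_rows",
    "adaptive_partition_mi",
    "hpmi",
    "dmi",
    "imi",
    "spearman_complete",
    "null_mi_values",
    "null_mi_threshold",
    "impute_row_min_noise",
]


@dataclass
class MiResult:
    """hpMI estimate plus the observed/missing quadrant counts.

    quadrant_counts = (n11 both observed, n00 both missing,
    n01 x-missing-only, n10 y-missing-only); they sum to n.
    """

    mi: float
    quadrant_counts: tuple[int, int, int, int]


def rank_rows(values: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Row-wise ranks of observed entries (1..n_obs); missing entries get 0.

    Ties (which arise when bootstrap resampling duplicates runs) are broken
    randomly with ``rng`` when given, otherwise deterministically by column
    position.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    n_rows, n_cols = v.shape
    out = np.zeros((n_rows, n_cols), dtype=np.int64)
    fin = np.isfinite(v)
    tb = rng.random(v.shape) if rng is not None else None
    for i in range(n_rows):
        obs = np.nonzero(fin[i])[0]
        m = obs.size
        if m == 0:
            continue
        key2 = tb[i, obs] if tb is not None else obs
        order = obs[np.lexsort((key2, v[i, obs]))]
        out[i, order] = np.arange(1, m + 1)
    return out


def _to_rank_vector(x) -> np.ndarray:
    return rank_rows(np.asarray(x, dtype=float)[None, :])[0]


def adaptive_partition_mi(x, y, max_depth: int | None = None) -> float:
    """Adaptive-partitioning MI (nats) of two complete vectors.

    ``max_depth`` forces a fixed 2^d x 2^d grid partition instead of the
    chi-square-driven recursion, which makes the final partition explicit
    for validation against plug-in contingency-table MI.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("adaptive_partition_mi requires at least 8 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("adaptive_partition_mi requires complete vectors")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant vector: MI is 0")
        return 0.0
    depth = -1 if max_depth is None else int(max_depth)
    return float(adaptive_mi(_to_rank_vector(x), _to_rank_vector(y), depth))


def hpmi(x, y) -> MiResult:
    """Hybrid-partition MI of two vectors with NaN marking missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("hpmi requires n >= 8")
    if not np.isfinite(x).any() or not np.isfinite(y).any():
        raise ValueError("all-missing vector")
    xr = _to_rank_vector(x)
    yr = _to_rank_vector(y)
    mi, n11, n00, n01, n10 = hpmi_ranks(xr, yr, -1)
    return MiResult(float(mi), (int(n11), int(n00), int(n01), int(n10)))


def dmi(x, y) -> float:
    """Complete-case (depleted) MI: adaptive-partition MI over jointly observed points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    joint = np.isfinite(x) & np.isfinite(y)
    if joint.sum() < 8:
        return 0.0
    return adaptive_partition_mi(x[joint], y[joint])


def impute_row_min_noise(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Impute missing entries as row minimum + uniform low-intensity noise.

    The noise range per row is the gap between the two lowest observed
    values; rows with fewer than two observed values get range 0 (with a
    warning), which leaves ties unbroken for that row.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float)).copy()
    warned = False
    for i in range(v.shape[0]):
        row = v[i]
        miss = ~np.isfinite(row)
        if not miss.any():
            continue
        obs = np.sort(row[~miss])
        if obs.size == 0:
            continue
        if obs.size < 2:
            rng_width = 0.0
            warned = True
        else:
            rng_width = obs[1] - obs[0]
        v[i, miss] = obs[0] + rng.uniform(0.0, 1.0, int(miss.sum())) * rng_width
    if warned:
        warnings.warn("rows with < 2 observed values imputed without noise")
    return v


def imi(x, y, seed: int = 0) -> float:
    """MI after row-min + low-intensity-noise imputation of missing values."""
    rng = np.random.default_rng(seed)
    xy = impute_row_min_noise(np.vstack([np.asarray(x, float), np.asarray(y, float)]), rng)
    return adaptive_partition_mi(xy[0], xy[1])


def spearman_complete(x, y) -> float:
    """Spearman correlation over jointly observed entries; NaN if < 3 joint points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    joint = np.isfinite(x) & np.isfinite(y)
    if joint.sum() < 3:
        return float("nan")
    rho = stats.spearmanr(x[joint], y[joint]).statistic
    return float(rho)


def _values_of(m) -> np.ndarray:
    if isinstance(m, PhosphoMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def _default_pairs(n_rows: int, max_pairs: int, rng: np.random.Generator):
    total = n_rows * (n_rows - 1) // 2
    iu = np.triu_indices(n_rows, k=1)
    ia, ib = iu[0].astype(np.int64), iu[1].astype(np.int64)
    if total > max_pairs:
        sel = rng.choice(total, size=max_pairs, replace=False)
        ia, ib = ia[sel], ib[sel]
    return ia, ib


def null_mi_values(
    m,
    pairs=None,
    n_perm: int = 10,
    seed: int = 0,
    estimator: str = "hpmi",
    max_pairs: int = 100_000,
) -> np.ndarray:
    """Null MI sample from row-wise permutation of the rank matrix.

    Missing values are permuted together with the observed ones, so the
    null preserves each vector's missingness rate while destroying both
    value- and missingness-coupling between vectors.
    """
    values = _values_of(m)
    rng = np.random.default_rng(seed)
    R = rank_rows(values)
    if pairs is None:
        ia, ib = _default_pairs(R.shape[0], max_pairs, rng)
    else:
        ia = np.asarray(pairs[0], dtype=np.int64)
        ib = np.asarray(pairs[1], dtype=np.int64)
    method = 0 if estimator == "hpmi" else 1
    nulls = np.empty(n_perm * ia.size)
    out = np.empty(ia.size)
    for p in range(n_perm):
        Rp = rng.permuted(R, axis=1)
        batch_mi(Rp, ia, ib, method, out)
        nulls[p * ia.size:(p + 1) * ia.size] = out
    return nulls


def null_mi_threshold(
    m,
    fwer: float = 0.05,
    n_perm: int = 10,
    pairs=None,
    n_candidates: int | None = None,
    seed: int = 0,
    estimator: str = "hpmi",
    max_pairs: int = 100_000,
) -> float:
    """Family-wise MI significance threshold from the permutation null.

    The per-test tail probability is Sidak-derived,
    ``p = 1 - (1 - fwer)^(1/n_candidates)``; the corresponding null
    quantile is read off empirically when the null sample resolves it and
    otherwise extrapolated by an exponential fit to the top 1% of null MI
    values.
    """
    if not (0.0 < fwer <= 1.0):
        raise ValueError("fwer must be in (0, 1]")
    nulls = null_mi_values(m, pairs=pairs, n_perm=n_perm, seed=seed,
                           estimator=estimator, max_pairs=max_pairs)
    if n_candidates is None:
        n_candidates = nulls.size // max(n_perm, 1)
    if fwer == 1.0:
        return float(nulls.min())
    p_target = 1.0 - (1.0 - fwer) ** (1.0 / max(n_candidates, 1))
    n_null = nulls.size
    if p_target * n_null >= 10.0:
        return float(np.quantile(nulls, 1.0 - p_target))
    if n_null < 2000:
        per_perm = n_null // max(n_perm, 1)
        need = math.ceil(2000 / max(per_perm, 1))
        raise ValueError(
            f"permutation null of size {n_null} cannot resolve the "
            f"{p_target:.2e} tail; need n_perm >= {need}"
        )
    u = float(np.quantile(nulls, 0.99))
    exc = nulls[nulls > u] - u
    if exc.size == 0 or exc.mean() == 0:
        return u
    rate = 1.0 / float(exc.mean())
    p_u = exc.size / n_null
    return u + math.log(p_u / p_target) / rate
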