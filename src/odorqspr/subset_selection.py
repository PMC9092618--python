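"""Exhaustive best-subset multiple linear regression.

Every combination of a fixed number of columns from the GFA-reduced pool
is fitted by ordinary least squares on the training rows and ranked by
the quality of its validation-set predictions: first by the trimmed-MAE
quality class (good < moderate < bad), then by the trimmed MAE itself,
then lexicographically by descriptor names.  The enumeration is batched
linear algebra over precomputed cross-products, so pools up to C(32,6)
(about 9.1e5 models) are practical on one core.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .validation_suite import mae_trimmed_stats, mae_class_from_stats

__all__ = ["SubsetModel", "fit_mlr", "enumerate_best_subsets", "final_pool"]

#: refuse enumerations larger than this many candidate fits
ENUMERATION_CAP = 2_000_000
_CLASS_ORDER = {"good": 0, "moderate": 1, "bad": 2}


class SubsetError(ValueError):
    pass


@dataclass
class SubsetModel:
    descriptors: list[str]
    coefficients: np.ndarray  # intercept first
    r2: float
    r2_adj: float
    s: float
    validation_mae: float
    validation_mae_class: str


def fit_mlr(X_subset: pd.DataFrame, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """OLS fit with intercept; returns (coefficients, residuals, R2, Ra2, s)."""
    y = np.asarray(y, dtype=float)
    n, p = X_subset.shape
    if n <= p + 1:
        raise SubsetError(f"need n > p + 1 (got n={n}, p={p})")
    A = np.column_stack([np.ones(n), X_subset.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank < p + 1:
        # identify offending columns via pivoted correlation check
        bad = []
        for j, name in enumerate(X_subset.columns):
            sub = np.delete(A, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise SubsetError(f"design matrix is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    s = float(np.sqrt(sse / (n - p - 1)))
    return coef, resid, r2, r2_adj, s


def enumerate_best_subsets(
    pool: pd.DataFrame,
    y_train: np.ndarray,
    X_valid: pd.DataFrame,
    y_valid: np.ndarray,
    size: int = 6,
    n_keep: int | None = 100,
    cap: int = ENUMERATION_CAP,
    batch: int = 20_000,
) -> list[SubsetModel]:
    """Fit all C(p, size) OLS models and rank them by validation MAE class.

    ``pool`` holds the training rows of the candidate columns, ``X_valid``
    the validation rows of the same columns.  Returns the ``n_keep`` best
    models (all models when ``n_keep`` is None).
    """
    names = list(pool.columns)
    p = len(names)
    if p < size:
        raise SubsetError(f"pool has {p} columns, fewer than subset size {size}")
    if list(X_valid.columns) != names:
        X_valid = X_valid[names]
    total = comb(p, size)
    if total > cap:
        raise SubsetError(
            f"C({p},{size}) = {total} exceeds the enumeration cap {cap}; "
            "reduce the pool or raise the cap"
        )
    y_tr = np.asarray(y_train, dtype=float)
    y_va = np.asarray(y_valid, dtype=float)
    n = len(y_tr)
    if n <= size + 1:
        raise SubsetError("too few training rows for the requested subset size")
    y_range = float(y_tr.max() - y_tr.min())

    # cross-products with intercept column prepended
    Xt = np.column_stack([np.ones(n), pool.to_numpy(dtype=float)])
    Xv = np.column_stack([np.ones(len(y_va)), X_valid.to_numpy(dtype=float)])
    G = Xt.T @ Xt  # (p+1, p+1)
    gy = Xt.T @ y_tr

    results: list[tuple[tuple, SubsetModel]] = []

    def flush(index_block: np.ndarray) -> None:
        B = index_block.shape[0]
        idx = np.concatenate([np.zeros((B, 1), dtype=int), index_block + 1], axis=1)
        Gs = G[idx[:, :, None], idx[:, None, :]]  # (B, s+1, s+1)
        gys = gy[idx]  # (B, s+1)
        try:
            beta = np.linalg.solve(Gs, gys[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta = np.stack([np.linalg.lstsq(Gs[i], gys[i], rcond=None)[0] for i in range(B)])
        pred = np.einsum("bvk,bk->bv", Xv[:, idx].transpose(1, 0, 2), beta)
        err = np.abs(pred - y_va[None, :])
        mae, sd = mae_trimmed_stats(err)
        for i in range(B):
            sub = tuple(index_block[i])
            cls = mae_class_from_stats(float(mae[i]), float(sd[i]), y_range)
            key = (_CLASS_ORDER[cls], float(mae[i]), tuple(sorted(names[j] for j in sub)))
            results.append(
                (
                    key,
                    SubsetModel(
                        descriptors=[names[j] for j in sub],
                        coefficients=beta[i],
                        r2=np.nan, r2_adj=np.nan, s=np.nan,
                        validation_mae=float(mae[i]),
                        validation_mae_class=cls,
                    ),
                )
            )
        # keep the memory footprint bounded for big enumerations
        if n_keep is not None and len(results) > 4 * max(n_keep, batch // 4):
            results.sort(key=lambda t: t[0])
            del results[max(n_keep, 1000):]

    block: list[tuple] = []
    for combo in itertools.combinations(range(p), size):
        block.append(combo)
        if len(block) == batch:
            flush(np.asarray(block, dtype=int))
            block = []
    if block:
        flush(np.asarray(block, dtype=int))

    results.sort(key=lambda t: t[0])
    if n_keep is not None:
        results = results[:n_keep]
    models = [m for _, m in results]
    # fill in training fit statistics for the retained models only
    for m in models:
        _, _, r2, r2a, s = fit_mlr(pool[m.descriptors], y_tr)
        m.r2, m.r2_adj, m.s = r2, r2a, s
    return models


def final_pool(top_models: Sequence[SubsetModel], m: int = 5) -> list[str]:
    """Union of descriptor names over the m best subset models."""
    if not top_models:
        raise SubsetError("no models supplied")
    if m > len(top_models):
        raise SubsetError(f"requested top {m} of only {len(top_models)} models")
    pool: list[str] = []
    for model in list(top_models)[:m]:
        for name in model.descriptors:
            if name not in pool:
                pool.append(name)
    return pool


def ranking_frame(models: Sequence[SubsetModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(models) + 1),
            "descriptors": [";".join(m.descriptors) for m in models],
            "train_r2": [m.r2 for m in models],
            "validation_mae": [m.validation_mae for m in models],
            "mae_class": [m.validation_mae_class for m in models],
        }
    )
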