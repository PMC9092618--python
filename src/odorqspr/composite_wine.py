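"""Composite odor-threshold prediction for multi-component wines.

A wine is a mixture of aroma compounds.  Its "composite" descriptor
vector is the (optionally weighted) mean of the final model's descriptor
columns — after spline transformation — over the wine's components; the
fitted PLS coefficients applied to that vector give a composite log(OT).
Because the model is linear in those columns, the composite prediction
equals the weighted mean of the per-component predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pls_engine import PLSModel

__all__ = [
    "WineComposition",
    "composite_descriptors",
    "predict_composite",
    "rank_wines",
    "read_wine_table",
]


class WineError(ValueError):
    pass


@dataclass
class WineComposition:
    wine_id: str
    components: list[str]
    weights: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if not self.components:
            raise WineError(f"wine {self.wine_id!r} has no components")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.components):
                raise WineError(f"wine {self.wine_id!r}: weights/components length mismatch")
            if np.any(w < 0) or w.sum() <= 0:
                raise WineError(f"wine {self.wine_id!r}: weights must be non-negative with positive sum")

    def normalized_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.components), 1.0 / len(self.components))
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()


def composite_descriptors(comp: WineComposition, table: pd.DataFrame) -> pd.Series:
    """Weighted mean of each model-descriptor column over the components.

    ``table`` holds per-compound values of the final model's descriptor
    columns (already spline-transformed), indexed by compound id.
    """
    missing = [c for c in comp.components if c not in table.index]
    if missing:
        raise WineError(f"wine {comp.wine_id!r}: unknown component ids {missing}")
    sub = table.loc[comp.components].to_numpy(dtype=float)
    w = comp.normalized_weights()
    return pd.Series(w @ sub, index=table.columns, name=comp.wine_id)


def predict_composite(model: PLSModel, composite: pd.Series | np.ndarray) -> float:
    """Apply the fitted coefficient form to a composite descriptor vector."""
    if isinstance(composite, pd.Series):
        missing = [c for c in model.columns if c not in composite.index]
        if missing:
            raise WineError(f"composite vector lacks model descriptors {missing}")
        vec = composite[model.columns].to_numpy(dtype=float)
    else:
        vec = np.asarray(composite, dtype=float).ravel()
        if len(vec) != model.n_vars:
            raise WineError(
                f"composite vector has {len(vec)} entries, model expects {model.n_vars}"
            )
    return float(model.intercept_ + vec @ model.coef_)


def rank_wines(predictions: Mapping[str, float]) -> list[tuple[str, float]]:
    """Ascending composite log(OT); lower threshold = more potent aroma."""
    if not predictions:
        raise WineError("no wines to rank")
    return sorted(predictions.items(), key=lambda kv: (kv[1], kv[0]))


def predict_wines(model: PLSModel, wines: Sequence[WineComposition],
                  table: pd.DataFrame) -> pd.DataFrame:
    preds = {w.wine_id: predict_composite(model, composite_descriptors(w, table)) for w in wines}
    ranked = rank_wines(preds)
    return pd.DataFrame(
        {
            "wine_id": [w for w, _ in ranked],
            "composite_log_ot": [v for _, v in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )


def read_wine_table(path: str | Path) -> list[WineComposition]:
    """Read ``wine_id,component_id[,weight]`` CSV into compositions."""
    df = pd.read_csv(path, dtype={"wine_id": str, "component_id": str})
    if not {"wine_id", "component_id"} <= set(df.columns):
        raise WineError("wine table needs columns wine_id,component_id[,weight]")
    wines = []
    for wid, grp in df.groupby("wine_id", sort=False):
        weights = grp["weight"].tolist() if "weight" in df.columns else None
        wines.append(WineComposition(str(wid), grp["component_id"].tolist(), weights))
    return wines
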