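"""SHAP-style attribution analysis of trained surrogates.

Per-sample, per-feature Shapley attributions are computed with the exact
tree-path algorithm (TreeSHAP) native to the LightGBM backend, so each
row satisfies local accuracy: baseline + sum(attributions) = prediction.
Global importance is the mean absolute attribution per feature; pairwise
effects are summarized as two-variable partial-dependence grids averaged
over a fixed background sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surrogate import GradientBoostedSurrogate

__all__ = [
    "AttributionMatrix",
    "attribute",
    "rank_importance",
    "interaction_surface",
]


@dataclass(frozen=True)
class AttributionMatrix:
    """n x d per-sample attributions (label units) plus the model baseline."""

    values: pd.DataFrame          # one column per feature
    baseline: float
    predictions: np.ndarray

    def __post_init__(self) -> None:
        recon = self.baseline + self.values.to_numpy().sum(axis=1)
        if not np.allclose(recon, self.predictions, atol=1e-6, rtol=1e-6):
            raise ValueError("local accuracy violated: baseline + sum != prediction")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def attribute(model: GradientBoostedSurrogate, inputs) -> AttributionMatrix:
    """Exact TreeSHAP attributions of every prediction on ``inputs``."""
    if model.backend != "lightgbm":
        raise NotImplementedError(
            f"TreeSHAP attributions require the lightgbm backend, got {model.backend!r}"
        )
    if isinstance(inputs, pd.DataFrame):
        expected = list(model.feature_names_in_)
        if list(inputs.columns) != expected:
            raise ValueError(
                f"feature-name mismatch: model expects {expected}, got {list(inputs.columns)}"
            )
        X = inputs.to_numpy(dtype=float)
        names = list(inputs.columns)
    else:
        X = np.asarray(inputs, dtype=float)
        names = list(model.feature_names_in_)
    contrib = model.model_.booster_.predict(X, pred_contrib=True)
    values, base = contrib[:, :-1], contrib[:, -1]
    preds = model.model_.booster_.predict(X)
    return AttributionMatrix(
        values=pd.DataFrame(values, columns=names),
        baseline=float(base[0]),
        predictions=np.asarray(preds),
    )


def rank_importance(attr: AttributionMatrix) -> pd.DataFrame:
    """Features ordered by mean |attribution|, descending.

    Ties are broken by original feature index (stable sort), so duplicated
    features keep their declaration order.
    """
    mean_abs = attr.values.abs().mean(axis=0)
    order = np.argsort(-mean_abs.to_numpy(), kind="stable")
    return pd.DataFrame(
        {
            "feature": [attr.feature_names[i] for i in order],
            "mean_abs_attribution": mean_abs.to_numpy()[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )


def interaction_surface(
    model,
    feature_pair: tuple[str, str],
    grid: tuple[np.ndarray, np.ndarray],
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Two-variable partial-dependence surface.

    For each node of the (g1 x g2) grid, the pair of features is clamped to
    the node value in every background row and the model predictions are
    averaged.  Returns a tidy frame with columns (f1, f2, response).
    """
    if len(background) == 0:
        raise ValueError("background set must be non-empty")
    f1, f2 = feature_pair
    g1, g2 = (np.atleast_1d(np.asarray(g, dtype=float)) for g in grid)
    cols = list(background.columns)
    i1, i2 = cols.index(f1), cols.index(f2)
    base = background.to_numpy(dtype=float)
    records = []
    for v1 in g1:
        for v2 in g2:
            Xg = base.copy()
            Xg[:, i1] = v1
            Xg[:, i2] = v2
            pred = float(np.mean(model.predict(pd.DataFrame(Xg, columns=cols))))
            records.append({f1: v1, f2: v2, "response": pred})
    return pd.DataFrame(records)
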