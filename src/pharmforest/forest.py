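"""Per-compound random-forest regressor with out-of-bag bookkeeping.

One forest is fitted per compound on the cell lines with a non-missing AUC.
Each of the B regression trees is trained on a bootstrap sample of size n
drawn with replacement; at every split, m candidate predictors are drawn
uniformly (default "one-third": m = max(1, floor(p/3)), the convention of the
R randomForest regression default).  Trees are grown deep with the usual
regression defaults (no depth cap, minimum leaf size 5).

The fit records the full in-bag multiplicity matrix, so the out-of-bag (OOB)
prediction for cell line i is the average over exactly the trees whose
bootstrap never drew i:

    yhat_i^OOB = (1 / |B_i|) * sum_{b in B_i} yhat_ib,
    B_i = {b : inbag[b, i] = 0}.

With B large these are virtually leave-one-out cross-validation predictions.
A cell line in-bag in every tree has an empty B_i; its OOB prediction is NaN
and it is excluded from downstream error and concordance computations.

Model stability is checked ex post from the OOB error curve e_b (OOB mean
squared error using only the first b trees): the stability value is the mean
of the last ``window`` squared successive differences of that curve, which is
0 at reporting precision once the forest has converged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ForestFit",
    "StabilityValue",
    "drop_missing",
    "resolve_mtry",
    "fit_forest",
    "oob_predictions",
    "stability_indicator",
]


def drop_missing(
    y: np.ndarray, X: np.ndarray, min_samples: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove cell lines with a missing response from both y and X.

    Returns ``(y_kept, X_kept, kept_mask)``.  Raises ``ValueError`` when
    fewer than ``min_samples`` cell lines remain.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X)
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"length mismatch: y has {y.shape[0]} rows, X has {X.shape[0]}")
    kept = ~np.isnan(y)
    n_kept = int(kept.sum())
    if n_kept < min_samples:
        raise ValueError(f"fewer than {min_samples} cell lines with observed AUC ({n_kept})")
    return y[kept], X[kept], kept


def resolve_mtry(m: int | str, n_predictors: int) -> int:
    """Number of candidate predictors per split; "one-third" -> max(1, p//3)."""
    if n_predictors < 1:
        raise ValueError("no predictors")
    if isinstance(m, str):
        if m != "one-third":
            raise ValueError(f"unknown mtry rule: {m!r}")
        return max(1, n_predictors // 3)
    m = int(m)
    if not 1 <= m <= n_predictors:
        raise ValueError(f"mtry {m} outside [1, {n_predictors}]")
    return m


@dataclass
class ForestFit:
    """A fitted per-compound forest with its OOB bookkeeping.

    ``inbag[b, i]`` is the bootstrap multiplicity of cell line i in tree b;
    ``tree_predictions[b, i]`` is tree b's prediction for cell line i;
    ``oob_pred`` is NaN where no tree left the cell line out-of-bag;
    ``oob_error_curve[b-1]`` is the OOB mean squared error after b trees.
    """

    trees: list[DecisionTreeRegressor]
    B: int
    m: int
    inbag: np.ndarray
    tree_predictions: np.ndarray
    oob_pred: np.ndarray
    oob_error_curve: np.ndarray
    y: np.ndarray
    sample_size: int
    mean_auc: float
    seed: int
    feature_names: list[str] | None = None

    @property
    def n_predictors(self) -> int:
        return self.trees[0].n_features_in_ if self.trees else 0

    def summary(self) -> dict:
        return {
            "B": self.B,
            "m": self.m,
            "seed": self.seed,
            "sample_size": self.sample_size,
            "mean_auc": self.mean_auc,
            "oob_mse": float(self.oob_error_curve[-1]),
            "n_empty_oob": int(np.isnan(self.oob_pred).sum()),
        }


@dataclass
class StabilityValue:
    """Ex-post forest stability: mean of the last ``window`` squared
    successive differences of the OOB error curve; ``reached`` when the value
    rounds to zero at reporting precision."""

    value: float
    window: int
    reached: bool


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 500,
    m: int | str = "one-third",
    seed: int = 0,
    min_samples_leaf: int = 5,
    feature_names: Sequence[str] | None = None,
) -> ForestFit:
    """Fit B bootstrap regression trees and assemble OOB predictions.

    ``X`` is the binary cell-line x alteration matrix (no missing values),
    ``y`` the observed AUCs in [0, 1].  The run is fully determined by
    ``seed``: bootstrap draws and per-tree split randomness derive from one
    generator, so refitting on the same data reproduces the in-bag matrix and
    all predictions bit for bit.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValueError("no predictors")
    if np.isnan(y).any():
        raise ValueError("missing response passed to fit_forest; use drop_missing first")
    m_int = resolve_mtry(m, p)
    rng = np.random.default_rng(seed)

    trees: list[DecisionTreeRegressor] = []
    inbag = np.zeros((B, n), dtype=np.int32)
    preds = np.empty((B, n), dtype=float)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        inbag[b] = np.bincount(idx, minlength=n)
        tree = DecisionTreeRegressor(
            max_features=m_int,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        preds[b] = tree.predict(X)
        trees.append(tree)

    oob_mask = inbag == 0
    cum_sum = np.cumsum(preds * oob_mask, axis=0)
    cum_cnt = np.cumsum(oob_mask, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum_mean = cum_sum / cum_cnt
    sq_err = np.where(cum_cnt > 0, (cum_mean - y[None, :]) ** 2, np.nan)
    with np.errstate(invalid="ignore"):
        curve = np.nanmean(sq_err, axis=1)
    oob_pred = np.where(cum_cnt[-1] > 0, cum_mean[-1], np.nan)

    return ForestFit(
        trees=trees,
        B=B,
        m=m_int,
        inbag=inbag,
        tree_predictions=preds,
        oob_pred=oob_pred,
        oob_error_curve=curve,
        y=y,
        sample_size=n,
        mean_auc=float(y.mean()),
        seed=seed,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def oob_predictions(fit: ForestFit) -> np.ndarray:
    """Per-cell-line OOB prediction vector (NaN where no tree left it out)."""
    return fit.oob_pred


def stability_indicator(
    fit: ForestFit, window: int = 10, tolerance: float = 1e-6
) -> StabilityValue:
    """Mean of the last ``window`` squared successive OOB-error differences.

    Requires ``B >= window + 1`` so that ``window`` successive differences
    exist.  ``reached`` reports whether the value rounds to zero at
    ``tolerance`` precision; the raw value stays auditable.
    """
    if fit.B < window + 1:
        raise ValueError(f"B={fit.B} too small for stability window {window}")
    diffs = np.diff(fit.oob_error_curve)[-window:]
    value = float(np.mean(diffs**2))
    return StabilityValue(value=value, window=window, reached=value < tolerance)
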