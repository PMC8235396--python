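"""Per-tree OOB permutation importance with z-tests and Bonferroni calls.

For each tree b and alteration j, the per-tree importance is the change of
tree b's mean squared error on its own OOB cell lines after permuting column
j within those OOB cell lines (one seeded permutation per tree/predictor
pair):

    imp_jb = MSE_b(OOB, X with column j permuted) - MSE_b(OOB, X).

A predictor never used in any split of a tree leaves that tree's predictions
unchanged, so its imp_jb is exactly 0 and no permutation is evaluated.  Trees
with fewer than two OOB cell lines contribute nothing (the divisor is
adjusted).  The mean importance over trees, imp(X_j), is normalized by its
estimated standard deviation -- the sample standard deviation of the imp_jb
(B - 1 denominator) divided by sqrt(B) -- into an approximate z-score, the
normalization the reference R implementation applies when scaling
importances; the one-sided p-value is the upper standard-normal tail at z.
Within each model the p-values get a Bonferroni correction over the
predictors entering that model, and an alteration is called significantly
influential when the adjusted p falls below 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
from scipy import stats

from .forest import ForestFit

__all__ = ["ImportanceTable", "permutation_importance", "importance_test"]


@dataclass
class ImportanceTable:
    """Per-alteration permutation importance and its significance test."""

    feature_names: list[str]
    imp: np.ndarray
    sd: np.ndarray
    n_trees: int  # trees that contributed (>= 2 OOB samples)
    z: np.ndarray | None = None
    p: np.ndarray | None = None
    p_adj: np.ndarray | None = None
    significant: np.ndarray | None = None
    per_tree: np.ndarray | None = None  # optional (B, p) audit matrix

    @property
    def n_predictors(self) -> int:
        return len(self.feature_names)

    def significant_alterations(self) -> list[str]:
        """Significant alterations ordered by decreasing mean importance."""
        if self.significant is None:
            raise ValueError("run importance_test first")
        idx = np.flatnonzero(self.significant)
        return [self.feature_names[i] for i in idx[np.argsort(-self.imp[idx], kind="stable")]]

    def to_frame(self, sort: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "alteration": self.feature_names,
                "imp": self.imp,
                "sd": self.sd,
                "z": self.z if self.z is not None else np.nan,
                "p": self.p if self.p is not None else np.nan,
                "p_adj": self.p_adj if self.p_adj is not None else np.nan,
                "significant": self.significant
                if self.significant is not None
                else False,
            }
        )
        if sort:
            df = df.sort_values("imp", ascending=False, kind="stable").reset_index(drop=True)
        return df

    def to_csv(self, target: str | Path | IO[str]) -> None:
        self.to_frame().to_csv(target, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_trees: int = 0) -> "ImportanceTable":
        return cls(
            feature_names=list(df["alteration"]),
            imp=df["imp"].to_numpy(float),
            sd=df["sd"].to_numpy(float),
            n_trees=n_trees,
            z=df["z"].to_numpy(float),
            p=df["p"].to_numpy(float),
            p_adj=df["p_adj"].to_numpy(float),
            significant=df["significant"].to_numpy(bool),
        )


def permutation_importance(
    fit: ForestFit,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    drug_index: int = 0,
    keep_per_tree: bool = False,
) -> ImportanceTable:
    """Per-tree OOB permutation importance of every predictor.

    Permutations are drawn from per-predictor generators keyed by
    ``(seed, drug_index, predictor)``, one draw per contributing tree, so
    results are reproducible and adding or removing drugs does not shift
    other models' permutations.  Only predictors actually used by a tree's
    splits are re-predicted (others change nothing); the perturbed inputs for
    all used predictors of a tree are stacked into a single predict call.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rngs = [np.random.default_rng(np.random.SeedSequence((seed, drug_index, j))) for j in range(p)]

    sums = np.zeros(p)
    sumsq = np.zeros(p)
    per_tree = np.zeros((fit.B, p)) if keep_per_tree else None
    n_eff = 0
    for b, tree in enumerate(fit.trees):
        oob = np.flatnonzero(fit.inbag[b] == 0)
        n_oob = oob.size
        if n_oob < 2:
            continue
        n_eff += 1
        y_oob = y[oob]
        base_mse = float(np.mean((fit.tree_predictions[b, oob] - y_oob) ** 2))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size == 0:
            continue
        X_oob = X[oob]
        block = np.tile(X_oob, (used.size, 1))
        for k, j in enumerate(used):
            perm = rngs[j].permutation(n_oob)
            block[k * n_oob : (k + 1) * n_oob, j] = X_oob[perm, j]
        perm_pred = tree.predict(block).reshape(used.size, n_oob)
        delta = np.mean((perm_pred - y_oob[None, :]) ** 2, axis=1) - base_mse
        sums[used] += delta
        sumsq[used] += delta**2
        if per_tree is not None:
            per_tree[b, used] = delta
    if n_eff == 0:
        raise ValueError("no tree had at least two OOB samples")

    imp = sums / n_eff
    if n_eff > 1:
        ss = np.maximum(sumsq - n_eff * imp**2, 0.0)
        sd = np.sqrt(ss / (n_eff - 1))
    else:
        sd = np.zeros(p)
    names = fit.feature_names if fit.feature_names is not None else [f"X{j}" for j in range(p)]
    return ImportanceTable(
        feature_names=list(names), imp=imp, sd=sd, n_trees=n_eff, per_tree=per_tree
    )


def importance_test(
    table: ImportanceTable, alpha: float = 0.005, n_tests: int | None = None
) -> ImportanceTable:
    """Fill in z, one-sided p, Bonferroni-adjusted p and significance flags.

    ``z`` is the mean per-tree importance over its standard error
    (sd / sqrt(number of contributing trees)).  ``n_tests`` defaults to the
    number of predictors entering the model (the Bonferroni family).
    Conventions for degenerate sd = 0 rows: p = 1 when the mean importance
    is <= 0 (never-used predictor), p = 0 when it is strictly positive
    (constant positive importance, flagged significant).
    """
    if n_tests is None:
        n_tests = table.n_predictors
    imp, sd = table.imp, table.sd
    se = sd / np.sqrt(table.n_trees)
    z = np.full_like(imp, np.nan)
    p = np.empty_like(imp)
    pos = se > 0
    z[pos] = imp[pos] / se[pos]
    p[pos] = stats.norm.sf(z[pos])
    p[~pos] = np.where(imp[~pos] > 0, 0.0, 1.0)
    p_adj = np.minimum(1.0, p * n_tests)
    table.z = z
    table.p = p
    table.p_adj = p_adj
    table.significant = p_adj < alpha
    return table
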