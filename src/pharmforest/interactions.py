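"""Screening and testing of drug-gene interactions between compound pairs.

A pharmacogenomic interaction, statistically, is a drug x alteration
interaction on the response scale: the effect of which compound was used
depends on the genomic state of the treated cell line.  Clues come from
Report-1 compound pairs with very similar average AUCs but different most
influential alterations: a similar marginal response that decomposes
differently over genomic subgroups.

For a candidate pair the AUCs of both compounds are stacked into a long
table, logit-normalized (with boundary clipping, since screens do produce
AUC = 1), and modelled by a two-way ANOVA with the compound as Factor 1 and
the joint status of the two top alterations (levels 00, 10, 01, 11) as
Factor 2.  The interaction is tested by a nested-model F comparison between
the additive model (compound + combination) and the full factorial model,
which is unambiguous under the unbalanced designs real screens produce and
coincides with the classical interaction F in balanced designs.  Per-
combination two-sample t-tests and boxplot-ready group summaries accompany
the test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .data_io import AlterationMatrix
from .importance import ImportanceTable

__all__ = [
    "CandidatePair",
    "InteractionResult",
    "candidate_pairs",
    "logit_auc",
    "pair_long_table",
    "interaction_anova",
]

COMBINATION_LEVELS = ("00", "10", "01", "11")


@dataclass
class CandidatePair:
    """A Report-1 compound pair worth a formal interaction test."""

    compound_a: str
    compound_b: str
    mean_auc_a: float
    mean_auc_b: float
    top_alteration_a: str
    top_alteration_b: str

    @property
    def auc_difference(self) -> float:
        return abs(self.mean_auc_a - self.mean_auc_b)

    def to_dict(self) -> dict:
        return {
            "compound_a": self.compound_a,
            "compound_b": self.compound_b,
            "mean_auc_a": self.mean_auc_a,
            "mean_auc_b": self.mean_auc_b,
            "auc_difference": self.auc_difference,
            "top_alteration_a": self.top_alteration_a,
            "top_alteration_b": self.top_alteration_b,
        }


def candidate_pairs(
    report1: pd.DataFrame,
    importance_by_compound: dict[str, ImportanceTable] | None = None,
    auc_tolerance: float = 0.02,
) -> list[CandidatePair]:
    """All unordered Report-1 pairs with similar mean AUC and different tops.

    The top alteration of a compound is its most important significant
    alteration; compounds without significant alterations cannot form pairs.
    Pairs are ordered by ascending mean-AUC difference (ties by compound
    names).
    """
    tops: dict[str, str] = {}
    means: dict[str, float] = {}
    for _, row in report1.iterrows():
        compound = row["compound"]
        if importance_by_compound is not None:
            sig = importance_by_compound[compound].significant_alterations()
        else:
            sig = [s for s in str(row["significant_alterations"]).split(";") if s]
        if not sig:
            continue
        tops[compound] = sig[0]
        means[compound] = float(row["mean_auc"])
    names = sorted(tops)
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if tops[a] == tops[b]:
                continue
            if abs(means[a] - means[b]) > auc_tolerance:
                continue
            pairs.append(
                CandidatePair(
                    compound_a=a,
                    compound_b=b,
                    mean_auc_a=means[a],
                    mean_auc_b=means[b],
                    top_alteration_a=tops[a],
                    top_alteration_b=tops[b],
                )
            )
    pairs.sort(key=lambda p: (p.auc_difference, p.compound_a, p.compound_b))
    return pairs


def logit_auc(auc, eps: float = 1e-3):
    """log(a / (1 - a)) after clipping a into [eps, 1 - eps].

    Clipping bounds the influence of boundary AUCs (0 and 1 occur in
    screens) instead of producing infinities.
    """
    a = np.clip(np.asarray(auc, dtype=float), eps, 1.0 - eps)
    out = np.log(a / (1.0 - a))
    return float(out) if np.isscalar(auc) or out.ndim == 0 else out


def pair_long_table(
    responses: pd.DataFrame,
    alterations: AlterationMatrix,
    pair: CandidatePair,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Long-format (cell line, compound, combination, logit AUC) table.

    ``responses`` is cell lines x compounds.  Each cell line contributes one
    row per compound it was screened for; the combination factor is the
    joint status ``<top_a><top_b>`` of the two alterations in that cell line.
    """
    x = alterations.values
    combo = (
        x[pair.top_alteration_a].astype(str) + x[pair.top_alteration_b].astype(str)
    )
    frames = []
    for compound in (pair.compound_a, pair.compound_b):
        auc = responses[compound]
        obs = auc.notna()
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": auc.index[obs],
                    "compound": compound,
                    "combination": combo[obs].to_numpy(),
                    "logit_auc": logit_auc(auc[obs].to_numpy(), eps=eps),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class InteractionResult:
    """Two-way ANOVA interaction test for a compound pair."""

    compound_a: str
    compound_b: str
    f_interaction: float
    p_interaction: float
    df_num: float
    df_den: float
    t_tests: dict[str, float]  # combination level -> two-sample t-test p
    group_summaries: pd.DataFrame
    n_total: int

    def to_dict(self) -> dict:
        return {
            "compound_a": self.compound_a,
            "compound_b": self.compound_b,
            "f_interaction": self.f_interaction,
            "p_interaction": self.p_interaction,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "t_tests": self.t_tests,
            "n_total": self.n_total,
        }


def _group_summaries(long: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (compound, combination), grp in long.groupby(["compound", "combination"], sort=True):
        v = grp["logit_auc"].to_numpy()
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        iqr = q75 - q25
        inliers = v[(v >= q25 - 1.5 * iqr) & (v <= q75 + 1.5 * iqr)]
        rows.append(
            {
                "compound": compound,
                "combination": combination,
                "n": v.size,
                "mean": float(v.mean()),
                "median": float(med),
                "q25": float(q25),
                "q75": float(q75),
                "whisker_lo": float(inliers.min()),
                "whisker_hi": float(inliers.max()),
            }
        )
    return pd.DataFrame(rows)


def interaction_anova(
    long: pd.DataFrame,
    compound_a: str | None = None,
    compound_b: str | None = None,
) -> InteractionResult:
    """Nested-model F test of the compound x combination interaction.

    ``long`` needs columns ``logit_auc``, ``compound`` and ``combination``.
    The additive OLS model ``logit_auc ~ compound + combination`` is compared
    with the full factorial model; under a balanced design the resulting F
    equals the classical two-way ANOVA interaction F.  Raises ``ValueError``
    when a factor has a single level or when fewer than two crossed cells
    hold at least two observations.
    """
    compounds = sorted(long["compound"].unique())
    if compound_a is None or compound_b is None:
        if len(compounds) != 2:
            raise ValueError(f"expected exactly two compounds, got {compounds}")
        compound_a, compound_b = compounds
    combos = sorted(long["combination"].unique())
    if len(compounds) < 2 or len(combos) < 2:
        raise ValueError("both factors must vary to test an interaction")
    cell_counts = long.groupby(["compound", "combination"]).size()
    if (cell_counts >= 2).sum() < 2:
        raise ValueError("need at least two crossed cells with >= 2 observations")

    additive = smf.ols("logit_auc ~ C(compound) + C(combination)", data=long).fit()
    full = smf.ols("logit_auc ~ C(compound) * C(combination)", data=long).fit()
    if full.df_resid <= 0:
        raise ValueError("no residual degrees of freedom for the full model")
    comparison = anova_lm(additive, full)
    f_stat = float(comparison["F"].iloc[1])
    p_value = float(comparison["Pr(>F)"].iloc[1])
    df_num = float(comparison["df_diff"].iloc[1])
    df_den = float(full.df_resid)

    t_tests: dict[str, float] = {}
    for combination, grp in long.groupby("combination"):
        va = grp.loc[grp["compound"] == compound_a, "logit_auc"].to_numpy()
        vb = grp.loc[grp["compound"] == compound_b, "logit_auc"].to_numpy()
        if va.size >= 2 and vb.size >= 2:
            t_tests[str(combination)] = float(stats.ttest_ind(va, vb).pvalue)

    return InteractionResult(
        compound_a=compound_a,
        compound_b=compound_b,
        f_interaction=f_stat,
        p_interaction=p_value,
        df_num=df_num,
        df_den=df_den,
        t_tests=t_tests,
        group_summaries=_group_summaries(long),
        n_total=len(long),
    )
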