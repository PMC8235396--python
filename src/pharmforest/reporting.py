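"""Tabular reports over the per-compound forest results.

Report 1 lists the compounds whose concordance between observed AUCs and OOB
predictions is at least fair (lower 95% CCC bound above a threshold, default
20 on the x100 scale), in decreasing order of CCC, with mean AUC, sample
size and the significantly influential alterations in decreasing order of
importance.

Report 2 lists the alterations that significantly influence Report-1
compounds, in decreasing order of significance frequency, each with its
redundancy-cluster id, size and members (an alteration collapsed into a
cluster in the reduction is considered as important as its representative)
and the influenced compounds in decreasing order of CCC.

Ties break alphabetically (compounds in Report 1, alterations in Report 2)
so reports are deterministic given the per-drug results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .evaluation import CCCResult
from .forest import StabilityValue
from .importance import ImportanceTable
from .reduction import ClusterMap

__all__ = ["DrugModelResult", "build_report1", "build_report2", "write_text_table"]

_SEP = ";"


@dataclass
class DrugModelResult:
    """Everything the reports need about one compound's fitted model."""

    compound: str
    ccc: CCCResult
    mean_auc: float
    sample_size: int
    stability: StabilityValue
    importance: ImportanceTable
    seed: int

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "mean_auc": self.mean_auc,
            "sample_size": self.sample_size,
            "seed": self.seed,
            "stability_value": self.stability.value,
            "stability_window": self.stability.window,
            "stability_reached": self.stability.reached,
            **{f"ccc_{k}": v for k, v in self.ccc.to_dict().items()},
        }


def build_report1(results: list[DrugModelResult], threshold: float = 20.0) -> pd.DataFrame:
    """Compounds with lower CCC bound above ``threshold``, by decreasing CCC."""
    rows = []
    for res in results:
        if res.ccc.ci_lower <= threshold:
            continue
        sig = res.importance.significant_alterations()
        rows.append(
            {
                "compound": res.compound,
                "ccc": res.ccc.ccc,
                "ci_lower": res.ccc.ci_lower,
                "ci_upper": res.ccc.ci_upper,
                "label": res.ccc.label,
                "mean_auc": res.mean_auc,
                "sample_size": res.sample_size,
                "n_significant": len(sig),
                "significant_alterations": _SEP.join(sig),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "compound",
            "ccc",
            "ci_lower",
            "ci_upper",
            "label",
            "mean_auc",
            "sample_size",
            "n_significant",
            "significant_alterations",
        ],
    )
    return df.sort_values(
        ["ccc", "compound"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def build_report2(
    report1: pd.DataFrame,
    importance_by_compound: dict[str, ImportanceTable],
    clusters: ClusterMap,
) -> pd.DataFrame:
    """Alterations influencing Report-1 compounds, by significance frequency.

    Raises ``KeyError`` when a significant alteration is absent from the
    cluster map.
    """
    ccc_by_compound = dict(zip(report1["compound"], report1["ccc"]))
    influenced: dict[str, list[str]] = {}
    for compound in report1["compound"]:
        table = importance_by_compound[compound]
        for alteration in table.significant_alterations():
            influenced.setdefault(alteration, []).append(compound)
    rows = []
    for alteration, compounds in influenced.items():
        cid = clusters.cluster_of(alteration)  # KeyError if unmapped
        members = clusters.members(cid)
        by_ccc = sorted(compounds, key=lambda c: (-ccc_by_compound[c], c))
        rows.append(
            {
                "alteration": alteration,
                "significance_frequency": len(compounds),
                "cluster_id": cid,
                "cluster_size": len(members),
                "cluster_members": _SEP.join(members),
                "compounds": _SEP.join(by_ccc),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "alteration",
            "significance_frequency",
            "cluster_id",
            "cluster_size",
            "cluster_members",
            "compounds",
        ],
    )
    return df.sort_values(
        ["significance_frequency", "alteration"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def write_text_table(df: pd.DataFrame, target: str | Path) -> None:
    """Human-readable fixed-width rendering of a report."""
    Path(target).write_text(df.to_string(index=False) + "\n")
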