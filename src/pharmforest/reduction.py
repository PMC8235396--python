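"""Unsupervised predictor reduction for binary alteration matrices.

Three steps, all applied before the predictors ever see the responses so no
supervised selection bias is introduced:

1. keep alterations of known cancer driver genes;
2. drop very frequent/infrequent alterations, whose binary variance
   p(1-p) falls strictly below a threshold derived from a minimum
   proportion (default 0.05, variance threshold 0.05 x 0.95 = 0.0475);
3. collapse redundant alterations by complete-linkage hierarchical
   clustering on the distance 1 - r^2 (r = Pearson, equal to the phi
   coefficient for binary columns), cutting at 1 - 0.95^2 = 0.0975 and
   keeping the first (lowest original row index) member of each cluster.

The module also houses the frequency/power check used to justify the
minimum-proportion threshold: the power of a two-sided two-sample t-test
comparing mean response between altered and unaltered cell lines, as a
function of the alteration's relative frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AlterationMatrix, DriverGeneSet

__all__ = [
    "ALTERATION_SUFFIXES",
    "ClusterMap",
    "ReductionResult",
    "gene_of",
    "step1_driver_filter",
    "binary_variance",
    "step2_variance_filter",
    "correlation_distance",
    "step3_redundancy_clusters",
    "reduce_predictors",
    "power_of_frequency",
    "min_frequency_for_power",
]

ALTERATION_SUFFIXES = ("_MUT", "_DEL", "_AMP")

# strict "<" comparisons against derived thresholds get a small absolute
# guard so that a boundary case computed through different float paths
# (e.g. 5/100 -> 0.05*0.95) is never excluded
_FLOAT_GUARD = 1e-12


def gene_of(label: str) -> str:
    """Gene symbol of an alteration label.

    Strips the ``_MUT``/``_DEL``/``_AMP`` suffix; for variant-qualified
    tokens such as ``BRAF.V600E_MUT`` the prefix before the first ``.`` is
    the gene.  Raises ``ValueError`` for an unknown suffix.
    """
    for suffix in ALTERATION_SUFFIXES:
        if label.endswith(suffix):
            token = label[: -len(suffix)]
            return token.split(".", 1)[0] if "." in token else token
    raise ValueError(f"unknown alteration suffix: {label!r}")


def step1_driver_filter(alt: AlterationMatrix, drivers: DriverGeneSet) -> AlterationMatrix:
    """Keep alterations whose gene is in the driver set (original order)."""
    keep = [lab for lab in alt.alterations if gene_of(lab) in drivers]
    return alt.select_alterations(keep)


def binary_variance(p: float) -> float:
    """Variance p(1-p) of a binary indicator with success proportion p."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion outside [0, 1]: {p}")
    return p * (1.0 - p)


def step2_variance_filter(
    alt: AlterationMatrix, min_proportion: float = 0.05
) -> AlterationMatrix:
    """Drop alterations whose observed variance is strictly below threshold.

    The threshold is ``min_proportion * (1 - min_proportion)``; an alteration
    whose variance equals the threshold exactly is kept ("below" is strict).
    """
    threshold = binary_variance(min_proportion)
    p_obs = alt.values.to_numpy().mean(axis=0)
    var = p_obs * (1.0 - p_obs)
    keep = var >= threshold - _FLOAT_GUARD
    return alt.select_alterations([lab for lab, k in zip(alt.alterations, keep) if k])


def _phi_correlation(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of binary columns via 2x2-table counts.

    Algebraically identical to the ordinary Pearson correlation (and to the
    phi coefficient / Cramer's V for binary variables) but computed from
    integer co-occurrence counts for numerical stability.
    """
    x = values.astype(np.int64)
    n = x.shape[0]
    s = x.sum(axis=0)
    scale = s * (n - s)
    if (scale == 0).any():
        bad = int(np.flatnonzero(scale == 0)[0])
        raise ValueError(f"constant column at position {bad}: correlation undefined")
    co = x.T @ x
    num = n * co - np.outer(s, s)
    den = np.sqrt(np.outer(scale, scale).astype(float))
    return num / den


def correlation_distance(alt: AlterationMatrix | np.ndarray) -> np.ndarray:
    """Distance matrix 1 - r^2 between alteration columns.

    Symmetric with a zero diagonal, entries in [0, 1].  Raises ``ValueError``
    on a constant column (undefined correlation).
    """
    values = alt.values.to_numpy() if isinstance(alt, AlterationMatrix) else np.asarray(alt)
    r = _phi_correlation(values)
    d = 1.0 - r**2
    np.clip(d, 0.0, 1.0, out=d)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _complete_linkage_cut(dist: np.ndarray, cut: float) -> list[list[int]]:
    """Agglomerate with complete linkage, merging while min distance <= cut.

    Deterministic tie-break: among tied minimum distances the pair with the
    lexicographically smallest member indices merges first (clusters are kept
    ordered by their smallest member, so a row-major scan realises this).
    Returns clusters as sorted member-index lists, ordered by smallest member.
    """
    m = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(m)]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    while len(clusters) > 1:
        flat = int(np.argmin(d))  # row-major: first hit is lexicographic min
        i, j = divmod(flat, d.shape[0])
        if i > j:
            i, j = j, i
        if d[i, j] > cut + _FLOAT_GUARD:
            break
        merged = np.maximum(d[i], d[j])
        d[i, :] = merged
        d[:, i] = merged
        d[i, i] = np.inf
        d = np.delete(np.delete(d, j, axis=0), j, axis=1)
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
    return clusters


@dataclass
class ClusterMap:
    """Composition of the redundancy clusters found in step 3.

    Stores every pre-clustering alteration with its 1-based cluster id and
    the cluster representative (the member with the smallest original row
    index).  Cluster ids are numbered by representative order of appearance.
    """

    labels: list[str]
    cluster_ids: np.ndarray  # per label, aligned with ``labels``
    representatives: list[str]  # index c-1 -> representative of cluster c

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        if len(self.cluster_ids) != len(self.labels):
            raise ValueError("cluster ids misaligned with labels")
        if self.sizes.sum() != len(self.labels):
            raise ValueError("cluster sizes do not add up to label count")
        for cid, rep in enumerate(self.representatives, start=1):
            if rep not in self.members(cid):
                raise ValueError(f"representative {rep!r} not a member of cluster {cid}")

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_ids, minlength=self.n_clusters + 1)[1:]

    def cluster_of(self, label: str) -> int:
        try:
            return int(self.cluster_ids[self.labels.index(label)])
        except ValueError as exc:
            raise KeyError(f"alteration {label!r} absent from cluster map") from exc

    def members(self, cluster_id: int) -> list[str]:
        return [lab for lab, cid in zip(self.labels, self.cluster_ids) if cid == cluster_id]

    def to_frame(self) -> pd.DataFrame:
        reps = set(self.representatives)
        return pd.DataFrame(
            {
                "alteration": self.labels,
                "cluster_id": self.cluster_ids,
                "representative_flag": [lab in reps for lab in self.labels],
            }
        )

    def to_csv(self, target: str | Path | IO[str]) -> None:
        self.to_frame().to_csv(target, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterMap":
        reps_df = df[df["representative_flag"].astype(bool)].sort_values("cluster_id")
        return cls(
            labels=list(df["alteration"]),
            cluster_ids=df["cluster_id"].to_numpy(),
            representatives=list(reps_df["alteration"]),
        )


def step3_redundancy_clusters(
    alt: AlterationMatrix, min_correlation: float = 0.95
) -> tuple[AlterationMatrix, ClusterMap]:
    """Collapse redundant alterations by complete-linkage clustering.

    The dendrogram over the distance 1 - r^2 is cut at
    ``1 - min_correlation**2`` (merges at exactly the cut height count as
    redundant); each cluster keeps its first member (smallest original row
    index) as representative.  Returns the reduced matrix (representatives
    only, original order) and the full :class:`ClusterMap`.
    """
    cut = 1.0 - float(min_correlation) ** 2
    dist = correlation_distance(alt)
    clusters = _complete_linkage_cut(dist, cut)
    labels = alt.alterations
    cluster_ids = np.empty(len(labels), dtype=int)
    representatives: list[str] = []
    for cid, members in enumerate(clusters, start=1):
        cluster_ids[members] = cid
        representatives.append(labels[members[0]])
    cmap = ClusterMap(labels=list(labels), cluster_ids=cluster_ids, representatives=representatives)
    return alt.select_alterations(representatives), cmap


@dataclass
class ReductionResult:
    """Outcome of the full three-step reduction with derived thresholds."""

    retained: AlterationMatrix
    step1_kept: int
    step2_excluded: int
    clusters: ClusterMap
    min_proportion: float
    min_correlation: float

    @property
    def variance_threshold(self) -> float:
        return binary_variance(self.min_proportion)

    @property
    def distance_threshold(self) -> float:
        return 1.0 - self.min_correlation**2

    def params(self) -> dict:
        return {
            "min_proportion": self.min_proportion,
            "min_correlation": self.min_correlation,
            "variance_threshold": self.variance_threshold,
            "distance_threshold": self.distance_threshold,
        }


def reduce_predictors(
    alt: AlterationMatrix,
    drivers: DriverGeneSet,
    min_proportion: float = 0.05,
    min_correlation: float = 0.95,
) -> ReductionResult:
    """Run driver filter, variance filter and redundancy clustering in order."""
    if not 0.0 < min_proportion <= 0.5:
        raise ValueError(
            f"infeasible threshold: min_proportion must be in (0, 0.5], got {min_proportion}"
        )
    step1 = step1_driver_filter(alt, drivers)
    step2 = step2_variance_filter(step1, min_proportion)
    retained, cmap = step3_redundancy_clusters(step2, min_correlation)
    return ReductionResult(
        retained=retained,
        step1_kept=step1.n_alterations,
        step2_excluded=step1.n_alterations - step2.n_alterations,
        clusters=cmap,
        min_proportion=min_proportion,
        min_correlation=min_correlation,
    )


def power_of_frequency(
    freq: float,
    n: float,
    effect_size: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Power of a two-sided two-sample t-test at a given alteration frequency.

    Group sizes are ``freq * n`` altered vs ``(1 - freq) * n`` unaltered cell
    lines (continuous, following power-calculator convention) and the
    standardized mean difference is Cohen's d = ``effect_size``.  Power is
    computed from the noncentral t distribution with ``n - 2`` degrees of
    freedom and noncentrality ``d * sqrt(n1 * n2 / n)``.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError(f"frequency outside (0, 1): {freq}")
    n1 = freq * n
    n2 = (1.0 - freq) * n
    if min(n1, n2) < 2.0:
        raise ValueError(f"degenerate group size: {min(n1, n2):.2f} < 2")
    df = n1 + n2 - 2.0
    ncp = effect_size * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    return float(power)


def min_frequency_for_power(
    target_power: float = 0.80,
    n: float = 523,
    effect_size: float = 0.5,
    alpha: float = 0.05,
    grid_step: float = 0.001,
) -> float:
    """Smallest frequency on a 0.001 grid whose t-test power meets the target.

    Scans frequencies ``grid_step, 2*grid_step, ..., 0.5``; raises
    ``ValueError`` when even the balanced design (frequency 0.5) falls short.
    """
    n_steps = int(round(0.5 / grid_step))
    for k in range(1, n_steps + 1):
        freq = k * grid_step
        n1 = freq * n
        if min(n1, n - n1) < 2.0:
            continue
        if power_of_frequency(freq, n, effect_size, alpha) >= target_power:
            return round(freq, 10)
    raise ValueError(f"target power {target_power} unreachable at n={n}, d={effect_size}")
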