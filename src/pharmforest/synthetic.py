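"""Synthetic alteration/response studies with known ground truth.

The generator emulates the statistical structure the framework assumes so
every stage is testable without the real cell-line screens:

* binary alterations drawn at prevalences spanning a wide spectrum,
  including sub-threshold columns for the variance filter to remove and
  near-duplicate column groups (a prototype copied with a small per-entry
  flip probability, tuning the within-group correlation) for the redundancy
  clustering to collapse;
* a handful of columns whose genes are excluded from the driver list, so the
  driver filter has work to do;
* dose-response AUCs generated on the logit scale: per drug,
  logit(AUC) = baseline + sum of planted alteration effects + Gaussian
  noise, mapped through the inverse logit, with per-drug missing-completely-
  at-random (MCAR) masks;
* drug x alteration interactions planted as differential coefficients
  between a drug pair (+delta/2 to one drug, -delta/2 to the other), so the
  interaction ANOVA's estimand is exactly the planted differential.

Effects live on the logit scale, matching the interaction module's model;
ground truth (true coefficient matrix, influential alterations per drug,
pairs carrying differential effects, realized within-group correlations) is
returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import AlterationMatrix, DriverGeneSet, MatchedStudy, ResponseMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_alterations",
           "generate_responses", "make_study", "demo_config", "driver_gene_set"]

_SUFFIX_CYCLE = ("MUT", "DEL", "AMP")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-generating parameters; all effects are on the logit-AUC scale.

    Column layout (``n_alterations`` total): a block of general independent
    columns (planted effects must point here), then ``n_redundant_groups``
    prototype columns, then ``n_nondriver_genes`` columns whose genes are
    left off the driver list, then the near-duplicate copies of the
    prototypes (``group_size - 1`` each).
    """

    n_cell_lines: int = 400
    n_alterations: int = 60
    frequency_range: tuple[float, float] = (0.02, 0.45)
    n_redundant_groups: int = 3
    group_size: int = 2
    flip_probability: float = 0.01
    n_drugs: int = 6
    missing_fraction: float = 0.2
    effects: tuple[tuple[int, int, float], ...] = ()  # (drug, alteration, beta)
    interactions: tuple[tuple[int, int, int, float], ...] = ()  # (drug_a, drug_b, alteration, delta)
    noise_sd: float = 0.1
    baseline_range: tuple[float, float] = (1.5, 2.5)
    baselines: tuple[float, ...] | None = None
    planted_prevalence: float = 0.3
    prototype_prevalence_range: tuple[float, float] = (0.15, 0.40)
    n_nondriver_genes: int = 5

    @property
    def n_copies(self) -> int:
        return self.n_redundant_groups * (self.group_size - 1)

    @property
    def n_independent(self) -> int:
        return self.n_alterations - self.n_copies

    @property
    def n_general(self) -> int:
        return self.n_independent - self.n_redundant_groups - self.n_nondriver_genes

    def validate(self) -> None:
        if self.n_drugs < 1:
            raise ValueError("config needs at least one drug")
        if self.n_cell_lines < 10:
            raise ValueError("config needs at least 10 cell lines")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.n_general < 1:
            raise ValueError(
                "infeasible config: redundant groups and non-driver columns exceed "
                "the alteration budget"
            )
        for lo, hi, name in (
            (*self.frequency_range, "frequency_range"),
            (*self.prototype_prevalence_range, "prototype_prevalence_range"),
        ):
            if not 0.0 < lo <= hi < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability outside [0, 1]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction outside [0, 1)")
        if self.baselines is not None and len(self.baselines) != self.n_drugs:
            raise ValueError("baselines length differs from n_drugs")
        for drug, alt, _ in self.effects:
            if not 0 <= drug < self.n_drugs:
                raise ValueError(f"effect references unknown drug {drug}")
            if not 0 <= alt < self.n_general:
                raise ValueError(
                    f"effect references alteration {alt} outside the general block "
                    f"[0, {self.n_general})"
                )
        for a, b, alt, _ in self.interactions:
            if a == b or not (0 <= a < self.n_drugs and 0 <= b < self.n_drugs):
                raise ValueError(f"interaction references invalid drug pair ({a}, {b})")
            if not 0 <= alt < self.n_general:
                raise ValueError(f"interaction references alteration {alt} outside general block")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated study."""

    alteration_labels: list[str]
    drug_labels: list[str]
    beta: pd.DataFrame  # drugs x alterations, logit-scale coefficients
    baselines: dict[str, float]
    influential: dict[str, list[str]]  # drug -> alterations with nonzero beta
    interaction_pairs: list[dict]  # pairs with a differential coefficient
    group_members: list[list[str]]
    group_correlations: list[list[float]]  # prototype-vs-copy realized r
    driver_genes: list[str]
    nondriver_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "alteration_labels": self.alteration_labels,
            "drug_labels": self.drug_labels,
            "beta": {d: self.beta.loc[d].to_dict() for d in self.beta.index},
            "baselines": self.baselines,
            "influential": self.influential,
            "interaction_pairs": self.interaction_pairs,
            "group_members": self.group_members,
            "group_correlations": self.group_correlations,
            "driver_genes": self.driver_genes,
            "nondriver_genes": self.nondriver_genes,
        }


def _labels(config: SyntheticConfig) -> list[str]:
    return [f"G{i + 1:03d}_{_SUFFIX_CYCLE[i % 3]}" for i in range(config.n_alterations)]


def _pair_correlation(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def generate_alterations(
    config: SyntheticConfig, seed: int
) -> tuple[AlterationMatrix, dict]:
    """Draw the binary alteration matrix plus layout metadata.

    Independent columns are Bernoulli at prevalences sampled from
    ``frequency_range`` (effect carriers pinned at ``planted_prevalence``);
    each redundancy-group copy is its prototype with entries flipped
    independently at ``flip_probability`` (0 gives identical columns, 0.5
    approximately independent ones).  Realized within-group correlations are
    reported for the truth record.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n, p = config.n_cell_lines, config.n_alterations
    labels = _labels(config)
    effect_cols = {alt for _, alt, _ in config.effects} | {
        alt for _, _, alt, _ in config.interactions
    }

    prevalence = rng.uniform(*config.frequency_range, size=p)
    proto_start = config.n_general
    prevalence[proto_start : proto_start + config.n_redundant_groups] = rng.uniform(
        *config.prototype_prevalence_range, size=config.n_redundant_groups
    )
    for alt in effect_cols:
        prevalence[alt] = config.planted_prevalence

    x = (rng.random((n, p)) < prevalence[None, :]).astype(np.int8)

    group_members: list[list[str]] = []
    group_correlations: list[list[float]] = []
    copy_idx = config.n_independent
    for g in range(config.n_redundant_groups):
        proto = proto_start + g
        members = [labels[proto]]
        corrs: list[float] = []
        for _ in range(config.group_size - 1):
            flips = rng.random(n) < config.flip_probability
            x[:, copy_idx] = np.where(flips, 1 - x[:, proto], x[:, proto])
            members.append(labels[copy_idx])
            corrs.append(_pair_correlation(x[:, proto], x[:, copy_idx]))
            copy_idx += 1
        group_members.append(members)
        group_correlations.append(corrs)

    cell_lines = [f"CL{i + 1:04d}" for i in range(n)]
    matrix = AlterationMatrix(pd.DataFrame(x, index=cell_lines, columns=labels))
    nondriver_start = config.n_general + config.n_redundant_groups
    nondriver_genes = [
        labels[i].split("_")[0] for i in range(nondriver_start, config.n_independent)
    ]
    meta = {
        "group_members": group_members,
        "group_correlations": group_correlations,
        "nondriver_genes": nondriver_genes,
    }
    return matrix, meta


def generate_responses(
    alt: AlterationMatrix, config: SyntheticConfig, seed: int, meta: dict | None = None
) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Generate per-drug AUCs from planted logit-scale effects, with MCAR.

    For drug d and cell line i:
    ``logit(AUC) = baseline_d + x_i . beta_d + N(0, noise_sd)``; an
    interaction entry (a, b, j, delta) splits the differential symmetrically,
    ``beta_a[j] += delta/2`` and ``beta_b[j] -= delta/2``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n, p = alt.values.shape
    d = config.n_drugs
    drug_labels = [f"D{k + 1:02d}" for k in range(d)]
    labels = alt.alterations

    if config.baselines is not None:
        baselines = np.asarray(config.baselines, dtype=float)
    else:
        baselines = rng.uniform(*config.baseline_range, size=d)
    beta = np.zeros((d, p))
    for drug, alt_idx, value in config.effects:
        beta[drug, alt_idx] += value
    for a, b, alt_idx, delta in config.interactions:
        beta[a, alt_idx] += delta / 2.0
        beta[b, alt_idx] -= delta / 2.0

    x = alt.values.to_numpy().astype(float)
    logit = baselines[None, :] + x @ beta.T + rng.normal(0.0, config.noise_sd, size=(n, d))
    auc = expit(logit)
    missing = rng.random((n, d)) < config.missing_fraction
    auc[missing] = np.nan
    responses = ResponseMatrix(pd.DataFrame(auc, index=alt.cell_lines, columns=drug_labels))

    beta_df = pd.DataFrame(beta, index=drug_labels, columns=labels)
    influential = {
        drug: [lab for lab in labels if beta_df.at[drug, lab] != 0.0] for drug in drug_labels
    }
    interaction_pairs = []
    for i in range(d):
        for j in range(i + 1, d):
            diff = beta_df.iloc[i] - beta_df.iloc[j]
            nz = diff[diff != 0.0]
            if len(nz):
                interaction_pairs.append(
                    {
                        "drug_a": drug_labels[i],
                        "drug_b": drug_labels[j],
                        "differentials": nz.to_dict(),
                    }
                )
    meta = meta or {}
    nondriver = meta.get("nondriver_genes", [])
    all_genes = [lab.split("_")[0] for lab in labels]
    truth = SyntheticTruth(
        alteration_labels=list(labels),
        drug_labels=drug_labels,
        beta=beta_df,
        baselines=dict(zip(drug_labels, baselines.tolist())),
        influential=influential,
        interaction_pairs=interaction_pairs,
        group_members=meta.get("group_members", []),
        group_correlations=meta.get("group_correlations", []),
        driver_genes=sorted(set(all_genes) - set(nondriver)),
        nondriver_genes=list(nondriver),
    )
    return responses, truth


def make_study(config: SyntheticConfig, seed: int) -> tuple[MatchedStudy, SyntheticTruth]:
    """Compose alteration and response generation into a matched study.

    The two generator stages use seeds spawned deterministically from
    ``seed``; the same seed always yields byte-identical outputs.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    seed_alt, seed_resp = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    alterations, meta = generate_alterations(config, seed_alt)
    responses, truth = generate_responses(alterations, config, seed_resp, meta)
    return MatchedStudy(alterations=alterations, responses=responses), truth


def driver_gene_set(truth: SyntheticTruth) -> DriverGeneSet:
    """The driver list a synthetic study ships with (non-driver genes held out)."""
    return DriverGeneSet(frozenset(truth.driver_genes))


def demo_config() -> SyntheticConfig:
    """The default demonstration study: 400 cell lines, 60 alterations,
    6 drugs, strong planted effects for two drugs with different top
    alterations and matched baselines (the planted interaction pair), two
    moderately determined drugs, and two null drugs."""
    return SyntheticConfig(
        n_cell_lines=400,
        n_alterations=60,
        n_drugs=6,
        effects=(
            (0, 0, -2.0),
            (1, 1, -2.0),
            (2, 2, -1.5),
            (3, 3, -1.5),
        ),
        baselines=(2.2, 2.2, 1.8, 1.8, 2.0, 2.0),
    )
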