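"""Quality control for per-drug missing-response deletion.

Cell lines with a missing AUC for a compound are dropped before that
compound's forest is fitted.  Deletion perturbs the alteration variance
spectrum and the pairwise correlations that the reduction thresholds were
calibrated on, so for every drug we quantify the perturbation on the
post-reduction alteration set:

* CCC (x100) between the full-cohort binary-variance vector and the
  screened-subset variance vector;
* CCC (x100) between the full and subset squared-correlation vectors,
  paired over the strict upper triangle in row-major order;
* share of retained alterations whose subset variance falls below the
  variance threshold (percent);
* share of retained pairs whose subset |r| reaches the redundancy
  threshold, in pcm (percent mille, per hundred thousand).

Pairs involving a column that became constant in the subset have an
undefined correlation; they are excluded from the paired CCC vectors but
counted as threshold violations (a constant column is itself a maximal
variance violation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AlterationMatrix
from .evaluation import ccc
from .reduction import binary_variance

__all__ = ["MissingnessQC", "missingness_impact", "missingness_table"]

_FLOAT_GUARD = 1e-12


@dataclass
class MissingnessQC:
    """Per-drug perturbation metrics after missing-AUC deletion."""

    sample_size: int
    ccc_variances: float  # x100
    ccc_sq_correlations: float  # x100
    frac_low_variance: float  # percent of retained alterations
    frac_high_correlation: float  # pcm of retained pairs
    n_degenerate_columns: int  # constant after subsetting

    def to_dict(self) -> dict:
        return {
            "sample_size": self.sample_size,
            "ccc_variances": self.ccc_variances,
            "ccc_sq_correlations": self.ccc_sq_correlations,
            "frac_low_variance_pct": self.frac_low_variance,
            "frac_high_correlation_pcm": self.frac_high_correlation,
            "n_degenerate_columns": self.n_degenerate_columns,
        }


def _paired_ccc_x100(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(a, b):
        return 100.0  # identical distributions, including the constant case
    return 100.0 * ccc(a, b)


def _squared_correlations(x: np.ndarray) -> np.ndarray:
    """Upper-triangle (row-major) squared Pearson correlations; NaN where a
    member column is constant."""
    n, p = x.shape
    s = x.sum(axis=0).astype(np.int64)
    scale = (s * (n - s)).astype(float)
    co = (x.T.astype(np.int64) @ x.astype(np.int64)).astype(float)
    num = n * co - np.outer(s, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / np.sqrt(np.outer(scale, scale))
    iu = np.triu_indices(p, k=1)
    return (r**2)[iu]


def missingness_impact(
    retained: AlterationMatrix | np.ndarray,
    available: np.ndarray,
    min_proportion: float = 0.05,
    min_correlation: float = 0.95,
    min_samples: int = 10,
) -> MissingnessQC:
    """Quantify how one drug's missing-AUC deletion perturbs the predictors.

    ``available`` is a boolean mask over cell lines, True where the drug's
    AUC was observed.  Raises ``ValueError`` when fewer than ``min_samples``
    cell lines remain.
    """
    x = retained.values.to_numpy() if isinstance(retained, AlterationMatrix) else np.asarray(retained)
    available = np.asarray(available, dtype=bool)
    if available.shape[0] != x.shape[0]:
        raise ValueError("availability mask misaligned with cell lines")
    xs = x[available]
    ns = xs.shape[0]
    if ns < min_samples:
        raise ValueError(f"screened subset smaller than {min_samples} cell lines ({ns})")

    var_threshold = binary_variance(min_proportion)
    p_full = x.mean(axis=0)
    p_sub = xs.mean(axis=0)
    var_full = p_full * (1.0 - p_full)
    var_sub = p_sub * (1.0 - p_sub)
    ccc_var = _paired_ccc_x100(var_full, var_sub)
    frac_low = 100.0 * float(np.mean(var_sub < var_threshold - _FLOAT_GUARD))

    r2_full = _squared_correlations(x)
    r2_sub = _squared_correlations(xs)
    degenerate_pair = np.isnan(r2_sub) | np.isnan(r2_full)
    valid = ~degenerate_pair
    if valid.sum() >= 3:
        ccc_sq = _paired_ccc_x100(r2_full[valid], r2_sub[valid])
    else:
        ccc_sq = float("nan")
    violating = np.zeros_like(r2_sub, dtype=bool)
    violating[valid] = r2_sub[valid] >= min_correlation**2 - _FLOAT_GUARD
    violating |= degenerate_pair
    frac_high = 1e5 * float(np.mean(violating)) if violating.size else 0.0

    return MissingnessQC(
        sample_size=ns,
        ccc_variances=ccc_var,
        ccc_sq_correlations=ccc_sq,
        frac_low_variance=frac_low,
        frac_high_correlation=frac_high,
        n_degenerate_columns=int((xs.std(axis=0) == 0).sum()),
    )


def missingness_table(
    retained: AlterationMatrix,
    responses: pd.DataFrame,
    min_proportion: float = 0.05,
    min_correlation: float = 0.95,
) -> pd.DataFrame:
    """One QC row per compound; ``responses`` is cell lines x compounds."""
    rows = []
    for compound in responses.columns:
        mask = responses[compound].notna().to_numpy()
        qc = missingness_impact(
            retained, mask, min_proportion=min_proportion, min_correlation=min_correlation
        )
        rows.append({"compound": compound, **qc.to_dict()})
    return pd.DataFrame(rows)
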