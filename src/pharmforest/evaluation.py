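"""Concordance correlation coefficient (CCC) between observed and predicted
AUCs, its confidence interval, and the benchmark classification.

The CCC between two vectors y and yhat is

    CCC = 2 cov(y, yhat) / [ var(y) + var(yhat) + (mean(y) - mean(yhat))^2 ]

with population (divide-by-n) moments throughout; mixing 1/n and 1/(n-1)
conventions would break the [-1, 1] bound because the squared mean shift does
not rescale.  The CCC is 1 only when the two vectors are identical, so it is
more conservative than the Pearson correlation (|CCC| <= |r| always, with
equality when means and variances match).

For reporting the CCC is multiplied by 100 and binned: <= 0 "none",
(0, 20] "poor", (20, 40] "fair", (40, 60] "moderate", (60, 80] "substantial",
(80, 100] "excellent".  A model is "at least fair" when the lower 95% bound
exceeds 20.  The confidence interval is Lin's asymptotic interval on the
Fisher-z transform of the CCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CCCResult", "ccc", "ccc_interval", "classify_ccc", "evaluate_concordance"]

_BENCHMARKS = ((0.0, "none"), (20.0, "poor"), (40.0, "fair"), (60.0, "moderate"),
               (80.0, "substantial"), (100.0, "excellent"))


def _moments(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float, float, float]:
    my, mh = y.mean(), yhat.mean()
    vy = float(np.mean((y - my) ** 2))
    vh = float(np.mean((yhat - mh) ** 2))
    cov = float(np.mean((y - my) * (yhat - mh)))
    return my, mh, vy, vh, cov


def _check_pair(y, yhat, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-d vectors of equal length")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {y.size}")
    if np.isnan(y).any() or np.isnan(yhat).any():
        raise ValueError("missing values in CCC input")
    return y, yhat


def ccc(y, yhat) -> float:
    """Concordance correlation coefficient, in [-1, 1]."""
    y, yhat = _check_pair(y, yhat)
    my, mh, vy, vh, cov = _moments(y, yhat)
    denom = vy + vh + (my - mh) ** 2
    if denom == 0.0:
        raise ValueError("degenerate CCC: both vectors constant with equal means")
    return float(2.0 * cov / denom)


def ccc_interval(y, yhat, level: float = 0.95) -> tuple[float, float]:
    """Lin's asymptotic confidence interval for the CCC, natural scale.

    The CCC is Fisher-z transformed, its asymptotic standard error (which
    involves the Pearson correlation r and the standardized mean shift
    u = (mean(y) - mean(yhat)) / sqrt(sd(y) sd(yhat))) is evaluated at the
    estimates, and the z-scale bounds are transformed back with tanh.
    Requires n >= 4 and |CCC| < 1.
    """
    y, yhat = _check_pair(y, yhat, min_n=4)
    n = y.size
    my, mh, vy, vh, cov = _moments(y, yhat)
    rho_c = ccc(y, yhat)
    if abs(rho_c) >= 1.0:
        raise ValueError("degenerate CCC interval: |CCC| = 1")
    if vy == 0.0 or vh == 0.0:
        raise ValueError("degenerate CCC interval: a vector is constant")
    r = cov / np.sqrt(vy * vh)
    if r == 0.0:
        raise ValueError("Pearson correlation is zero; asymptotic CI undefined")
    u2 = (my - mh) ** 2 / np.sqrt(vy * vh)
    one_m = 1.0 - rho_c**2
    var_z = (
        (1.0 - r**2) * rho_c**2 / (one_m * r**2)
        + 2.0 * rho_c**3 * (1.0 - rho_c) * u2 / (r * one_m**2)
        - rho_c**4 * u2**2 / (2.0 * r**2 * one_m**2)
    ) / (n - 2.0)
    se_z = np.sqrt(max(var_z, 1e-300))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(rho_c)
    return float(np.tanh(z - zcrit * se_z)), float(np.tanh(z + zcrit * se_z))


def classify_ccc(value_x100: float) -> str:
    """Benchmark class of a CCC on the x100 scale."""
    if not -100.0 - 1e-9 <= value_x100 <= 100.0 + 1e-9:
        raise ValueError(f"CCC x100 outside [-100, 100]: {value_x100}")
    for upper, label in _BENCHMARKS:
        if value_x100 <= upper:
            return label
    return "excellent"


@dataclass
class CCCResult:
    """CCC and its confidence bounds on the x100 reporting scale."""

    ccc: float
    ci_lower: float
    ci_upper: float
    n: int
    label: str

    @property
    def at_least_fair(self) -> bool:
        """Lower confidence bound above the fair threshold of 20."""
        return self.ci_lower > 20.0

    def to_dict(self) -> dict:
        return {
            "ccc": self.ccc,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n": self.n,
            "label": self.label,
        }


def evaluate_concordance(y, yhat, level: float = 0.95) -> CCCResult:
    """CCC of observed vs predicted AUCs with CI and benchmark label (x100)."""
    value = ccc(y, yhat)
    lo, hi = ccc_interval(y, yhat, level=level)
    return CCCResult(
        ccc=100.0 * value,
        ci_lower=100.0 * lo,
        ci_upper=100.0 * hi,
        n=int(np.asarray(y).size),
        label=classify_ccc(100.0 * value),
    )
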