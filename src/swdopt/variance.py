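"""GLS variance of the treatment-effect estimator and Wald-test power.

The outcome model is a linear mixed model for repeated cross-sectional
continuous outcomes with categorical period effects and cluster-period
random effects whose correlation across periods follows one of three
structures: discrete-time decay (correlation rho * r**|j - j'|),
block-exchangeable (rho * r for any two distinct periods) or exchangeable
(rho throughout).

Variances are computed on cluster-period means, which is exact for this
model, with the total outcome variance normalized to 1 so that effect
sizes are directly standardized: the cluster-period random-effect variance
is rho and the residual variance 1 - rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.stats import norm

from .design import Design

__all__ = [
    "STRUCTURES",
    "CorrelationSpec",
    "PowerSpec",
    "NotEstimableError",
    "cluster_covariance",
    "treatment_variance",
    "is_estimable",
    "power",
]

STRUCTURES = ("discrete_time_decay", "block_exchangeable", "exchangeable")

#: Reciprocal-condition-number floor for the reduced period-effect
#: information matrix; below this the design is declared non-estimable.
RCOND_TOL = 1e-10
#: Positivity floor for the treatment-effect information scalar, relative
#: to the raw treatment information (plus a tiny absolute floor).
SCALAR_REL_TOL = 1e-9
SCALAR_ABS_TOL = 1e-12


class NotEstimableError(ValueError):
    """The treatment effect is not estimable under this design."""


@dataclass(frozen=True)
class CorrelationSpec:
    """Within-cluster correlation structure and its parameters.

    ``icc`` (rho) is the within-period intracluster correlation; ``cac``
    (r) the cluster autocorrelation, ignored for the exchangeable
    structure. Decay with ``cac=1`` coincides with exchangeable.
    """

    icc: float
    cac: float = 1.0
    structure: str = "discrete_time_decay"

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown correlation structure {self.structure!r}; "
                f"expected one of {STRUCTURES}"
            )
        if not 0.0 <= self.icc < 1.0:
            raise ValueError(f"icc must be in [0, 1), got {self.icc}")
        if not 0.0 <= self.cac <= 1.0:
            raise ValueError(f"cac must be in [0, 1], got {self.cac}")

    def period_correlation(self, periods: np.ndarray) -> np.ndarray:
        """Cluster-period random-effect correlation matrix for the given
        (0-based) period labels; gaps widen the lag under decay."""
        periods = np.asarray(periods, dtype=float)
        lags = np.abs(periods[:, None] - periods[None, :])
        if self.structure == "discrete_time_decay":
            return self.cac**lags
        if self.structure == "block_exchangeable":
            return np.where(lags == 0, 1.0, self.cac)
        return np.ones_like(lags)


@dataclass(frozen=True)
class PowerSpec:
    """Effect size, test size and the minimum acceptable power."""

    effect_size: float
    alpha: float = 0.05
    min_power: float = 0.80

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.min_power < 1.0:
            raise ValueError(f"min_power must be in (0, 1), got {self.min_power}")


def cluster_covariance(
    design: Design, sequence: int, corr: CorrelationSpec
) -> np.ndarray:
    """Covariance matrix of the measured cluster-period means for one
    cluster on the given (1-based) sequence.

    Diagonal entries are ``rho + (1 - rho)/m``; off-diagonals are ``rho``
    times the structure's correlation at the original period lag.
    """
    if not 1 <= sequence <= design.n_sequences:
        raise IndexError(f"sequence index {sequence} out of range")
    periods = np.flatnonzero(design.observed[sequence - 1])
    if periods.size == 0:
        raise ValueError(f"sequence {sequence} has no observed periods")
    return _mean_covariance(periods, design.cluster_period_size, corr)


def _mean_covariance(
    periods: np.ndarray, m: int, corr: CorrelationSpec
) -> np.ndarray:
    tau2 = corr.icc
    sigma2 = 1.0 - corr.icc
    cov = tau2 * corr.period_correlation(periods)
    cov[np.diag_indices_from(cov)] += sigma2 / m
    return cov


def _sequence_terms(
    treatment_row: np.ndarray,
    observed_row: np.ndarray,
    m: int,
    n_periods: int,
    corr: CorrelationSpec,
):
    """Per-cluster information pieces for one sequence, or None if the
    sequence has no measured periods.

    Returns ``(a, b, c)`` with ``a = X'V^-1 X`` (scalar), ``b = Z'V^-1 X``
    and ``c = Z'V^-1 Z`` scattered into full ``T``-period coordinates.
    """
    periods = np.flatnonzero(observed_row)
    if periods.size == 0:
        return None
    cov = _mean_covariance(periods, m, corr)
    x = treatment_row[periods].astype(float)
    factor = cho_factor(cov)
    vinv_x = cho_solve(factor, x)
    vinv = cho_solve(factor, np.eye(periods.size))
    a = float(x @ vinv_x)
    b = np.zeros(n_periods)
    b[periods] = vinv_x
    c = np.zeros((n_periods, n_periods))
    c[np.ix_(periods, periods)] = vinv
    return a, b, c


def _variance_from_information(
    a: float, b: np.ndarray, c: np.ndarray, period_idx: np.ndarray
) -> float:
    """Invert the profiled information; raises NotEstimableError on a
    (near-)singular period-effect block or a non-positive scalar."""
    if period_idx.size == 0:
        raise NotEstimableError("design has no observed periods")
    c_red = c[np.ix_(period_idx, period_idx)]
    b_red = b[period_idx]
    try:
        factor = cho_factor(c_red)
    except LinAlgError as exc:
        raise NotEstimableError("period-effect information is singular") from exc
    if 1.0 / np.linalg.cond(c_red) < RCOND_TOL:
        raise NotEstimableError("period-effect information is ill-conditioned")
    scalar = a - float(b_red @ cho_solve(factor, b_red))
    if scalar <= max(SCALAR_ABS_TOL, SCALAR_REL_TOL * abs(a)):
        raise NotEstimableError(
            "treatment effect is confounded with period effects"
        )
    return 1.0 / scalar


def _assemble_information(design: Design, corr: CorrelationSpec):
    n_periods = design.n_periods
    a_total = 0.0
    b_total = np.zeros(n_periods)
    c_total = np.zeros((n_periods, n_periods))
    for s in range(design.n_sequences):
        terms = _sequence_terms(
            design.treatment[s], design.observed[s], design.cluster_period_size,
            n_periods, corr,
        )
        if terms is None:
            continue
        n_s = design.clusters_per_sequence[s]
        a_total += n_s * terms[0]
        b_total += n_s * terms[1]
        c_total += n_s * terms[2]
    period_idx = np.flatnonzero(design.observed.any(axis=0))
    return a_total, b_total, c_total, period_idx


def treatment_variance(design: Design, corr: CorrelationSpec) -> float:
    """GLS variance of the treatment-effect estimator, on the standardized
    outcome scale (total variance 1).

    Period effects are categorical; periods with no measurements in any
    sequence are dropped from the period-effect parameterization (they
    carry no information), while original period labels are preserved
    inside the decay correlation.
    """
    a, b, c, period_idx = _assemble_information(design, corr)
    return _variance_from_information(a, b, c, period_idx)


def is_estimable(design: Design, corr: CorrelationSpec) -> bool:
    """True iff the design yields a finite, positive treatment-effect
    variance at the module's numerical tolerances."""
    if design.n_observed_cells == 0:
        return False
    try:
        treatment_variance(design, corr)
    except NotEstimableError:
        return False
    return True


def power(design: Design, corr: CorrelationSpec, pw: PowerSpec) -> float:
    """Asymptotic power of the two-sided Wald test, using standard normal
    critical values: Phi(effect / sqrt(var) - z_{1 - alpha/2})."""
    var = treatment_variance(design, corr)
    z_crit = norm.ppf(1.0 - pw.alpha / 2.0)
    return float(norm.cdf(pw.effect_size / np.sqrt(var) - z_crit))
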