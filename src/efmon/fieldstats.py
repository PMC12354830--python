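"""Validation statistics for paired monitoring series.

Spearman rank correlations between per-period series, Fisher r-to-z
comparison of two correlation coefficients (independent-samples form), and
an OLS slope with its t-test p-value. Two-tailed throughout, alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ContractError


@dataclass
class ValidationSeries:
    period_ids: list[str]
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.size != self.values_b.size:
            raise ContractError("paired series must have equal length")

    @property
    def n(self) -> int:
        return self.values_a.size


@dataclass
class CorrelationComparison:
    rho_1: float
    n_1: int
    rho_2: float
    n_2: int
    z_score: float
    p_value: float


def spearman(series: ValidationSeries, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), two-tailed p.

    The p-value uses the t-approximation by default; ``exact=True`` switches
    to a permutation test (feasible only at small n).
    """
    if series.n < 4:
        raise ContractError("need n >= 4 for a correlation test")
    if np.ptp(series.values_a) == 0 or np.ptp(series.values_b) == 0:
        raise ContractError("correlation undefined for a constant series")
    if exact:
        res = stats.permutation_test(
            (series.values_a, series.values_b),
            lambda x, y: stats.spearmanr(x, y).statistic,
            permutation_type="pairings",
            n_resamples=10000,
        )
        rho = stats.spearmanr(series.values_a, series.values_b).statistic
        return float(rho), float(res.pvalue)
    rho, p = stats.spearmanr(series.values_a, series.values_b)
    return float(rho), float(p)


def fisher_z_compare(rho_1: float, n_1: int, rho_2: float, n_2: int) -> CorrelationComparison:
    """Compare two independent correlations through the r-to-z transform.

    z = (atanh(rho_1) - atanh(rho_2)) / sqrt(1/(n_1 - 3) + 1/(n_2 - 3)),
    with a two-tailed normal p-value.
    """
    for rho, n in ((rho_1, n_1), (rho_2, n_2)):
        if abs(rho) >= 1:
            raise ContractError("|rho| must be < 1 for the z transform")
        if n <= 3:
            raise ContractError("need n > 3 per sample")
    z = (np.arctanh(rho_1) - np.arctanh(rho_2)) / np.sqrt(
        1.0 / (n_1 - 3) + 1.0 / (n_2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(rho_1, n_1, rho_2, n_2, float(z), float(p))


def ols_slope(series: ValidationSeries) -> tuple[float, float]:
    """Least-squares slope of values_a on values_b with its t-test p-value."""
    if series.n < 3:
        raise ContractError("need n >= 3 for a slope test")
    if np.ptp(series.values_b) == 0:
        raise ContractError("zero variance in predictor")
    res = stats.linregress(series.values_b, series.values_a)
    return float(res.slope), float(res.pvalue)


def shapiro_normality(values: np.ndarray) -> tuple[float, float]:
    """Advisory Shapiro-Wilk check; the pipeline always reports Spearman."""
    stat, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(stat), float(p)


def validation_report(
    sensor1: np.ndarray,
    sensor2: np.ndarray,
    malaise1: np.ndarray,
    malaise2: np.ndarray,
    period_ids: list[str] | None = None,
) -> dict:
    """All pairwise statistics for one variable (counts or biomass)."""
    ids = period_ids or [str(i) for i in range(len(sensor1))]

    def pair(a, b):
        s = ValidationSeries(ids, np.asarray(a, float), np.asarray(b, float))
        rho, rho_p = spearman(s)
        beta, beta_p = ols_slope(s)
        return {"rho": rho, "rho_p": rho_p, "beta": beta, "beta_p": beta_p}

    report = {
        "site1_sensor_vs_malaise": pair(sensor1, malaise1),
        "site2_sensor_vs_malaise": pair(sensor2, malaise2),
        "sensor_vs_sensor": pair(sensor1, sensor2),
        "malaise_vs_malaise": pair(malaise1, malaise2),
    }
    n = len(ids)
    cmp_ = fisher_z_compare(
        report["sensor_vs_sensor"]["rho"], n, report["malaise_vs_malaise"]["rho"], n
    )
    report["fisher_z"] = {"z": cmp_.z_score, "p": cmp_.p_value}
    return report
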