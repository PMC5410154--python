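"""Spearman-Karber median-lethal-dose estimation.

The LD50 assay design is a serial dilution: the top venom concentration is
diluted by a constant factor (two-fold in practice) to obtain the lower
doses, and mortality is recorded per dose group after a fixed observation
window. The Spearman-Karber estimator integrates the empirical tolerance
distribution on the log-dose scale and needs no parametric dose-response
model, which makes it the standard choice for small fixed-design assays.

With ascending log10 doses x_1..x_k at constant spacing d and observed
mortality proportions p_i, the classical estimator is

    log10 LD50 = x_k + d/2 - d * sum_i p_i

which equals the trapezoid integral sum_i (p_{i+1}-p_i)(x_i+x_{i+1})/2
once the series is completed with p = 0 below the lowest dose and p = 1
above the highest. The trapezoid form is used here because it also covers
unequal log spacing. When the observed mortality does not bracket 0 and 1
the completion is an extrapolation and a warning is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

from venomont.datatypes import DoseResponseTable, ValidationError


@dataclass
class Ld50Estimate:
    ld50: float  # mg/kg
    log10_se: float
    warnings: list[str] = field(default_factory=list)


def design_dilution_series(
    top_dose: float, n_doses: int = 5, factor: float = 2.0
) -> np.ndarray:
    """Doses top_dose / factor**k for k = 0..n_doses-1 (descending)."""
    if top_dose <= 0:
        raise ValidationError("top_dose must be positive")
    if n_doses < 2:
        raise ValidationError("need at least 2 doses")
    if factor <= 1:
        raise ValidationError("dilution factor must be > 1")
    return top_dose / factor ** np.arange(n_doses)


def monotone_adjust(p: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Pool-adjacent-violators isotonic regression of mortality proportions.

    Enforces non-decreasing mortality with increasing dose (``p`` must be
    ordered by ascending dose), weighted by group size. Off by default in
    :func:`spearman_karber_ld50`; enable via ``isotonic=True``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("proportions must lie in [0, 1]")
    res = isotonic_regression(p, weights=weights, increasing=True)
    return np.asarray(res.x)


def spearman_karber_ld50(
    table: DoseResponseTable, isotonic: bool = False, trim: float = 0.0
) -> Ld50Estimate:
    """Untrimmed (or trimmed) Spearman-Karber LD50 with binomial SE.

    Parameters
    ----------
    table
        Dose series with group sizes and deaths; any strictly monotone
        dose order is accepted.
    isotonic
        Apply pool-adjacent-violators smoothing to non-monotone mortality
        before estimation.
    trim
        Symmetric trimming fraction in [0, 0.1]; 0 gives the classical
        untrimmed estimator.

    Returns the LD50 on the dose scale (scale-equivariant: multiplying all
    doses by c multiplies the estimate by c) plus the standard error of
    log10 LD50 from the binomial Spearman-Karber variance
    sum_i p_i (1-p_i) / (n_i - 1) * d_i^2, available when all groups have
    more than one animal.
    """
    if len(table.doses) < 2:
        raise ValidationError("need at least 2 doses")
    if not 0.0 <= trim <= 0.1:
        raise ValidationError("trim must be in [0, 0.1]")
    order = np.argsort(table.doses)
    x = np.log10(table.doses[order])
    n = table.n_per_group[order]
    p = table.proportions[order]
    warnings: list[str] = []

    if np.all(p == 0) or np.all(p == 1):
        raise ValidationError("LD50 outside tested range: mortality never crosses 50%")

    spacings = np.diff(x)
    d = float(np.mean(spacings))
    if np.ptp(spacings) > 1e-6:
        warnings.append(
            "unequal log-dose spacing: using trapezoid generalization of Spearman-Karber"
        )
    if isotonic:
        p = monotone_adjust(p, weights=n)
    elif np.any(np.diff(p) < 0):
        warnings.append("non-monotone mortality; consider isotonic=True")

    if trim > 0:
        p = np.clip((p - trim) / (1 - 2 * trim), 0.0, 1.0)

    # Complete the tolerance distribution beyond the tested range.
    xe = np.concatenate(([x[0] - d], x, [x[-1] + d]))
    pe = np.concatenate(([0.0], p, [1.0]))
    if p[0] > 0:
        warnings.append(
            f"lowest dose mortality {p[0]:.2f} > 0: assuming 0% mortality one dilution below"
        )
    if p[-1] < 1:
        warnings.append(
            f"highest dose mortality {p[-1]:.2f} < 1: assuming 100% mortality one dilution above"
        )

    # Trapezoid integral of x over the empirical tolerance CDF.
    log_ld50 = float(np.sum(np.diff(pe) * (xe[:-1] + xe[1:]) / 2.0))

    if np.all(n > 1):
        var = float(np.sum(p * (1 - p) / (n - 1)) * d**2)
        se = float(np.sqrt(var))
    else:
        se = float("nan")
        warnings.append("groups of size 1: standard error unavailable")

    ld50 = float(10**log_ld50)
    lo, hi = float(table.doses.min()), float(table.doses.max())
    if not (lo <= ld50 <= hi):
        warnings.append(f"estimate {ld50:.4g} outside tested dose range [{lo:.4g}, {hi:.4g}]")
    return Ld50Estimate(ld50=ld50, log10_se=se, warnings=warnings)
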