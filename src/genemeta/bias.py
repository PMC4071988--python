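"""Small-study / publication-bias diagnostics.

Egger's test regresses the standardised effect (theta/se) on precision
(1/se) by ordinary least squares and t-tests the intercept against zero on
k-2 degrees of freedom; a funnel that is symmetric about the pooled effect
yields an intercept near zero.  Begg's test is the Kendall rank correlation
between variance-standardised deviates and sampling variances.  Both need
at least three studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import kendalltau, norm
from scipy.stats import t as t_dist

from .errors import InsufficientStudiesError
from .types import Z975, EffectEstimate

__all__ = ["egger_test", "begg_test", "funnel_data", "EggerResult", "BeggResult", "FunnelPoint", "FunnelData"]

#: At or below this k, Begg's p is an exact permutation tail probability.
BEGG_EXACT_MAX_K = 8


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    t_statistic: float
    df: int
    p_value: float
    slope: float


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    p_value: float
    exact: bool


@dataclass(frozen=True)
class FunnelPoint:
    x: float  # log odds ratio
    y: float  # standard error (plotted on an inverted axis by convention)
    study_id: str | None = None


@dataclass(frozen=True)
class FunnelData:
    points: list[FunnelPoint]
    center: float                 # pooled (fixed-effects) log OR reference line
    se_grid: np.ndarray
    lower: np.ndarray             # pseudo-95%-CI bounds over the se grid
    upper: np.ndarray


def _require_k(effects, k_min: int, what: str) -> None:
    if len(effects) < k_min:
        raise InsufficientStudiesError(
            f"{what} requires at least {k_min} studies, got {len(effects)}"
        )


def egger_test(effects: list[EffectEstimate]) -> EggerResult:
    """Egger's weighted-regression asymmetry test.

    OLS of z_i = theta_i/se_i on precision_i = 1/se_i; the intercept
    measures funnel asymmetry and is tested with Student's t on k-2 df.
    """
    _require_k(effects, 3, "Egger's test")
    k = len(effects)
    x = np.array([1.0 / e.se for e in effects])
    y = np.array([e.log_or / e.se for e in effects])
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise InsufficientStudiesError("all studies have identical precision; Egger regression is degenerate")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    df = k - 2
    s2 = float((resid**2).sum()) / df
    se_int = math.sqrt(s2 * (1.0 / k + xm * xm / sxx))
    t_stat = intercept / se_int
    p = float(2.0 * t_dist.sf(abs(t_stat), df))
    return EggerResult(intercept, se_int, t_stat, df, p, slope)


def _standardised_deviates(effects: list[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    theta_hat = float((w * [e.log_or for e in effects]).sum()) / float(w.sum())
    v_star = v - 1.0 / float(w.sum())
    t = (np.array([e.log_or for e in effects]) - theta_hat) / np.sqrt(v_star)
    return t, v


def _tau_b(x, y) -> float:
    return float(kendalltau(x, y).statistic)


def begg_test(effects: list[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank correlation test.

    Kendall's tau (tau-b for ties) between the variance-standardised
    deviates from the fixed-effects pooled estimate and the sampling
    variances.  p is an exact permutation tail for k <= 8, else the normal
    approximation on the Kendall score with continuity correction.
    """
    _require_k(effects, 3, "Begg's test")
    t, v = _standardised_deviates(effects)
    tau = _tau_b(t, v)
    k = len(effects)
    if k <= BEGG_EXACT_MAX_K:
        hits = total = 0
        for perm in permutations(range(k)):
            total += 1
            if abs(_tau_b(t[list(perm)], v)) >= abs(tau) - 1e-12:
                hits += 1
        return BeggResult(tau, hits / total, exact=True)
    # Normal approximation on the Kendall score with continuity correction.
    concordant_minus_discordant = 0
    for i in range(k):
        for j in range(i + 1, k):
            concordant_minus_discordant += int(np.sign((t[i] - t[j]) * (v[i] - v[j])))
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    z = max(0.0, abs(concordant_minus_discordant) - 1.0) / math.sqrt(var_s)
    return BeggResult(tau, float(2.0 * norm.sf(z)), exact=False)


def funnel_data(
    effects: list[EffectEstimate],
    study_ids: list[str] | None = None,
    n_grid: int = 50,
) -> FunnelData:
    """Coordinates for a funnel plot: one point per study plus the pooled
    reference line and 95% pseudo-confidence bounds over a grid of SEs.

    ``n_grid=0`` returns the points with empty bounds.  Rendering (and the
    conventional inverted SE axis) is left to the caller.
    """
    _require_k(effects, 1, "funnel coordinates")
    ids = study_ids or [None] * len(effects)
    points = [FunnelPoint(e.log_or, e.se, sid) for e, sid in zip(effects, ids)]
    if len(effects) == 1:
        center = effects[0].log_or
    else:
        w = np.array([1.0 / e.variance for e in effects])
        center = float((w * np.array([e.log_or for e in effects])).sum() / w.sum())
    se_grid = np.linspace(0.0, 1.1 * max(e.se for e in effects), max(0, n_grid))
    return FunnelData(
        points=points,
        center=center,
        se_grid=se_grid,
        lower=center - Z975 * se_grid,
        upper=center + Z975 * se_grid,
    )
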