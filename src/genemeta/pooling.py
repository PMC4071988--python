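"""Cross-study synthesis.

Fixed-effects pooling is Mantel-Haenszel (with the Robins-Breslow-Greenland
variance for the pooled log odds ratio) or inverse-variance; random effects
use the DerSimonian-Laird moment estimator of the between-study variance.
Model choice follows the heterogeneity gate: random effects only when
Cochran's Q is significant at the configured alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import chi2

from .errors import InsufficientStudiesError, UndefinedEffectError, ValidationError
from .io import validate_dataset
from .stats import build_contrast, hwe_test, odds_ratio, quality_score
from .types import (
    EffectEstimate,
    GeneticModel,
    HeterogeneityResult,
    HWEResult,
    MetaConfig,
    PooledResult,
    PoolingMethod,
    QualityScore,
    SNPDataset,
    TwoByTwoTable,
)

__all__ = [
    "cochran_q",
    "pool_mantel_haenszel",
    "pool_inverse_variance",
    "select_model",
    "meta_analyze",
    "leave_one_out",
    "MetaAnalysisResult",
]


def _require_k(effects, k_min: int, what: str) -> None:
    if len(effects) < k_min:
        raise InsufficientStudiesError(
            f"{what} requires at least {k_min} studies, got {len(effects)}"
        )


def cochran_q(effects: list[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q about the inverse-variance fixed pooled log odds ratio.

    Also returns I-squared = max(0, (Q - df)/Q) and the DerSimonian-Laird
    moment estimate tau^2 = max(0, (Q - df)/(sum(w) - sum(w^2)/sum(w))).
    """
    _require_k(effects, 2, "heterogeneity testing")
    w = [1.0 / e.variance for e in effects]
    sw = sum(w)
    theta_hat = sum(wi * e.log_or for wi, e in zip(w, effects)) / sw
    q = sum(wi * (e.log_or - theta_hat) ** 2 for wi, e in zip(w, effects))
    df = len(effects) - 1
    p = float(chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    denom = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_value=p, i_squared=i2, tau_squared=tau2)


def pool_mantel_haenszel(
    tables: list[TwoByTwoTable],
    cc=None,
    model: GeneticModel | None = None,
) -> PooledResult:
    """Mantel-Haenszel fixed-effects pooled odds ratio over stratified 2x2 tables.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the SE of its log is the
    Robins-Breslow-Greenland variance.  MH works on the raw cell counts, so
    no continuity correction is applied to the pooled estimate itself; the
    attached heterogeneity statistic is computed from the per-table Woolf
    effects (using ``cc``, default halves-when-zero).
    """
    _require_k(tables, 2, "Mantel-Haenszel pooling")
    if any(t.n <= 0 for t in tables):
        raise ValidationError("every stratum must have a positive total")
    R = sum(t.a * t.d / t.n for t in tables)
    S = sum(t.b * t.c / t.n for t in tables)
    if S == 0 or R == 0:
        raise UndefinedEffectError("Mantel-Haenszel odds ratio undefined (zero cross-product sum)")
    log_or = math.log(R / S)
    # Robins-Breslow-Greenland variance of log(OR_MH).
    sum_pr = sum((t.a + t.d) / t.n * (t.a * t.d / t.n) for t in tables)
    sum_ps_qr = sum(
        ((t.a + t.d) / t.n) * (t.b * t.c / t.n) + ((t.b + t.c) / t.n) * (t.a * t.d / t.n)
        for t in tables
    )
    sum_qs = sum((t.b + t.c) / t.n * (t.b * t.c / t.n) for t in tables)
    var = sum_pr / (2 * R * R) + sum_ps_qr / (2 * R * S) + sum_qs / (2 * S * S)
    estimate = EffectEstimate.from_log_or(log_or, math.sqrt(var))
    from .types import ContinuityCorrection

    cc = ContinuityCorrection.HALVES_WHEN_ZERO if cc is None else cc
    het = cochran_q([odds_ratio(t, cc) for t in tables])
    return PooledResult(
        method=PoolingMethod.MANTEL_HAENSZEL_FIXED,
        estimate=estimate,
        heterogeneity=het,
        k=len(tables),
        model=model,
    )


def pool_inverse_variance(
    effects: list[EffectEstimate],
    random: bool = False,
    model: GeneticModel | None = None,
) -> PooledResult:
    """Inverse-variance pooled log odds ratio, fixed or DerSimonian-Laird random.

    Fixed weights are 1/se^2; random weights 1/(se^2 + tau^2) with the DL
    tau^2.  When Q <= df, tau^2 is 0 and the two coincide.
    """
    _require_k(effects, 2, "inverse-variance pooling")
    het = cochran_q(effects)
    tau2 = het.tau_squared if random else 0.0
    w = [1.0 / (e.variance + tau2) for e in effects]
    sw = sum(w)
    theta = sum(wi * e.log_or for wi, e in zip(w, effects)) / sw
    estimate = EffectEstimate.from_log_or(theta, math.sqrt(1.0 / sw))
    return PooledResult(
        method=(
            PoolingMethod.DERSIMONIAN_LAIRD_RANDOM
            if random
            else PoolingMethod.INVERSE_VARIANCE_FIXED
        ),
        estimate=estimate,
        heterogeneity=het,
        k=len(effects),
        model=model,
    )


def select_model(het: HeterogeneityResult, cfg: MetaConfig) -> PoolingMethod:
    """Heterogeneity gate: random effects iff Q's p-value < alpha (strict)."""
    if het.p_value < cfg.heterogeneity_alpha:
        return PoolingMethod.DERSIMONIAN_LAIRD_RANDOM
    return cfg.fixed_method


def _pool_by_method(
    method: PoolingMethod,
    tables: list[TwoByTwoTable],
    effects: list[EffectEstimate],
    cfg: MetaConfig,
    model: GeneticModel | None,
) -> PooledResult:
    if method is PoolingMethod.MANTEL_HAENSZEL_FIXED:
        return pool_mantel_haenszel(tables, cc=cfg.cc, model=model)
    if method is PoolingMethod.INVERSE_VARIANCE_FIXED:
        return pool_inverse_variance(effects, random=False, model=model)
    return pool_inverse_variance(effects, random=True, model=model)


@dataclass(frozen=True)
class MetaAnalysisResult:
    """Everything needed to re-render a per-SNP association report."""

    snp_id: str
    config: MetaConfig
    studies: tuple
    effects: dict[GeneticModel, list[EffectEstimate]] = field(hash=False)
    hwe: dict[str, HWEResult] = field(hash=False)
    pooled: dict[GeneticModel, PooledResult] = field(hash=False)
    quality: dict[str, QualityScore] = field(hash=False)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)


def meta_analyze(ds: SNPDataset, cfg: MetaConfig | None = None) -> MetaAnalysisResult:
    """Run the full per-SNP synthesis across all four genetic models.

    For each model: per-study odds ratios, Cochran's Q, and the pooled
    estimate by the heterogeneity-gated method.  HWE is tested in every
    control arm; quality scores are computed where metadata is present.
    """
    cfg = cfg or MetaConfig()
    findings = validate_dataset(ds)
    if findings:
        raise ValidationError(
            "dataset failed validation: " + "; ".join(str(f) for f in findings)
        )
    if ds.k < 2:
        raise InsufficientStudiesError("meta-analysis requires at least 2 studies")

    effects_by_model: dict[GeneticModel, list[EffectEstimate]] = {}
    pooled: dict[GeneticModel, PooledResult] = {}
    for model in GeneticModel:
        try:
            tables = [build_contrast(s, model) for s in ds.studies]
            effects = [odds_ratio(t, cfg.cc) for t in tables]
            het = cochran_q(effects)
            method = select_model(het, cfg)
            result = _pool_by_method(method, tables, effects, cfg, model)
        except Exception as exc:
            raise type(exc)(f"[{model.value}] {exc}") from exc
        effects_by_model[model] = effects
        pooled[model] = PooledResult(
            method=result.method,
            estimate=result.estimate,
            heterogeneity=result.heterogeneity,
            k=result.k,
            model=model,
            selected=True,
        )

    hwe = {s.study_id: hwe_test(s.controls, cfg.hwe_alpha) for s in ds.studies}
    quality = {
        s.study_id: quality_score(s.metadata)
        for s in ds.studies
        if s.metadata is not None
    }
    return MetaAnalysisResult(
        snp_id=ds.snp_id,
        config=cfg,
        studies=ds.studies,
        effects=effects_by_model,
        hwe=hwe,
        pooled=pooled,
        quality=quality,
    )


def leave_one_out(
    ds: SNPDataset, model: GeneticModel, cfg: MetaConfig | None = None
) -> list[PooledResult]:
    """Re-pool k times, each omitting one study (influence diagnostics).

    Each result is tagged with the omitted study's id.  Requires k >= 3 so
    every reduced dataset still supports pooling.
    """
    cfg = cfg or MetaConfig()
    if ds.k < 3:
        raise InsufficientStudiesError(
            f"leave-one-out requires at least 3 studies, got {ds.k}"
        )
    out = []
    for omit in ds.study_ids:
        sub = ds.drop(omit)
        tables = [build_contrast(s, model) for s in sub.studies]
        effects = [odds_ratio(t, cfg.cc) for t in tables]
        het = cochran_q(effects)
        method = select_model(het, cfg)
        res = _pool_by_method(method, tables, effects, cfg, model)
        out.append(
            PooledResult(
                method=res.method,
                estimate=res.estimate,
                heterogeneity=res.heterogeneity,
                k=res.k,
                model=model,
                selected=True,
                omitted_study_id=omit,
            )
        )
    return out
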