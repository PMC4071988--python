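"""Per-study statistics: contrasts, odds ratios, HWE, quality scoring.

A genotype table (three classes per arm) collapses to a 2x2 table under each
of four genetic models; the odds ratio with a Wald interval on the log scale
is the per-study effect measure throughout.
"""

from __future__ import annotations

import math

from scipy.stats import chi2

from .errors import DegenerateTableError, UndefinedEffectError, ValidationError
from .types import (
    CaseSource,
    ContinuityCorrection,
    ControlSource,
    EffectEstimate,
    GeneticModel,
    GenotypeCounts,
    HWEResult,
    QualityFeatures,
    QualityScore,
    Specimen,
    StudyRecord,
    TwoByTwoTable,
)

__all__ = [
    "build_contrast",
    "odds_ratio",
    "hwe_test",
    "quality_score",
]


def build_contrast(study: StudyRecord, model: GeneticModel) -> TwoByTwoTable:
    """Collapse a study's genotype counts into the 2x2 table of a genetic model.

    homozygote:   T2T2 vs T1T1 (heterozygotes dropped)
    heterozygote: T1T2 vs T1T1 (variant homozygotes dropped)
    dominant:     T1T2+T2T2 vs T1T1
    recessive:    T2T2 vs T1T1+T1T2
    """
    ca, co = study.cases, study.controls
    model = GeneticModel(model)
    if model is GeneticModel.HOMOZYGOTE:
        cells = (ca.n22, ca.n11, co.n22, co.n11)
    elif model is GeneticModel.HETEROZYGOTE:
        cells = (ca.n12, ca.n11, co.n12, co.n11)
    elif model is GeneticModel.DOMINANT:
        cells = (ca.n12 + ca.n22, ca.n11, co.n12 + co.n22, co.n11)
    else:  # recessive
        cells = (ca.n22, ca.n11 + ca.n12, co.n22, co.n11 + co.n12)
    return TwoByTwoTable(*cells, study_id=study.study_id)


def apply_continuity_correction(
    t: TwoByTwoTable, cc: ContinuityCorrection
) -> tuple[TwoByTwoTable, bool]:
    """Return the (possibly corrected) table and whether 0.5 was added."""
    cc = ContinuityCorrection(cc)
    cells = (t.a, t.b, t.c, t.d)
    if cc is ContinuityCorrection.HALVES_ALWAYS or (
        cc is ContinuityCorrection.HALVES_WHEN_ZERO and any(x == 0 for x in cells)
    ):
        return TwoByTwoTable(*(x + 0.5 for x in cells), study_id=t.study_id), True
    return t, False


def _check_margins(t: TwoByTwoTable) -> None:
    # An empty margin leaves the odds ratio undefined regardless of correction.
    if (t.a == 0 and t.c == 0) or (t.b == 0 and t.d == 0):
        raise UndefinedEffectError(
            "an exposure column is empty in both arms; the odds ratio is undefined"
        )
    if (t.a == 0 and t.b == 0) or (t.c == 0 and t.d == 0):
        raise UndefinedEffectError(
            "one study arm is empty; the odds ratio is undefined"
        )


def odds_ratio(
    t: TwoByTwoTable,
    cc: ContinuityCorrection = ContinuityCorrection.HALVES_WHEN_ZERO,
) -> EffectEstimate:
    """Odds ratio (a*d)/(b*c) with Woolf SE sqrt(1/a+1/b+1/c+1/d).

    The confidence interval and two-sided p come from the normal
    approximation on the log scale.  Zero cells are handled by the
    continuity-correction policy; with ``cc='none'`` they raise.
    """
    _check_margins(t)
    corrected_t, corrected = apply_continuity_correction(t, cc)
    a, b, c, d = corrected_t.a, corrected_t.b, corrected_t.c, corrected_t.d
    if min(a, b, c, d) == 0:
        raise DegenerateTableError(
            "table has a zero cell; enable a continuity correction "
            "('halves-when-zero' or 'halves-always') to estimate the odds ratio"
        )
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate.from_log_or(log_or, se, corrected=corrected)


def hwe_test(controls: GenotypeCounts, alpha: float = 0.05) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions in one arm.

    Expected counts come from the sample allele frequency, leaving 1 df.
    A monomorphic arm is reported as in equilibrium (chi-square 0) with the
    ``monomorphic`` flag set, since the test carries no information there.
    """
    n = controls.total
    if n < 1:
        raise ValidationError("HWE test requires at least one genotyped subject")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    a1, a2 = controls.allele_counts
    if a1 == 0 or a2 == 0:
        return HWEResult(0.0, 1, 1.0, True, monomorphic=True)
    q = a2 / (a1 + a2)
    expected = (n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q * q)
    observed = (controls.n11, controls.n12, controls.n22)
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(chi2.sf(stat, 1))
    return HWEResult(stat, 1, p, p > alpha)


# Points of the quality rubric: five categories, 0-15 total.
_CASE_SOURCE_POINTS = {
    CaseSource.POPULATION_OR_REGISTRY: 3,
    CaseSource.MIXED: 2,
    CaseSource.HOSPITAL: 1,
    CaseSource.OTHER: 0,
}
_CONTROL_SOURCE_POINTS = {
    ControlSource.POPULATION: 3,
    ControlSource.VOLUNTEERS_OR_BLOOD_BANK: 2,
    ControlSource.HOSPITAL_CANCER_FREE: 1,
    ControlSource.NOT_DESCRIBED: 0,
}
_SPECIMEN_POINTS = {
    Specimen.BLOOD_OR_NORMAL_TISSUE: 3,
    Specimen.MIXED_BLOOD_PARAFFIN: 1,
    Specimen.TUMOR_OR_EXFOLIATED: 0,
}


def _size_points(n: int) -> int:
    if n >= 1000:
        return 3
    if n >= 500:
        return 2
    if n >= 200:
        return 1
    return 0


def quality_score(f: QualityFeatures, high_quality_threshold: int = 10) -> QualityScore:
    """Score a study on the five-category epidemiological quality rubric.

    Categories: source of cases (0-3), source of controls (0-3), genotyping
    specimen (0-3), HWE in controls (0 or 3), total sample size (0-3).
    """
    per = {
        "case_source": _CASE_SOURCE_POINTS[CaseSource(f.case_source)],
        "control_source": _CONTROL_SOURCE_POINTS[ControlSource(f.control_source)],
        "specimen": _SPECIMEN_POINTS[Specimen(f.specimen)],
        "hwe": 3 if f.hwe_in_controls else 0,
        "sample_size": _size_points(f.total_sample_size),
    }
    total = sum(per.values())
    return QualityScore(total=total, per_category=per, is_high_quality=total >= high_quality_threshold)
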