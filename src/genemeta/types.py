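"""Core domain types for genotype-level case-control meta-analysis.

The unit of data is one case-control study of a biallelic SNP, stored as two
genotype-count triplets (common homozygote T1T1, heterozygote T1T2, variant
homozygote T2T2).  Column order is fixed by convention: the package never
re-labels alleles from observed frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import ValidationError

#: Two-sided 95% normal critical value, at the precision legacy
#: meta-analysis software carried it.
Z975 = 1.959964


class GeneticModel(str, Enum):
    """The four genotype contrasts of a biallelic association analysis."""

    HOMOZYGOTE = "homozygote"      # T2T2 vs T1T1
    HETEROZYGOTE = "heterozygote"  # T1T2 vs T1T1
    DOMINANT = "dominant"          # T1T2+T2T2 vs T1T1
    RECESSIVE = "recessive"        # T2T2 vs T1T1+T1T2


class PoolingMethod(str, Enum):
    MANTEL_HAENSZEL_FIXED = "mantel_haenszel_fixed"
    INVERSE_VARIANCE_FIXED = "inverse_variance_fixed"
    DERSIMONIAN_LAIRD_RANDOM = "dersimonian_laird_random"


class ContinuityCorrection(str, Enum):
    """Policy for adding 0.5 to 2x2 cells before taking the odds ratio."""

    NONE = "none"
    HALVES_WHEN_ZERO = "halves-when-zero"
    HALVES_ALWAYS = "halves-always"


class CaseSource(str, Enum):
    POPULATION_OR_REGISTRY = "population_or_registry"
    MIXED = "mixed"
    HOSPITAL = "hospital"
    OTHER = "other"


class ControlSource(str, Enum):
    POPULATION = "population"
    VOLUNTEERS_OR_BLOOD_BANK = "volunteers_or_blood_bank"
    HOSPITAL_CANCER_FREE = "hospital_cancer_free"
    NOT_DESCRIBED = "not_described"


class Specimen(str, Enum):
    BLOOD_OR_NORMAL_TISSUE = "blood_or_normal_tissue"
    MIXED_BLOOD_PARAFFIN = "mixed_blood_paraffin"
    TUMOR_OR_EXFOLIATED = "tumor_or_exfoliated"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one arm (cases or controls) of one study.

    ``n11``, ``n12``, ``n22`` are the T1T1, T1T2 and T2T2 counts.  An
    all-zero arm is representable (a simulated arm of size 0) but is
    rejected by dataset validation before analysis.
    """

    n11: int
    n12: int
    n22: int

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n22"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n22

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(T1, T2) allele counts."""
        return 2 * self.n11 + self.n12, self.n12 + 2 * self.n22

    @property
    def variant_allele_frequency(self) -> float:
        a1, a2 = self.allele_counts
        if a1 + a2 == 0:
            raise ValidationError("allele frequency undefined for an empty arm")
        return a2 / (a1 + a2)


@dataclass(frozen=True)
class QualityFeatures:
    """The five study features the quality rubric scores."""

    case_source: CaseSource
    control_source: ControlSource
    specimen: Specimen
    hwe_in_controls: bool
    total_sample_size: int

    def __post_init__(self) -> None:
        if self.total_sample_size < 0:
            raise ValidationError("total_sample_size must be >= 0")


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    year: int
    cases: GenotypeCounts
    controls: GenotypeCounts
    metadata: QualityFeatures | None = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")


@dataclass(frozen=True)
class SNPDataset:
    """An ordered collection of studies of a single SNP.

    Study order is preserved for report layout only; every statistic is
    invariant under permutation of the studies.
    """

    snp_id: str
    studies: tuple[StudyRecord, ...]

    def __init__(self, snp_id: str, studies) -> None:
        object.__setattr__(self, "snp_id", snp_id)
        object.__setattr__(self, "studies", tuple(studies))

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s.study_id for s in self.studies)

    def drop(self, study_id: str) -> "SNPDataset":
        """Dataset without the named study (leave-one-out helper)."""
        kept = [s for s in self.studies if s.study_id != study_id]
        if len(kept) == len(self.studies):
            raise ValidationError(f"no study named {study_id!r}")
        return SNPDataset(self.snp_id, kept)


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposed/unexposed x case/control counts for one genetic contrast.

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  Cells are reals so a continuity-corrected
    table is representable; raw tables carry integers.
    """

    a: float
    b: float
    c: float
    d: float
    study_id: str | None = None

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValidationError(f"cell {name} must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def swap_arms(self) -> "TwoByTwoTable":
        """Exchange the case and control rows."""
        return TwoByTwoTable(self.c, self.d, self.a, self.b, self.study_id)

    def swap_exposure(self) -> "TwoByTwoTable":
        """Exchange the exposed and unexposed columns."""
        return TwoByTwoTable(self.b, self.a, self.d, self.c, self.study_id)


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its Wald machinery."""

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False

    @classmethod
    def from_log_or(cls, log_or: float, se: float, corrected: bool = False) -> "EffectEstimate":
        from scipy.stats import norm

        if se <= 0:
            raise ValidationError(f"standard error must be positive, got {se}")
        z = log_or / se
        return cls(
            log_or=log_or,
            se=se,
            or_=math.exp(log_or),
            ci_low=math.exp(log_or - Z975 * se),
            ci_high=math.exp(log_or + Z975 * se),
            p_value=float(2.0 * norm.sf(abs(z))),
            corrected=corrected,
        )

    @property
    def variance(self) -> float:
        return self.se * self.se


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df = 1)."""

    chi_square: float
    df: int
    p_value: float
    in_equilibrium: bool
    monomorphic: bool = False


@dataclass(frozen=True)
class QualityScore:
    """Rubric score: five categories, 0-15 total, >=10 means high quality."""

    total: int
    per_category: dict[str, int] = field(hash=False)
    is_high_quality: bool = False

    def __post_init__(self) -> None:
        if self.total != sum(self.per_category.values()):
            raise ValidationError("total must equal the sum of category scores")
        if not 0 <= self.total <= 15:
            raise ValidationError("total must lie in [0, 15]")


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its derived I-squared and DerSimonian-Laird tau-squared."""

    q: float
    df: int
    p_value: float
    i_squared: float
    tau_squared: float


@dataclass(frozen=True)
class PooledResult:
    method: PoolingMethod
    estimate: EffectEstimate
    heterogeneity: HeterogeneityResult
    k: int
    model: GeneticModel | None = None
    selected: bool = False
    omitted_study_id: str | None = None


@dataclass(frozen=True)
class MetaConfig:
    """Knobs of the synthesis pipeline.

    heterogeneity_alpha gates the fixed/random choice: random effects are
    used only when Cochran's Q has p below this threshold.
    """

    heterogeneity_alpha: float = 0.05
    fixed_method: PoolingMethod = PoolingMethod.MANTEL_HAENSZEL_FIXED
    cc: ContinuityCorrection = ContinuityCorrection.HALVES_WHEN_ZERO
    hwe_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("heterogeneity_alpha", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.fixed_method == PoolingMethod.DERSIMONIAN_LAIRD_RANDOM:
            raise ValidationError("fixed_method must be a fixed-effects method")
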