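"""Synthetic case-control genotype studies with known truth.

Controls are drawn from Hardy-Weinberg proportions at a chosen variant
allele frequency; case genotype probabilities are the control probabilities
tilted by per-genotype odds ratios (heterozygote and variant-homozygote,
relative to the common homozygote) and renormalised.  Optional
between-study heterogeneity adds a study-specific Normal(0, tau^2) shift to
both log odds ratios, matching the random-effects model under test.

Default parameters are the package's reference study conditions: a common
variant (q = 0.3) with a protective variant homozygote (OR 0.7, heterozygote
OR 1), 50 studies of 1,000 subjects per arm, no heterogeneity.

Reproducibility: each study draws from a dedicated generator spawned from
the master seed with the study index as spawn key, so counts depend only on
(seed, study_index), never on generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .types import GenotypeCounts, SNPDataset, StudyRecord

__all__ = ["SimulationParams", "expected_genotype_probs", "simulate_study", "simulate_dataset"]


@dataclass(frozen=True)
class SimulationParams:
    """Generating parameters of one synthetic multi-study dataset."""

    q: float = 0.3            # variant (T2) allele frequency in controls
    or_het: float = 1.0       # true heterozygote odds ratio (T1T2 vs T1T1)
    or_hom: float = 0.7       # true homozygote odds ratio (T2T2 vs T1T1)
    n_cases: int = 1000
    n_controls: int = 1000
    k: int = 50               # number of studies
    tau: float = 0.0          # between-study SD of the log odds ratios
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValidationError(f"q must lie in (0, 1), got {self.q}")
        if self.or_het <= 0 or self.or_hom <= 0:
            raise ValidationError("odds ratios must be positive")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValidationError("arm sizes must be non-negative")
        if self.k < 1:
            raise ValidationError("k must be at least 1")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")

    @property
    def label(self) -> str:
        return (
            f"sim_q{self.q:g}_orhet{self.or_het:g}_orhom{self.or_hom:g}"
            f"_n{self.n_cases}x{self.n_controls}_k{self.k}_tau{self.tau:g}_seed{self.seed}"
        )


def expected_genotype_probs(
    q: float, or_het: float, or_hom: float
) -> tuple[np.ndarray, np.ndarray]:
    """(control, case) genotype probability 3-vectors (T1T1, T1T2, T2T2).

    Controls follow HWE: ((1-q)^2, 2q(1-q), q^2).  Case probabilities are
    the control probabilities multiplied by (1, or_het, or_hom) and
    renormalised — the genotype distribution implied by those odds ratios
    under a rare-free logistic disease model.
    """
    if not 0.0 < q < 1.0:
        raise ValidationError(f"q must lie in (0, 1), got {q}")
    if or_het <= 0 or or_hom <= 0:
        raise ValidationError("odds ratios must be positive")
    control = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    tilted = control * np.array([1.0, or_het, or_hom])
    return control, tilted / tilted.sum()


def _study_rng(seed: int, study_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(study_index,)))


def simulate_study(p: SimulationParams, study_index: int) -> StudyRecord:
    """Draw one study: multinomial genotype counts in each arm.

    With tau > 0 a single shift delta ~ Normal(0, tau^2) is added to both
    log odds ratios before the case probabilities are formed (drawn first,
    then controls, then cases, from the study's own generator).
    """
    rng = _study_rng(p.seed, study_index)
    delta = rng.normal(0.0, p.tau) if p.tau > 0 else 0.0
    control_probs, case_probs = expected_genotype_probs(
        p.q, p.or_het * math.exp(delta), p.or_hom * math.exp(delta)
    )
    controls = rng.multinomial(p.n_controls, control_probs)
    cases = rng.multinomial(p.n_cases, case_probs)
    return StudyRecord(
        study_id=f"sim{study_index:03d}",
        year=0,
        cases=GenotypeCounts(*(int(x) for x in cases)),
        controls=GenotypeCounts(*(int(x) for x in controls)),
    )


def simulate_dataset(p: SimulationParams) -> SNPDataset:
    """Draw a k-study dataset; the snp_id records the generating parameters."""
    return SNPDataset(p.label, [simulate_study(p, i) for i in range(p.k)])


def with_seed(p: SimulationParams, seed: int) -> SimulationParams:
    """Copy of the parameters with a different master seed."""
    return replace(p, seed=seed)
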