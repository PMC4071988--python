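"""Heterogeneity, fixed/random pooling, model selection and leave-one-out.

statsmodels (StratifiedTable, meta_analysis.combine_effects) serves as the
independent oracle for the Mantel-Haenszel and inverse-variance /
DerSimonian-Laird estimators.
"""

import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.meta_analysis import combine_effects

from genemeta import (
    EffectEstimate,
    GeneticModel,
    InsufficientStudiesError,
    MetaConfig,
    PoolingMethod,
    SNPDataset,
    TwoByTwoTable,
    build_contrast,
    cochran_q,
    leave_one_out,
    meta_analyze,
    odds_ratio,
    pool_inverse_variance,
    pool_mantel_haenszel,
    select_model,
)
from genemeta.types import HeterogeneityResult


def _effect(log_or, se):
    return EffectEstimate.from_log_or(log_or, se)


def _fixture_tables(ds, model):
    return [build_contrast(s, model) for s in ds.studies]


class TestCochranQ:
    def test_hand_computed_weighted_sum(self):
        # theta=(0, 0.5, 1), se=0.2 -> w=25 each, mean 0.5, Q=25*(0.25+0.25)=12.5
        het = cochran_q([_effect(0.0, 0.2), _effect(0.5, 0.2), _effect(1.0, 0.2)])
        assert het.q == pytest.approx(12.5)
        assert het.df == 2
        assert het.i_squared == pytest.approx((12.5 - 2) / 12.5)
        # DL: tau2 = (Q - df) / (sw - sum(w^2)/sw) = 10.5 / (75 - 1875/75)
        assert het.tau_squared == pytest.approx(10.5 / 50.0)

    def test_identical_effects_have_zero_q(self):
        het = cochran_q([_effect(0.3, 0.1), _effect(0.3, 0.4), _effect(0.3, 0.2)])
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i_squared == 0.0 and het.p_value == pytest.approx(1.0)

    def test_published_two_study_heterogeneity(self, datasets):
        ds = datasets["rs1799794"]
        effects = [odds_ratio(t) for t in _fixture_tables(ds, GeneticModel.HOMOZYGOTE)]
        assert cochran_q(effects).p_value == pytest.approx(0.77, abs=0.02)

    def test_single_study_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            cochran_q([_effect(0.1, 0.1)])


class TestMantelHaenszel:
    def test_published_pooled_recessive(self, datasets):
        tables = _fixture_tables(datasets["rs1799794"], GeneticModel.RECESSIVE)
        res = pool_mantel_haenszel(tables)
        assert res.estimate.or_ == pytest.approx(0.67, abs=0.005)
        assert res.estimate.ci_low == pytest.approx(0.52, abs=0.01)
        assert res.estimate.ci_high == pytest.approx(0.87, abs=0.01)

    def test_duplicated_table_pools_to_itself(self):
        t = TwoByTwoTable(30, 70, 50, 50)
        res = pool_mantel_haenszel([t, t])
        assert res.estimate.or_ == pytest.approx(odds_ratio(t).or_)

    def test_null_tables_pool_to_one(self):
        res = pool_mantel_haenszel([TwoByTwoTable(10, 10, 10, 10), TwoByTwoTable(20, 20, 20, 20)])
        assert res.estimate.or_ == pytest.approx(1.0)

    def test_agrees_with_statsmodels_oracle(self, datasets):
        for snp, ds in datasets.items():
            for model in GeneticModel:
                tables = _fixture_tables(ds, model)
                ours = pool_mantel_haenszel(tables)
                sm = StratifiedTable([np.array([[t.a, t.b], [t.c, t.d]]) for t in tables])
                assert ours.estimate.or_ == pytest.approx(sm.oddsratio_pooled, rel=1e-10)
                assert ours.estimate.se == pytest.approx(sm.logodds_pooled_se, rel=1e-10)


class TestInverseVariance:
    def test_hand_computed_weighted_mean(self):
        # w = (100, 1/0.09); pooled = (100*0.2 + 11.11*0.6) / 111.11 = 0.2324
        effects = [_effect(0.2, 0.1), _effect(0.6, 0.3)]
        res = pool_inverse_variance(effects)
        w1, w2 = 100.0, 1.0 / 0.09
        assert res.estimate.log_or == pytest.approx((w1 * 0.2 + w2 * 0.6) / (w1 + w2))
        assert res.estimate.se == pytest.approx(1.0 / math.sqrt(w1 + w2))

    def test_published_pooled_homozygote(self, datasets):
        tables = _fixture_tables(datasets["rs1799794"], GeneticModel.HOMOZYGOTE)
        res = pool_inverse_variance([odds_ratio(t) for t in tables])
        assert res.estimate.or_ == pytest.approx(0.70, abs=0.005)

    def test_random_equals_fixed_when_q_below_df(self):
        effects = [_effect(0.30, 0.2), _effect(0.31, 0.25), _effect(0.29, 0.3)]
        fixed = pool_inverse_variance(effects, random=False)
        random = pool_inverse_variance(effects, random=True)
        assert fixed.heterogeneity.tau_squared == 0.0
        assert random.estimate.log_or == pytest.approx(fixed.estimate.log_or)
        assert random.estimate.se == pytest.approx(fixed.estimate.se)

    def test_agrees_with_statsmodels_combine_effects(self):
        # Clearly heterogeneous effects so the DL tau2 is positive —
        # statsmodels does not truncate a negative moment estimate at zero,
        # whereas the conventional (and our) definition does.
        rng = np.random.default_rng(7)
        theta = rng.normal(0.2, 1.5, size=6)
        se = rng.uniform(0.1, 0.5, size=6)
        effects = [_effect(t, s) for t, s in zip(theta, se)]
        sm = combine_effects(theta, se**2, method_re="dl")
        fixed = pool_inverse_variance(effects, random=False)
        random = pool_inverse_variance(effects, random=True)
        assert fixed.estimate.log_or == pytest.approx(sm.mean_effect_fe, rel=1e-10)
        assert fixed.estimate.se == pytest.approx(sm.sd_eff_w_fe, rel=1e-10)
        assert random.estimate.log_or == pytest.approx(sm.mean_effect_re, rel=1e-10)
        assert random.estimate.se == pytest.approx(sm.sd_eff_w_re, rel=1e-10)
        assert fixed.heterogeneity.tau_squared == pytest.approx(sm.tau2, rel=1e-10)

    def test_random_interval_contains_fixed_interval(self):
        effects = [_effect(-0.5, 0.15), _effect(0.6, 0.2), _effect(0.1, 0.25)]
        fixed = pool_inverse_variance(effects, random=False)
        random = pool_inverse_variance(effects, random=True)
        width_f = math.log(fixed.estimate.ci_high / fixed.estimate.ci_low)
        width_r = math.log(random.estimate.ci_high / random.estimate.ci_low)
        assert width_r >= width_f


class TestSelectModel:
    @pytest.mark.parametrize(
        "p, alpha, expected",
        [
            (0.001, 0.05, PoolingMethod.DERSIMONIAN_LAIRD_RANDOM),
            (0.05, 0.05, PoolingMethod.MANTEL_HAENSZEL_FIXED),  # boundary: strict <
            (0.5, 0.05, PoolingMethod.MANTEL_HAENSZEL_FIXED),
        ],
    )
    def test_heterogeneity_gate(self, p, alpha, expected):
        het = HeterogeneityResult(q=1.0, df=1, p_value=p, i_squared=0.0, tau_squared=0.0)
        cfg = MetaConfig(heterogeneity_alpha=alpha)
        assert select_model(het, cfg) == expected

    def test_fixture_contrasts_all_select_fixed(self, datasets, default_config):
        for ds in datasets.values():
            res = meta_analyze(ds, default_config)
            for pooled in res.pooled.values():
                assert pooled.method == PoolingMethod.MANTEL_HAENSZEL_FIXED


class TestMetaAnalyze:
    def test_published_pooled_results(self, datasets):
        res = meta_analyze(datasets["rs861539"])
        hom = res.pooled[GeneticModel.HOMOZYGOTE].estimate
        assert hom.or_ == pytest.approx(0.95, abs=0.005)
        assert hom.ci_low == pytest.approx(0.85, abs=0.01)
        assert hom.ci_high == pytest.approx(1.06, abs=0.01)
        res96 = meta_analyze(datasets["rs1799796"])
        het = res96.pooled[GeneticModel.HETEROZYGOTE].estimate
        assert het.or_ == pytest.approx(0.91, abs=0.005)
        assert het.ci_low == pytest.approx(0.83, abs=0.01)
        assert het.ci_high == pytest.approx(0.99, abs=0.01)

    def test_identical_studies_pool_to_single_study_effect(self):
        from genemeta import GenotypeCounts, StudyRecord

        s1 = StudyRecord("A", 2000, GenotypeCounts(100, 80, 20), GenotypeCounts(90, 90, 20))
        s2 = StudyRecord("B", 2001, s1.cases, s1.controls)
        res = meta_analyze(SNPDataset("rs0", [s1, s2]))
        for model, pooled in res.pooled.items():
            single = odds_ratio(build_contrast(s1, model))
            assert pooled.estimate.or_ == pytest.approx(single.or_)
            assert pooled.heterogeneity.q == pytest.approx(0.0, abs=1e-12)

    def test_order_invariance(self, datasets):
        ds = datasets["rs861539"]
        shuffled = SNPDataset(ds.snp_id, list(reversed(ds.studies)))
        a, b = meta_analyze(ds), meta_analyze(shuffled)
        for model in GeneticModel:
            assert a.pooled[model].estimate.log_or == pytest.approx(
                b.pooled[model].estimate.log_or, rel=1e-12
            )
            assert a.pooled[model].heterogeneity.q == pytest.approx(
                b.pooled[model].heterogeneity.q, rel=1e-12
            )

    def test_fixed_pooled_within_per_study_hull(self, datasets):
        for ds in datasets.values():
            res = meta_analyze(ds)
            for model in GeneticModel:
                logs = [e.log_or for e in res.effects[model]]
                pooled = res.pooled[model].estimate.log_or
                assert min(logs) - 1e-12 <= pooled <= max(logs) + 1e-12

    def test_mh_and_iv_agree_on_homogeneous_data(self, datasets):
        iv_cfg = MetaConfig(fixed_method=PoolingMethod.INVERSE_VARIANCE_FIXED)
        for ds in datasets.values():
            mh = meta_analyze(ds)
            iv = meta_analyze(ds, iv_cfg)
            for model in GeneticModel:
                assert mh.pooled[model].estimate.or_ == pytest.approx(
                    iv.pooled[model].estimate.or_, abs=0.01
                )


class TestLeaveOneOut:
    def test_returns_k_results_each_excluding_one(self, datasets, default_config):
        ds = datasets["rs861539"]
        results = leave_one_out(ds, GeneticModel.DOMINANT, default_config)
        assert [r.omitted_study_id for r in results] == list(ds.study_ids)
        assert all(r.k == ds.k - 1 for r in results)

    def test_omitting_a_study_at_the_pooled_mean_changes_nothing(self):
        from genemeta import GenotypeCounts, StudyRecord

        base = StudyRecord("A", 2000, GenotypeCounts(100, 80, 20), GenotypeCounts(90, 90, 20))
        clones = [
            StudyRecord(f"S{i}", 2000 + i, base.cases, base.controls) for i in range(4)
        ]
        ds = SNPDataset("rs0", clones)
        full = meta_analyze(ds).pooled[GeneticModel.DOMINANT].estimate.or_
        for res in leave_one_out(ds, GeneticModel.DOMINANT):
            assert res.estimate.or_ == pytest.approx(full, abs=1e-3)

    def test_requires_three_studies(self, datasets):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out(datasets["rs1799794"], GeneticModel.DOMINANT)
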