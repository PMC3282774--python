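"""Fixed/random-effects pooling, heterogeneity and the model-selection rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genemeta import (
    GeneticModel,
    TwoByTwo,
    cochran_q,
    collapse,
    dl_pool,
    iv_pool,
    mh_pool,
    pool_with_selection,
    study_odds_ratio,
)

MODELS = list(GeneticModel)


def _stratum(table, model, ethnicity=None):
    recs = [r for r in table if ethnicity is None or r.ethnicity == ethnicity]
    tabs = [collapse(r.cases, r.controls, model) for r in recs]
    effs = [study_odds_ratio(t, study_id=r.study_id, model=model) for t, r in zip(tabs, recs)]
    return tabs, effs


from genemeta import EffectEstimate  # noqa: E402


def make_effect(log_or, se, sid="s"):
    return EffectEstimate(
        study_id=sid,
        model=GeneticModel.HOM,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
    )


class TestMantelHaenszel:
    def test_european_homozygote_pool(self, fixture_table):
        tabs, _ = _stratum(fixture_table, GeneticModel.HOM, "European")
        log_or, se = mh_pool(tabs)
        assert math.exp(log_or) == pytest.approx(1.29, abs=0.01)
        assert math.exp(log_or - 1.959964 * se) == pytest.approx(1.02, abs=0.02)
        assert math.exp(log_or + 1.959964 * se) == pytest.approx(1.63, abs=0.02)

    def test_european_recessive_pool(self, fixture_table):
        tabs, _ = _stratum(fixture_table, GeneticModel.REC, "European")
        log_or, se = mh_pool(tabs)
        assert math.exp(log_or) == pytest.approx(1.31, abs=0.01)

    def test_single_table_reduces_to_study_estimate(self):
        t = TwoByTwo(30, 70, 20, 80)
        est = study_odds_ratio(t)
        log_or, se = mh_pool([t])
        assert (log_or, se) == (est.log_or, est.se)

    def test_matches_statsmodels_stratified_table(self, fixture_table):
        """Independent cross-check of the MH estimator and RBG variance."""
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        tabs, _ = _stratum(fixture_table, GeneticModel.REC)
        strata = np.array([[[t.a, t.b], [t.c, t.d]] for t in tabs]).T
        st_tab = sm_ct.StratifiedTable(strata.astype(float))
        log_or, se = mh_pool(tabs)
        assert math.exp(log_or) == pytest.approx(st_tab.oddsratio_pooled, rel=1e-9)
        lcb, ucb = st_tab.oddsratio_pooled_confint(0.05)
        assert math.exp(log_or - 1.959964 * se) == pytest.approx(lcb, rel=1e-6)
        assert math.exp(log_or + 1.959964 * se) == pytest.approx(ucb, rel=1e-6)


class TestInverseVariance:
    def test_null_effects_pool_to_null(self):
        effs = [make_effect(0.0, s) for s in (0.1, 0.2, 0.3)]
        log_or, se = iv_pool(effs)
        assert log_or == 0.0
        assert se == pytest.approx(1 / math.sqrt(sum(1 / s**2 for s in (0.1, 0.2, 0.3))))

    def test_single_effect_unchanged(self):
        e = make_effect(0.4, 0.2)
        assert iv_pool([e]) == pytest.approx((0.4, 0.2))

    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("ethnicity", [None, "European"])
    def test_agrees_with_mh_within_two_percent(self, fixture_table, model, ethnicity):
        """Cross-estimator consistency on every multi-study stratum."""
        tabs, effs = _stratum(fixture_table, model, ethnicity)
        mh_log, _ = mh_pool(tabs)
        iv_log, _ = iv_pool(effs)
        assert math.exp(iv_log) == pytest.approx(math.exp(mh_log), rel=0.02)


class TestDerSimonianLaird:
    def test_truncated_tau2_reduces_to_iv(self, fixture_table):
        # overall homozygote stratum: Q well below df, tau2 truncates to 0
        _, effs = _stratum(fixture_table, GeneticModel.HOM)
        het = cochran_q(effs)
        assert het.tau2 == 0.0
        dl_log, dl_se, tau2 = dl_pool(effs)
        iv_log, iv_se = iv_pool(effs)
        assert (dl_log, dl_se, tau2) == pytest.approx((iv_log, iv_se, 0.0), abs=1e-12)

    def test_symmetric_pair_pools_to_null(self):
        effs = [make_effect(0.7, 0.1), make_effect(-0.7, 0.1)]
        log_or, se, tau2 = dl_pool(effs)
        assert log_or == pytest.approx(0.0, abs=1e-12)
        assert tau2 > 0

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            dl_pool([make_effect(0.1, 0.1)])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(-1.5, 1.5), st.floats(0.05, 1.0)), min_size=2, max_size=8
        )
    )
    def test_tau2_truncation_property(self, pairs):
        effs = [make_effect(lo, se) for lo, se in pairs]
        het = cochran_q(effs)
        assert het.tau2 >= 0
        if het.Q <= het.df:
            assert het.tau2 == 0.0
            assert dl_pool(effs)[:2] == pytest.approx(iv_pool(effs), abs=1e-12)


class TestCochranQ:
    def test_overall_heterozygote_pq(self, fixture_table):
        _, effs = _stratum(fixture_table, GeneticModel.HET)
        assert cochran_q(effs).p_Q == pytest.approx(0.364, abs=0.005)

    def test_european_recessive_pq(self, fixture_table):
        _, effs = _stratum(fixture_table, GeneticModel.REC, "European")
        assert cochran_q(effs).p_Q == pytest.approx(0.839, abs=0.005)

    def test_identical_effects_have_zero_q(self):
        effs = [make_effect(0.3, 0.2) for _ in range(4)]
        het = cochran_q(effs)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.I2 == 0.0

    def test_single_study_undefined(self):
        with pytest.raises(ValueError):
            cochran_q([make_effect(0.1, 0.1)])


class TestPoolWithSelection:
    def test_overall_homozygote_uses_fixed_effects(self, fixture_table):
        tabs, effs = _stratum(fixture_table, GeneticModel.HOM)
        res = pool_with_selection(tabs, effs, GeneticModel.HOM)
        assert res.method == "MH-fixed"
        assert res.or_ == pytest.approx(1.16, abs=0.01)

    def test_european_recessive_association_p(self, fixture_table):
        tabs, effs = _stratum(fixture_table, GeneticModel.REC, "European")
        res = pool_with_selection(tabs, effs, GeneticModel.REC, stratum="European")
        assert res.p_assoc == pytest.approx(0.019, abs=0.001)
        assert res.ci_low <= res.or_ <= res.ci_high

    def test_significant_heterogeneity_switches_to_random(self):
        # two wildly different studies: Q p below the 0.10 threshold
        tabs = [TwoByTwo(80, 20, 20, 80), TwoByTwo(20, 80, 80, 20)]
        effs = [study_odds_ratio(t) for t in tabs]
        assert cochran_q(effs).p_Q < 0.10
        res = pool_with_selection(tabs, effs, GeneticModel.HOM)
        assert res.method == "DL-random"

    def test_single_study_reports_no_heterogeneity(self):
        t = TwoByTwo(30, 70, 20, 80)
        res = pool_with_selection([t], [study_odds_ratio(t)], GeneticModel.DOM)
        assert res.k == 1 and res.het is None
        assert res.or_ == pytest.approx(study_odds_ratio(t).or_)

    @pytest.mark.parametrize("model", MODELS)
    def test_fixed_pool_within_study_range(self, fixture_table, model):
        tabs, effs = _stratum(fixture_table, model)
        res = pool_with_selection(tabs, effs, model)
        ors = [e.or_ for e in effs]
        assert min(ors) <= res.or_ <= max(ors)

    def test_z_and_p_consistent(self, fixture_table):
        tabs, effs = _stratum(fixture_table, GeneticModel.REC)
        res = pool_with_selection(tabs, effs, GeneticModel.REC)
        from scipy import stats

        assert res.p_assoc == pytest.approx(2 * stats.norm.sf(abs(res.z)), rel=1e-9)
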