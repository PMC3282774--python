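"""Publication-bias tests and familywise multiplicity adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genemeta import (
    EffectEstimate,
    GeneticModel,
    begg_test,
    bonferroni_adjust,
    collapse,
    egger_test,
    holm_adjust,
    mh_pool,
    study_odds_ratio,
)
from genemeta.bias import funnel_data


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


def _overall(table, model):
    tabs = [collapse(r.cases, r.controls, model) for r in table]
    effs = [study_odds_ratio(t, study_id=r.study_id, model=model) for t, r in zip(tabs, table)]
    return effs, mh_pool(tabs)


PUBLISHED_BIAS_P = {
    GeneticModel.HET: (0.707, 0.955),
    GeneticModel.HOM: (0.452, 0.130),
    GeneticModel.DOM: (0.707, 0.976),
    GeneticModel.REC: (0.707, 0.078),
}


class TestBegg:
    @pytest.mark.parametrize("model", list(GeneticModel))
    def test_published_pvalues(self, fixture_table, model):
        effs, (pl, psl) = _overall(fixture_table, model)
        res = begg_test(effs, pl, psl)
        assert res.p == pytest.approx(PUBLISHED_BIAS_P[model][0], abs=0.005)

    def test_closed_form_k6_s3(self):
        """k = 6, |S| = 3, no ties: z = 2/sqrt(6*5*17/18) ~ 0.376, p ~ 0.707."""
        ses = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        # deviates with 6 rank inversions against the ascending variances,
        # so S = 9 concordant - 6 discordant = 3
        devs = [0.3, 0.2, 0.1, 0.0, 0.4, 0.5]
        effs = [make_effect(d * s, s) for d, s in zip(devs, ses)]
        # zero pooled variance makes t_i = log_or_i / se_i = devs exactly
        res = begg_test(effs, 0.0, 0.0)
        assert res.statistic == pytest.approx(2 / math.sqrt(6 * 5 * 17 / 18), abs=1e-9)
        assert res.p == pytest.approx(0.707, abs=0.001)

    def test_perfect_concordance_minimal_p(self):
        k = 6
        effs = [make_effect(i * 0.2, 0.1 + 0.1 * i) for i in range(k)]
        res = begg_test(effs, 0.0, 0.0)
        s_max = k * (k - 1) / 2
        z_max = (s_max - 1) / math.sqrt(k * (k - 1) * (2 * k + 5) / 18)
        assert res.statistic == pytest.approx(z_max)

    def test_sign_flip_invariance(self, fixture_table):
        effs, (pl, psl) = _overall(fixture_table, GeneticModel.REC)
        flipped = [make_effect(-e.log_or, e.se, e.study_id) for e in effs]
        direct = begg_test(effs, pl, psl)
        mirror = begg_test(flipped, -pl, psl)
        assert direct.p == pytest.approx(mirror.p, abs=1e-12)

    def test_too_few_studies_not_computable(self):
        res = begg_test([make_effect(0.1, 0.2)] * 2, 0.0, 0.1)
        assert not res.computable


class TestEgger:
    @pytest.mark.parametrize("model", list(GeneticModel))
    def test_published_pvalues(self, fixture_table, model):
        effs, _ = _overall(fixture_table, model)
        res = egger_test(effs)
        assert res.p == pytest.approx(PUBLISHED_BIAS_P[model][1], abs=0.005)

    def test_points_through_origin_have_zero_intercept(self):
        # snd = 0.4 * precision exactly => intercept 0, p = 1
        ses = [0.1, 0.2, 0.4, 0.8]
        effs = [make_effect(0.4, s) for s in ses]
        res = egger_test(effs)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_identical_precisions_singular(self):
        with pytest.raises(ValueError, match="singular"):
            egger_test([make_effect(x, 0.2) for x in (0.1, 0.2, 0.3)])

    def test_too_few_studies_not_computable(self):
        assert not egger_test([make_effect(0.1, 0.2)] * 2).computable


class TestMultiplicity:
    def test_stepdown_reproduces_published_smallest_adjusted_p(self):
        # the smallest of the four model p-values, 0.019, adjusts to 4x = 0.076
        adj = holm_adjust([0.019, 0.032, 0.5, 0.7])
        assert adj.adjusted[0] == pytest.approx(0.076, abs=1e-12)

    def test_stepdown_hand_computation(self):
        adj = holm_adjust([0.019, 0.032, 0.5, 0.7])
        assert adj.adjusted == pytest.approx((0.076, 0.096, 1.0, 1.0))

    def test_bonferroni_elementwise(self):
        adj = bonferroni_adjust([0.019, 0.032, 0.5, 0.7])
        assert adj.adjusted == pytest.approx((0.076, 0.128, 1.0, 1.0))

    def test_bonferroni_explains_why_only_recessive_survives(self):
        # at the 0.1 familywise threshold, 0.019*4 = 0.076 passes
        # while 0.032*4 = 0.128 does not
        adj = bonferroni_adjust([0.509, 0.032, 0.975, 0.019])
        assert adj.significant() == (False, False, False, True)

    @pytest.mark.parametrize("raw", [[1.0], [0.0, 0.5]])
    def test_degenerate_inputs(self, raw):
        assert list(bonferroni_adjust(raw).adjusted) == [min(1.0, len(raw) * p) for p in raw]
        assert holm_adjust([1.0]).adjusted == (1.0,)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_holm_never_exceeds_bonferroni_and_dominates_raw(self, raw):
        h = holm_adjust(raw).adjusted
        b = bonferroni_adjust(raw).adjusted
        assert all(hi <= bi + 1e-15 for hi, bi in zip(h, b))
        assert all(hi >= ri for hi, ri in zip(h, raw))

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_holm_matches_statsmodels(self, raw):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        expected = sm.multipletests(raw, method="holm")[1]
        assert np.allclose(holm_adjust(raw).adjusted, expected)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_holm_monotone_in_sorted_order(self, raw):
        adj = holm_adjust(raw)
        order = np.argsort(adj.raw)
        assert np.all(np.diff(np.array(adj.adjusted)[order]) >= -1e-15)


class TestFunnelData:
    def test_columns_and_rows(self, fixture_table):
        effs, (pl, psl) = _overall(fixture_table, GeneticModel.REC)
        df = funnel_data(effs, pl, psl)
        assert list(df.columns) == [
            "study_id", "log_or", "se", "precision", "snd", "std_deviate",
        ]
        assert len(df) == 6
        assert np.allclose(df["snd"], df["log_or"] / df["se"])
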