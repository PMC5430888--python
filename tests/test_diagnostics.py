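import math

import numpy as np
import pytest

from genemeta import (
    ContrastKind,
    EffectEstimate,
    GenotypeStudy,
    PowerSpec,
    begg_test,
    build_contrast,
    cumulative_by_size,
    egger_test,
    funnel_data,
    leave_one_out,
    odds_ratio,
    pool_auto,
    power_two_proportion,
)
from genemeta.data_io import DegenerateInputError, InsufficientStudiesError


def est(theta, se, label=""):
    return EffectEstimate.from_log(theta, se, label=label)


def study(sid, case, ctrl, snp="rs1"):
    return GenotypeStudy(sid, sid, 2001, snp, *case, *ctrl)


IDENTICAL = [study(f"S{i}", (30, 90, 80), (20, 100, 80)) for i in range(4)]


class TestLeaveOneOut:
    def test_identical_studies_give_identical_results(self):
        res = leave_one_out(IDENTICAL, ContrastKind.RECESSIVE)
        assert len(res.rows) == 4
        first = res.rows[0][1].effect
        for _, r in res.rows:
            assert r.effect.or_ == pytest.approx(first.or_)
        assert not res.significance_flips

    def test_robust_contrast_never_flips(self, by_snp):
        res = leave_one_out(by_snp["rs987107"], ContrastKind.RECESSIVE)
        assert not res.significance_flips
        assert all(r.effect.ci_low > 1 for _, r in res.rows)

    def test_borderline_contrast_flags_flip(self, by_snp):
        # the pooled dominant CI scrapes 1, so some omissions lose significance
        res = leave_one_out(by_snp["rs11567686"], ContrastKind.DOMINANT)
        assert res.significance_flips

    def test_needs_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out(IDENTICAL[:2], ContrastKind.RECESSIVE)


class TestCumulative:
    def test_single_study_single_step(self):
        steps = cumulative_by_size(IDENTICAL[:1], ContrastKind.RECESSIVE)
        assert len(steps) == 1
        crude = odds_ratio(build_contrast(IDENTICAL[0], ContrastKind.RECESSIVE))
        assert steps[0].result.effect.or_ == pytest.approx(crude.or_)

    def test_descending_starts_with_largest(self, by_snp):
        steps = cumulative_by_size(by_snp["rs987107"], ContrastKind.RECESSIVE)
        assert steps[0].added_study_id == "Lundmark2007"
        sizes = [next(s.n_total for s in by_snp["rs987107"] if s.study_id == st.added_study_id)
                 for st in steps]
        assert sizes == sorted(sizes, reverse=True)

    def test_ties_break_lexicographically(self):
        steps = cumulative_by_size(IDENTICAL, ContrastKind.RECESSIVE)
        assert [s.added_study_id for s in steps] == ["S0", "S1", "S2", "S3"]

    def test_final_step_is_bit_identical_to_full_pool(self, by_snp):
        for snp, contrast in [("rs987107", ContrastKind.RECESSIVE),
                              ("rs3194051", ContrastKind.RECESSIVE),
                              ("rs11567685", ContrastKind.ALLELIC)]:
            studies = by_snp[snp]
            final = cumulative_by_size(studies, contrast)[-1].result
            full = pool_auto([build_contrast(s, contrast) for s in studies])
            assert final.effect.log_or == full.effect.log_or
            assert final.effect.se_log_or == full.effect.se_log_or
            assert final.effect_model == full.effect_model

    def test_ascending_order_flag(self, by_snp):
        steps = cumulative_by_size(by_snp["rs987107"], ContrastKind.RECESSIVE,
                                   order="asc")
        assert steps[0].added_study_id == "ODoherty1_2008"


class TestEgger:
    def test_hand_computed_three_point_regression(self):
        """Frozen oracle: OLS of (theta/se) on (1/se) for three studies."""
        estimates = [est(0.25, 0.1), est(0.20, 0.2), est(0.15, 0.4)]
        res = egger_test(estimates)
        assert res.intercept == pytest.approx(-0.375, abs=1e-9)
        assert res.t_statistic == pytest.approx(-4.582576, abs=1e-5)
        assert res.p_value == pytest.approx(0.1367777, abs=1e-5)
        assert res.df == 1

    def test_proportional_effects_give_zero_intercept(self):
        # theta_i/se_i proportional to 1/se_i <=> theta_i constant
        estimates = [est(0.3, se) for se in (0.1, 0.2, 0.4)]
        res = egger_test(estimates)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.degenerate and math.isnan(res.p_value)

    def test_unbiased_funnel_is_clean(self, by_snp):
        estimates = [odds_ratio(build_contrast(s, ContrastKind.RECESSIVE))
                     for s in by_snp["rs3194051"]]
        assert egger_test(estimates).p_value > 0.05

    def test_contract_errors(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([est(0.1, 0.1), est(0.2, 0.2)])
        with pytest.raises(DegenerateInputError):
            egger_test([est(0.1, 0.2), est(0.2, 0.2), est(0.3, 0.2)])

    def test_type_one_error_near_nominal(self):
        """On symmetric (unbiased) funnels the intercept test rejects at ~alpha."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            se = rng.uniform(0.05, 0.5, size=10)
            theta = rng.normal(0.0, se)
            res = egger_test([est(t, s) for t, s in zip(theta, se)])
            rejections += res.p_value < 0.05
        # binomial 3-sigma band around 0.05 with n = 1000
        assert 0.029 <= rejections / n_reps <= 0.071, rejections


class TestBegg:
    def test_perfectly_correlated_deviates(self):
        # deviates increase with variance: tau = +1, z from 3 concordant pairs
        estimates = [est(0.0, 0.1), est(0.3, 0.2), est(0.9, 0.4)]
        res = begg_test(estimates)
        u = _deviates(estimates)
        assert np.all(np.diff(u) > 0)
        assert res.kendall_tau == pytest.approx(1.0)
        assert res.z == pytest.approx(3 / math.sqrt(3 * 2 * 11 / 18))

    def test_antisymmetry(self):
        # negating every effect mirrors the deviates around the pooled value
        up = [est(0.0, 0.1), est(0.3, 0.2), est(0.9, 0.4)]
        down = [est(-0.0, 0.1), est(-0.3, 0.2), est(-0.9, 0.4)]
        assert begg_test(down).z == pytest.approx(-begg_test(up).z)
        assert begg_test(down).kendall_tau == pytest.approx(-1.0)

    def test_no_signal_with_ties(self):
        estimates = [est(0.2, 0.1)] * 3
        res = begg_test(estimates)
        assert res.kendall_tau == 0.0
        assert res.z == 0.0 and res.p_value == pytest.approx(1.0)

    def test_needs_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            begg_test([est(0.1, 0.1), est(0.2, 0.2)])


def _deviates(estimates):
    theta = np.array([e.log_or for e in estimates])
    var = np.array([e.se_log_or for e in estimates]) ** 2
    w = 1 / var
    pooled = (w * theta).sum() / w.sum()
    return (theta - pooled) / np.sqrt(var - 1 / w.sum())


class TestFunnel:
    def test_one_row_per_estimate(self, by_snp):
        estimates = [odds_ratio(build_contrast(s, ContrastKind.RECESSIVE))
                     for s in by_snp["rs987107"]]
        table = funnel_data(estimates)
        assert len(table) == 6
        assert np.allclose(table["or"], np.exp([e.log_or for e in estimates]))
        assert np.allclose(table["inverse_se"] * table["se_log_or"], 1.0)


class TestPower:
    def test_null_effect_gives_alpha_over_two(self):
        spec = PowerSpec(n_cases=500, n_controls=500, p0=0.2, psi=1.0)
        assert power_two_proportion(spec) == pytest.approx(0.025, abs=0.001)

    def test_monotone_in_sample_size_and_effect(self):
        base = dict(p0=0.1, psi=1.4)
        powers_n = [power_two_proportion(PowerSpec(n, n, **base))
                    for n in (200, 800, 3200, 12800)]
        assert powers_n == sorted(powers_n)
        assert powers_n[-1] > 0.99
        powers_psi = [power_two_proportion(
            PowerSpec(1000, 1000, p0=0.1, psi=psi)) for psi in (1.1, 1.3, 1.6, 2.2)]
        assert powers_psi == sorted(powers_psi)
        # protective effects of equal magnitude give comparable power
        assert power_two_proportion(PowerSpec(1000, 1000, p0=0.5, psi=1 / 1.5)) == \
            pytest.approx(power_two_proportion(PowerSpec(1000, 1000, p0=0.5, psi=1.5)),
                          abs=1e-9)

    def test_pooled_recessive_comparison_has_full_power(self, by_snp):
        studies = by_snp["rs987107"]
        p0 = sum(s.ctrl_mm for s in studies) / sum(s.n_controls for s in studies)
        spec = PowerSpec(n_cases=sum(s.n_cases for s in studies),
                         n_controls=sum(s.n_controls for s in studies),
                         p0=p0, psi=1.44)
        assert power_two_proportion(spec) > 0.99

    def test_degenerate_p0(self):
        with pytest.raises(DegenerateInputError):
            PowerSpec(n_cases=10, n_controls=10, p0=0.0, psi=1.5)
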