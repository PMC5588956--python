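"""Transition models: Weibull cycle probabilities, period conversion,
statin effect, secondary-event equations, substate allocation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from primrose_sim.transitions import (EffectParameters, ReachModel,
                                      SubstateTable, TransitionConfigError,
                                      WeibullSurvivalModel, allocate_substate,
                                      apply_statin_effect,
                                      convert_period_probability,
                                      cycle_probability,
                                      default_transition_models,
                                      other_cause_death_probability,
                                      reach_20_month_probability,
                                      secondary_annual_risks)
from primrose_sim.treatment import TreatmentPlan

PATIENT = {"id": 0, "age": 50.3, "sex": "male", "sbp": 128.0}


def _model(alpha, gamma):
    return WeibullSurvivalModel(name="m", alpha=alpha, gamma=gamma)


class TestCycleProbability:
    def test_exponential_constant_hazard(self):
        m = _model(np.log(0.1), 1.0)
        ps = [cycle_probability(m, PATIENT, t) for t in range(1, 11)]
        np.testing.assert_allclose(ps, ps[0])

    def test_closed_form_first_year(self):
        m = _model(np.log(0.1), 1.0)
        assert cycle_probability(m, PATIENT, 1) == pytest.approx(1 - np.exp(-0.1), abs=1e-12)

    def test_telescoping_identity(self):
        """Π_{t=1..10}(1−p_t) = S(10) to 1e-12."""
        m = _model(-2.3, 1.37)
        prod = np.prod([1 - cycle_probability(m, PATIENT, t) for t in range(1, 11)])
        s10 = float(m.survival(0.0, 10.0))
        assert prod == pytest.approx(s10, abs=1e-12)

    def test_invalid_shape_rejected(self):
        with pytest.raises(TransitionConfigError):
            _model(-2.0, 0.0)

    def test_other_cause_death_same_form(self):
        m = _model(-3.0, 1.4)
        assert other_cause_death_probability(m, PATIENT, 3) == pytest.approx(
            cycle_probability(m, PATIENT, 3))

    def test_inverse_cdf_sampling_oracle(self):
        """Event-time simulation via inverse-CDF Weibull draws reproduces the
        per-year conditional probabilities within 3·SE (10^5 draws)."""
        rng = np.random.default_rng(2024)
        for alpha, gamma in ((-2.6, 0.8), (-3.1, 1.3)):
            m = _model(alpha, gamma)
            lam = np.exp(alpha)
            n = 100_000
            u = rng.random(n)
            times = (-np.log(u) / lam) ** (1 / gamma)   # inverse CDF of S(t)
            for t in (1, 2, 5, 10):
                at_risk = (times > t - 1).sum()
                events = ((times > t - 1) & (times <= t)).sum()
                p_hat = events / at_risk
                p = cycle_probability(m, PATIENT, t)
                se = np.sqrt(p * (1 - p) / at_risk)
                assert abs(p_hat - p) < 3 * se + 1e-12

    @settings(max_examples=60, deadline=None)
    @given(alpha=st.floats(-8, 0), gamma=st.floats(0.2, 4), t=st.integers(1, 10))
    def test_probability_in_unit_interval(self, alpha, gamma, t):
        assert 0.0 <= cycle_probability(_model(alpha, gamma), PATIENT, t) <= 1.0


class TestStatinEffect:
    NEW = TreatmentPlan("new_statin", 21.0, True)
    UC = TreatmentPlan("usual_care", 0.0, False)

    def test_full_adherence_relative_risks(self):
        eff = EffectParameters()
        p_chd, p_cva = apply_statin_effect(0.10, 0.10, self.NEW, eff)
        assert p_chd == pytest.approx(0.073)
        assert p_cva == pytest.approx(0.078)

    def test_usual_care_unchanged(self):
        eff = EffectParameters()
        assert apply_statin_effect(0.10, 0.20, self.UC, eff) == (0.10, 0.20)

    def test_partial_adherence_linear_mixing(self):
        eff = EffectParameters(adherence=0.5)
        p_chd, _ = apply_statin_effect(0.10, 0.10, self.NEW, eff)
        assert p_chd == pytest.approx(0.0865)

    def test_never_increases_and_rr1_is_identity(self):
        eff1 = EffectParameters(rr_chd=1.0, rr_stroke=1.0)
        assert apply_statin_effect(0.3, 0.4, self.NEW, eff1) == (0.3, 0.4)
        eff = EffectParameters()
        p_chd, p_cva = apply_statin_effect(0.3, 0.4, self.NEW, eff)
        assert p_chd <= 0.3 and p_cva <= 0.4

    def test_invalid_parameters_rejected(self):
        with pytest.raises(TransitionConfigError):
            EffectParameters(rr_chd=1.5)
        with pytest.raises(TransitionConfigError):
            EffectParameters(adherence=-0.1)


class TestPeriodConversion:
    def test_zero_maps_to_zero(self):
        assert convert_period_probability(0.0, 20, 12) == 0.0

    def test_twenty_to_twelve_month_closed_form(self):
        assert convert_period_probability(0.3, 20, 12) == pytest.approx(
            1 - 0.7 ** 0.6, abs=1e-12)

    def test_round_trip_identity(self):
        p12 = convert_period_probability(0.3, 20, 12)
        assert convert_period_probability(p12, 12, 20) == pytest.approx(0.3, abs=1e-12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            convert_period_probability(1.0, 20, 12)

    @settings(max_examples=50, deadline=None)
    @given(p=st.floats(0, 0.999), q=st.floats(0, 0.999))
    def test_order_preserving(self, p, q):
        lo, hi = sorted((p, q))
        assert (convert_period_probability(lo, 20, 12)
                <= convert_period_probability(hi, 20, 12))


class TestSecondaryRisks:
    def test_intercept_only_closed_form(self):
        """All betas zero: p20 = expit(intercept); conversion gives
        0.5 → 1 − 0.5^0.6."""
        reach = ReachModel(name="r", intercept_event=0.0, intercept_fatal=-20.0)
        p_nonfatal, p_fatal = secondary_annual_risks(PATIENT, reach)
        assert reach_20_month_probability(0.0, 0.0) == pytest.approx(0.5)
        expected = 1 - 0.5 ** 0.6
        assert p_nonfatal + p_fatal == pytest.approx(expected, rel=1e-9)

    def test_fixed_assumption_covariates_never_contribute(self):
        base = ReachModel(name="r", intercept_event=-1.0, intercept_fatal=-2.0)
        loaded = ReachModel(name="r", intercept_event=-1.0, intercept_fatal=-2.0,
                            coefficients_event={"chf": 5.0, "af": 2.0, "aspirin": -3.0,
                                                "vascular_beds": 1.0},
                            coefficients_fatal={"chf": 4.0},
                            centering={"vascular_beds": 1.0})
        assert secondary_annual_risks(PATIENT, loaded) == pytest.approx(
            secondary_annual_risks(PATIENT, base))

    def test_monotone_in_fatal_intercept(self):
        lo = ReachModel(name="r", intercept_event=-1.0, intercept_fatal=-3.0)
        hi = ReachModel(name="r", intercept_event=-1.0, intercept_fatal=-2.0)
        assert secondary_annual_risks(PATIENT, hi)[1] > secondary_annual_risks(PATIENT, lo)[1]

    def test_missing_covariate_named(self):
        reach = ReachModel(name="reachy", intercept_event=0.0, intercept_fatal=0.0,
                           coefficients_event={"creatinine": 0.1})
        with pytest.raises(KeyError, match="creatinine.*reachy"):
            secondary_annual_risks(PATIENT, reach)


class TestSubstates:
    def test_degenerate_table_always_mi(self):
        table = SubstateTable(
            chd={"stable_angina": 0, "unstable_angina": 0, "mi": 1.0,
                 "surgery": 0, "unclassified_chd": 0},
            cva={"tia": 1.0, "haemorrhagic_stroke": 0, "ischaemic_stroke": 0,
                 "unspecified_cva": 0},
            fatal_chd=0.1, fatal_cva=0.1,
            secondary_nonfatal={"secondary_mi": 1.0, "secondary_stroke": 0.0})
        rng = np.random.default_rng(0)
        assert all(allocate_substate("chd", table, rng) == "mi" for _ in range(20))

    def test_secondary_fatal_default_equal_split(self):
        table = default_transition_models()["substates"]
        assert table.secondary_fatal == {"secondary_mi": 0.5, "secondary_stroke": 0.5}

    def test_invalid_proportions_rejected(self):
        with pytest.raises(TransitionConfigError):
            SubstateTable(
                chd={"stable_angina": 0.5, "unstable_angina": 0.4, "mi": 0.4,
                     "surgery": 0, "unclassified_chd": 0},
                cva={"tia": 1.0, "haemorrhagic_stroke": 0, "ischaemic_stroke": 0,
                     "unspecified_cva": 0},
                fatal_chd=0.1, fatal_cva=0.1,
                secondary_nonfatal={"secondary_mi": 1.0, "secondary_stroke": 0.0})

    def test_allocation_frequencies_chi_square(self):
        """10^5 draws against the table pass a chi-square GoF at p > 0.001."""
        table = default_transition_models()["substates"]
        rng = np.random.default_rng(5)
        draws = [allocate_substate("chd", table, rng) for _ in range(100_000)]
        levels, probs = table.probs("chd")
        observed = np.array([draws.count(l) for l in levels])
        _, pval = stats.chisquare(observed, probs * len(draws))
        assert pval > 0.001
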