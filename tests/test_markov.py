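import math

import numpy as np
import pytest

from albuscreen import (
    ModelParameters,
    STATES,
    build_transition,
    discount_factor,
    initial_distribution,
    run_markov,
    total_cost_qalys,
)
from albuscreen.markov import TransitionConsistencyError


def frozen_params(**overrides) -> ModelParameters:
    """Parameters with every stochastic flow switched off, for limit checks."""
    base = dict(
        general_mortality=0.0,
        rr_ckd_mortality=1.0,
        rrr_treatment=0.0,
        discontinue_first_cycle=0.0,
        discontinue_annual=0.0,
        p_fn_redetect=0.0,
        p_progress_symptomatic=0.0,
        p_fp_revert=0.0,
        p_recover=0.0,
        discount_rate=0.0,
        utility_ckd=1.0,
        charge_initial_screen=False,
    )
    base.update(overrides)
    return ModelParameters(**base)


class TestInitialDistribution:
    def test_single_morning_sample_positive_mass(self):
        """Prevalence 82/157 with sens 1 and spec 52/75 puts (82+23)/157 of the
        cohort into treated states, matching the decision-tree arithmetic."""
        v = initial_distribution(82 / 157, (1.0, 52 / 75))
        treated = v[STATES.index("pos_treated_true")] + v[STATES.index("pos_treated_false")]
        assert treated == pytest.approx(105 / 157)
        assert v.sum() == pytest.approx(1.0)

    def test_perfect_test_positive_mass_is_prevalence(self):
        v = initial_distribution(0.3, (1.0, 1.0))
        assert v[STATES.index("pos_treated_true")] == pytest.approx(0.3)
        assert v[STATES.index("pos_treated_false")] == 0.0

    def test_zero_prevalence_positive_mass_is_fp_rate(self):
        v = initial_distribution(0.0, (0.9, 0.8))
        assert v[STATES.index("pos_treated_false")] == pytest.approx(0.2)

    def test_undefined_validity_rejected(self):
        from albuscreen import ConfusionTable, validity_metrics

        degenerate = validity_metrics(ConfusionTable(tp=0, fp=0, tn=5, fn=0))
        with pytest.raises(ValueError):
            initial_distribution(0.5, degenerate)


class TestBuildTransition:
    def test_all_flows_zero_gives_identity(self):
        P = build_transition(frozen_params(), 1)
        assert np.allclose(P, np.eye(len(STATES)))

    def test_rows_stochastic_at_defaults(self):
        P = build_transition(ModelParameters(p_fn_redetect=0.9), 1)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_untreated_case_death_rate_composition(self):
        """Rate-based composition: p = 1-(1-p0)^RR, checked against a closed
        form evaluated independently of the matrix construction."""
        params = ModelParameters(
            general_mortality=0.0119, rr_ckd_mortality=1.63, rrr_treatment=0.0,
            p_fn_redetect=0.0,
        )
        P = build_transition(params, 1)
        expected = 1.0 - (1.0 - 0.0119) ** 1.63
        i, j = STATES.index("neg_false"), STATES.index("dead")
        assert P[i, j] == pytest.approx(expected, abs=1e-15)
        # multiplicative alternative
        P2 = build_transition(params.with_(mortality_composition="multiplicative"), 1)
        assert P2[i, j] == pytest.approx(0.0119 * 1.63, abs=1e-15)

    def test_first_cycle_discontinuation_rule(self):
        params = ModelParameters(p_fn_redetect=0.9)
        i = STATES.index("pos_treated_true")
        j = STATES.index("pos_discontinued")
        _, _, p_treated = params.death_probabilities()
        p1 = build_transition(params, 1)[i, j]
        p2 = build_transition(params, 2)[i, j]
        assert p1 == pytest.approx((1 - p_treated) * 0.25)
        assert p2 == pytest.approx((1 - p_treated) * 0.02)

    def test_redetected_false_negatives_face_entry_discontinuation(self):
        params = frozen_params(p_fn_redetect=1.0, discontinue_first_cycle=0.25)
        P = build_transition(params, 5)
        i = STATES.index("neg_false")
        assert P[i, STATES.index("pos_treated_true")] == pytest.approx(0.75)
        assert P[i, STATES.index("pos_discontinued")] == pytest.approx(0.25)

    def test_dead_absorbing(self):
        P = build_transition(ModelParameters(p_fn_redetect=0.5), 3)
        i = STATES.index("dead")
        assert P[i, i] == 1.0

    def test_unresolved_redetect_rejected(self):
        with pytest.raises(ValueError, match="p_fn_redetect"):
            build_transition(ModelParameters(), 1)


class TestRunMarkov:
    def test_null_limit_total_qalys_equal_horizon(self):
        """No death, no transitions, utility 1 everywhere, no discounting:
        total QALYs are exactly the 30-year horizon."""
        trace = run_markov(frozen_params(), (0.9, 0.8), "DAY1")
        assert trace.total_qalys == pytest.approx(30.0, abs=1e-12)

    def test_discounted_constant_accrual_matches_geometric_series(self):
        params = frozen_params(discount_rate=0.05)
        trace = run_markov(params, (0.9, 0.8), "DAY1")
        series = sum(1.05**-t for t in range(1, 31))
        assert trace.total_qalys == pytest.approx(series, abs=1e-9)
        # cost side: NEG occupants pay the 24 screening cost each year, the
        # treated states the annual drug cost; occupancies are frozen
        prev = params.prevalence_albuminuria
        neg = prev * (1 - 0.9) + (1 - prev) * 0.8  # neg_false + neg_true
        assert trace.total_cost == pytest.approx(
            (neg * 24.0 + (1 - neg) * 2867.2) * series, abs=1e-6
        )

    def test_mass_conserved_every_cycle_at_defaults(self, base_params):
        trace = run_markov(base_params, (77 / 82, 61 / 75), "DAY1_RANDOM_DAY2")
        occ = trace.occupancy().sum(axis=1).to_numpy()
        assert np.abs(occ - 1.0).max() < 1e-9
        assert len(trace.trace) == 31  # allocation + 30 cycles

    def test_dead_occupancy_monotone(self, base_params):
        trace = run_markov(base_params, (1.0, 52 / 75), "DAY1")
        dead = trace.trace["dead"].to_numpy()
        assert (np.diff(dead) >= -1e-15).all()

    @pytest.mark.parametrize("field,values", [
        ("discount_rate", (0.0, 0.03, 0.05, 0.10)),
        ("general_mortality", (0.005, 0.0119, 0.03, 0.08)),
    ])
    def test_total_qalys_monotone_decreasing(self, base_params, field, values):
        totals = [
            run_markov(base_params.with_(**{field: v}), (1.0, 52 / 75), "DAY1").total_qalys
            for v in values
        ]
        assert totals == sorted(totals, reverse=True)

    def test_validity_is_only_inter_strategy_difference(self):
        """With perfect tests, no treatment effect and identical screening
        costs, all four strategies produce identical traces."""
        params = ModelParameters(
            rrr_treatment=0.0,
            screening_costs={s: 24.0 for s in ("DAY1", "RANDOM", "DAY1_RANDOM", "DAY1_RANDOM_DAY2")},
        )
        traces = [
            run_markov(params, (1.0, 1.0), s).trace
            for s in ("DAY1", "RANDOM", "DAY1_RANDOM", "DAY1_RANDOM_DAY2")
        ]
        for other in traces[1:]:
            assert np.allclose(traces[0].to_numpy(), other.to_numpy())

    def test_null_disease_model_effects_independent_of_validity(self):
        """With RR=1, no treatment effect and CKD utility 1, life-years do not
        depend on the screening test at all."""
        params = ModelParameters(
            rr_ckd_mortality=1.0, rrr_treatment=0.0, utility_ckd=1.0, p_fn_redetect=0.5
        )
        q = [
            run_markov(params, validity, "DAY1").total_qalys
            for validity in ((1.0, 1.0), (0.9, 0.5), (0.5, 0.9))
        ]
        assert q[0] == pytest.approx(q[1]) and q[1] == pytest.approx(q[2])

    def test_totals_fast_path_agrees_with_trace(self, base_params):
        for s, validity in [("DAY1", (1.0, 52 / 75)), ("RANDOM", (79 / 82, 35 / 75))]:
            trace = run_markov(base_params, validity, s)
            cost, qalys = total_cost_qalys(base_params, validity, s)
            assert cost == pytest.approx(trace.total_cost, rel=1e-12)
            assert qalys == pytest.approx(trace.total_qalys, rel=1e-12)

    def test_half_cycle_correction_is_noop_without_flows(self):
        a = run_markov(frozen_params(), (0.9, 0.8), "DAY1").total_qalys
        b = run_markov(frozen_params(half_cycle_correction=True), (0.9, 0.8), "DAY1").total_qalys
        assert a == pytest.approx(b)

    def test_unknown_strategy_cost_rejected(self, base_params):
        with pytest.raises(KeyError, match="GOLD"):
            run_markov(base_params, (1.0, 1.0), "GOLD")


class TestDiscountFactor:
    def test_zero_rate_is_one(self):
        assert all(discount_factor(0.0, t) == 1.0 for t in range(5))

    def test_convention_anchor(self):
        assert discount_factor(0.05, 0) == 1.0
        assert discount_factor(0.05, 1) == pytest.approx(1 / 1.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(utility_ckd=1.2)
    with pytest.raises(ValueError):
        ModelParameters(rr_ckd_mortality=0.8)
    with pytest.raises(ValueError):
        ModelParameters(discontinue_first_cycle=-0.1)
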