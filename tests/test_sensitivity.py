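import math

import numpy as np
import pandas as pd
import pytest

from albuscreen import (
    ModelParameters,
    ParameterDistribution,
    ceac,
    default_distributions,
    one_way_tornado,
    parameterize_distribution,
    run_psa,
    total_cost_qalys,
)
from albuscreen.sensitivity import TABLE_COUNTS, default_validity_inputs

RNG = lambda: np.random.default_rng(1234)


class TestParameterizeDistribution:
    def test_fixed_family_constant(self):
        s = parameterize_distribution(ParameterDistribution("x", "fixed", 3.5))
        assert (s.draw(RNG(), 100) == 3.5).all()

    def test_lognormal_relative_risk_median(self):
        """Lognormal from the (1.5, 1.77) CI: sample median e^mu = 1.63
        within 1% at n=100,000, and the 2.5/97.5 percentiles near the CI."""
        spec = ParameterDistribution("rr", "lognormal", 1.63, low=1.5, high=1.77)
        x = parameterize_distribution(spec).draw(RNG(), 100_000)
        assert np.median(x) == pytest.approx(1.63, rel=0.01)
        lo, hi = np.percentile(x, [2.5, 97.5])
        assert lo == pytest.approx(1.5, rel=0.05)
        assert hi == pytest.approx(1.77, rel=0.05)

    def test_gamma_cost_mean(self):
        spec = ParameterDistribution("c", "gamma", 34205.0, pm_fraction=0.25)
        x = parameterize_distribution(spec).draw(RNG(), 100_000)
        assert x.mean() == pytest.approx(34205.0, rel=0.01)
        assert (x > 0).all()

    def test_beta_utility_mean(self):
        spec = ParameterDistribution("u", "beta", 0.899, pm_absolute=0.145)
        x = parameterize_distribution(spec).draw(RNG(), 100_000)
        assert x.mean() == pytest.approx(0.899, abs=0.005)
        assert ((0 < x) & (x < 1)).all()

    def test_one_minus_transform_keeps_rrr_in_unit_interval(self):
        spec = ParameterDistribution(
            "rrr", "lognormal", 1 - 0.24, low=0.63, high=0.92,
            transform="one_minus", bounds=(0.0, 1.0),
        )
        sampler = parameterize_distribution(spec)
        x = sampler.draw(RNG(), 100_000)
        assert ((0 <= x) & (x <= 1)).all()
        assert np.median(x) == pytest.approx(0.24, abs=0.005)

    def test_truncation_counted(self):
        spec = ParameterDistribution("p", "lognormal", 0.9, pm_fraction=0.25, bounds=(0.0, 1.0))
        sampler = parameterize_distribution(spec)
        sampler.draw(RNG(), 10_000)
        assert sampler.truncated > 0

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            parameterize_distribution(
                ParameterDistribution("u", "beta", 0.5, pm_absolute=0.49 * 1.96 * 2)
            )

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            parameterize_distribution(ParameterDistribution("x", "gamma", 1.0, low=2.0, high=2.0))

    def test_spread_specification_exclusive(self):
        with pytest.raises(ValueError, match="only one"):
            ParameterDistribution("x", "gamma", 1.0, low=0.5, high=1.5, pm_fraction=0.25)


class TestTornado:
    def test_zero_influence_parameter_sorted_last(self, base_params):
        ranges = {
            "screening_costs.RANDOM": (18.0, 30.0),  # not in the pair
            "ckd_annual_cost": (34205.0 * 0.75, 34205.0 * 1.25),
            "rrr_treatment": (0.08, 0.37),
        }
        table = one_way_tornado(base_params, ranges, ("DAY1", "DAY1_RANDOM_DAY2"))
        assert table.iloc[-1]["parameter"] == "screening_costs.RANDOM"
        assert table.iloc[-1]["inmb_swing"] == pytest.approx(0.0, abs=1e-9)
        assert (table["inmb_swing"].to_numpy()[:-1] >= table["inmb_swing"].to_numpy()[1:]).all()

    def test_swing_reproduces_direct_model_evaluations(self, base_params):
        """The treatment-efficacy row equals two direct re-runs of the model
        at the bounds, performed here independently."""
        table = one_way_tornado(
            base_params, {"rrr_treatment": (0.08, 0.37)}, ("DAY1", "DAY1_RANDOM_DAY2")
        )
        row = table.iloc[0]
        validity = default_validity_inputs()
        for bound, suffix in ((0.08, "low"), (0.37, "high")):
            p = base_params.with_(rrr_treatment=bound)
            c0, e0 = total_cost_qalys(
                p, (82 / 82, 52 / 75), "DAY1"
            )
            c1, e1 = total_cost_qalys(p, (77 / 82, 61 / 75), "DAY1_RANDOM_DAY2")
            assert row[f"incr_cost_{suffix}"] == pytest.approx(c1 - c0)
            assert row[f"incr_effect_{suffix}"] == pytest.approx(e1 - e0)

    def test_discounting_monotone_for_every_strategy(self, base_params):
        for s, ct in default_validity_inputs().items():
            validity = (ct.tp / (ct.tp + ct.fn), ct.tn / (ct.tn + ct.fp))
            q0 = total_cost_qalys(base_params.with_(discount_rate=0.0), validity, s)[1]
            q10 = total_cost_qalys(base_params.with_(discount_rate=0.10), validity, s)[1]
            assert q0 > q10

    def test_degenerate_range_equals_base_case(self, base_params):
        table = one_way_tornado(
            base_params, {"utility_ckd": (0.899, 0.899)}, ("DAY1", "DAY1_RANDOM_DAY2")
        )
        assert table.iloc[0]["inmb_low"] == pytest.approx(table.attrs["base_inmb"])
        assert table.iloc[0]["inmb_swing"] == pytest.approx(0.0, abs=1e-9)

    def test_unknown_parameter_rejected(self, base_params):
        with pytest.raises(KeyError, match="not_a_parameter"):
            one_way_tornado(base_params, {"not_a_parameter": (0, 1)}, ("DAY1", "RANDOM"))


class TestRunPsa:
    def test_all_fixed_equals_deterministic_base(self, base_params):
        dists = {
            "utility_ckd": ParameterDistribution("utility_ckd", "fixed", base_params.utility_ckd)
        }
        table = run_psa(
            base_params, dists, n_iterations=3, seed=0, sample_validity=False
        )
        for s, ct in default_validity_inputs().items():
            expected = total_cost_qalys(
                base_params, (ct.tp / (ct.tp + ct.fn), ct.tn / (ct.tn + ct.fp)), s
            )
            rows = table[table.strategy == s]
            assert np.allclose(rows["cost"], expected[0])
            assert np.allclose(rows["effect"], expected[1])

    def test_deterministic_given_seed(self, base_params):
        a = run_psa(base_params, n_iterations=50, seed=99)
        b = run_psa(base_params, n_iterations=50, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_psa_mean_near_deterministic_at_means(self, base_params):
        """For the near-linear cost parameters the PSA mean converges to the
        deterministic value at the distribution means."""
        table = run_psa(base_params, n_iterations=1500, seed=5, sample_validity=False)
        for s, ct in default_validity_inputs().items():
            det_cost, det_eff = total_cost_qalys(
                base_params, (ct.tp / (ct.tp + ct.fn), ct.tn / (ct.tn + ct.fp)), s
            )
            rows = table[table.strategy == s]
            assert rows["cost"].mean() == pytest.approx(det_cost, rel=0.03)
            assert rows["effect"].mean() == pytest.approx(det_eff, rel=0.01)

    def test_common_random_numbers_within_draw(self, base_params):
        table = run_psa(base_params, n_iterations=20, seed=7)
        assert set(table.groupby("iteration").size()) == {4}


class TestCeac:
    def test_single_strategy_always_accepted(self):
        psa = pd.DataFrame(
            {"iteration": [0, 1], "strategy": ["A", "A"], "cost": [1.0, 2.0], "effect": [1.0, 1.1]}
        )
        curves = ceac(psa, [0, 50_000])
        assert (curves["A"] == 1.0).all()

    def test_dominant_strategy_in_every_draw(self):
        rows = []
        for i in range(10):
            rows.append((i, "cheap_good", 100.0 + i, 10.0))
            rows.append((i, "dear_bad", 200.0 + i, 9.0))
        psa = pd.DataFrame(rows, columns=["iteration", "strategy", "cost", "effect"])
        curves = ceac(psa, [0, 1e4, 1e5])
        assert (curves["cheap_good"] == 1.0).all()
        assert (curves["dear_bad"] == 0.0).all()

    def test_hand_built_draws_match_bruteforce(self):
        draws = [
            (0, {"A": (100, 1.0), "B": (150, 1.2)}),
            (1, {"A": (100, 1.3), "B": (150, 1.2)}),
            (2, {"A": (200, 1.0), "B": (150, 1.0)}),
            (3, {"A": (100, 1.0), "B": (150, 1.1)}),
        ]
        rows = [
            (i, s, c, e) for i, d in draws for s, (c, e) in d.items()
        ]
        psa = pd.DataFrame(rows, columns=["iteration", "strategy", "cost", "effect"])
        wtp = 1000.0
        wins = {"A": 0.0, "B": 0.0}
        for _, d in draws:
            nmb = {s: wtp * e - c for s, (c, e) in d.items()}
            best = max(nmb.values())
            tied = [s for s in nmb if nmb[s] == best]
            for s in tied:
                wins[s] += 1 / len(tied) / len(draws)
        curves = ceac(psa, [wtp])
        assert curves.loc[wtp, "A"] == pytest.approx(wins["A"])
        assert curves.loc[wtp, "B"] == pytest.approx(wins["B"])

    def test_acceptabilities_sum_to_one(self, base_params):
        psa = run_psa(base_params, n_iterations=100, seed=2)
        curves = ceac(psa, np.arange(0, 2e5, 2e4))
        assert np.allclose(curves.sum(axis=1), 1.0)

    def test_empty_grid_rejected(self, base_params):
        psa = run_psa(base_params, n_iterations=5, seed=2)
        with pytest.raises(ValueError):
            ceac(psa, [])
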