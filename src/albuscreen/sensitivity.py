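"""One-way (tornado) and probabilistic sensitivity analysis, plus CEACs.

Parameter uncertainty follows the conventional families for each kind of
input: lognormal for mortality and relative risks, gamma for costs, beta for
utilities. Stated ranges are read as 95% intervals:

* lognormal — median at the central value, sigma = (ln(high) - ln(low)) / (2 * 1.96);
  a "+/- f" spread is first expanded to (central*(1-f), central*(1+f));
* gamma — moment-matched to mean = central and sd = half-range / 1.96;
* beta — moment-matched to mean = central and sd = half-width / 1.96
  (infeasible mean/sd combinations are rejected with a diagnostic).

The treatment relative-risk-reduction is sampled on the relative-risk scale
(RR = 1 - RRR, lognormal over the RR confidence interval) so that draws stay
inside (0, 1). Probability-type draws are truncated into [0, 1]; truncation
events are counted on the sampler.

The PSA additionally samples each strategy's sensitivity and specificity from
Jeffreys Beta posteriors of its cohort-study confusion counts — without this
source of uncertainty the acceptability curves would be degenerate 0/1 steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cea import net_monetary_benefit
from .markov import ModelParameters, total_cost_qalys
from .validity import CEA_STRATEGIES, ConfusionTable

__all__ = [
    "ParameterDistribution",
    "Sampler",
    "parameterize_distribution",
    "default_distributions",
    "default_validity_inputs",
    "TABLE_COUNTS",
    "one_way_tornado",
    "run_psa",
    "ceac",
]

#: Confusion counts of each strategy in the cohort study (vs the three-month
#: gold standard, n=157), the validity inputs of the economic model.
TABLE_COUNTS: Mapping[str, ConfusionTable] = {
    "DAY1": ConfusionTable(tp=82, fp=23, tn=52, fn=0),
    "RANDOM": ConfusionTable(tp=79, fp=40, tn=35, fn=3),
    "DAY1_RANDOM": ConfusionTable(tp=79, fp=18, tn=57, fn=3),
    "DAY1_DAY2": ConfusionTable(tp=79, fp=17, tn=58, fn=3),
    "DAY1_RANDOM_DAY2": ConfusionTable(tp=77, fp=14, tn=61, fn=5),
}


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty specification for one model parameter.

    Exactly one spread form applies: an explicit (low, high) range, or a
    ``pm_fraction`` (+/- f of the central value), or ``pm_absolute`` (+/- a).
    ``transform="one_minus"`` samples x from the stated distribution and
    returns 1 - x. ``bounds`` truncates draws (with counting).
    """

    name: str
    family: str  # lognormal | gamma | beta | fixed
    central: float
    low: Optional[float] = None
    high: Optional[float] = None
    pm_fraction: Optional[float] = None
    pm_absolute: Optional[float] = None
    transform: Optional[str] = None
    bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if (self.low is None) != (self.high is None):
            raise ValueError(f"{self.name}: low and high must be given together")
        n_forms = sum(
            x is not None for x in (self.low, self.pm_fraction, self.pm_absolute)
        )
        if n_forms > 1:
            raise ValueError(f"{self.name}: give only one of (low, high) / pm_fraction / pm_absolute")
        if self.family != "fixed" and n_forms == 0:
            raise ValueError(f"{self.name}: a spread specification is required")
        if self.transform not in (None, "one_minus"):
            raise ValueError(f"{self.name}: unknown transform {self.transform!r}")

    def range_bounds(self) -> Tuple[float, float]:
        """The stated (low, high) range, expanding +/- forms."""
        if self.low is not None and self.high is not None:
            return self.low, self.high
        if self.pm_fraction is not None:
            return self.central * (1 - self.pm_fraction), self.central * (1 + self.pm_fraction)
        if self.pm_absolute is not None:
            return self.central - self.pm_absolute, self.central + self.pm_absolute
        raise ValueError(f"{self.name}: no range specified")


class Sampler:
    """Deterministic-given-seed sampler for one parameter."""

    def __init__(
        self,
        name: str,
        draw: Callable[[np.random.Generator, int], np.ndarray],
        transform: Optional[str] = None,
        bounds: Optional[Tuple[float, float]] = None,
    ):
        self.name = name
        self._draw = draw
        self._transform = transform
        self._bounds = bounds
        self.truncated = 0  # number of draws clipped into bounds so far

    def draw(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        x = np.asarray(self._draw(rng, size), dtype=float)
        if self._transform == "one_minus":
            x = 1.0 - x
        if self._bounds is not None:
            lo, hi = self._bounds
            out = np.clip(x, lo, hi)
            self.truncated += int(np.sum(out != x))
            x = out
        return x


def parameterize_distribution(spec: ParameterDistribution) -> Sampler:
    """Build a sampler from a distribution spec (see module docstring)."""
    c = spec.central
    if spec.family == "fixed":
        return Sampler(spec.name, lambda rng, n: np.full(n, c), spec.transform, spec.bounds)

    lo, hi = spec.range_bounds()
    if not (lo < hi):
        raise ValueError(f"{spec.name}: degenerate range ({lo}, {hi})")

    if spec.family == "lognormal":
        if lo <= 0 or c <= 0:
            raise ValueError(f"{spec.name}: lognormal requires positive central/low values")
        mu = math.log(c)
        sigma = (math.log(hi) - math.log(lo)) / (2 * 1.96)
        return Sampler(
            spec.name, lambda rng, n: rng.lognormal(mu, sigma, n), spec.transform, spec.bounds
        )

    if spec.family == "gamma":
        sd = (hi - lo) / (2 * 1.96)
        if c <= 0 or sd <= 0:
            raise ValueError(f"{spec.name}: gamma requires positive mean and spread")
        shape = (c / sd) ** 2
        scale = sd**2 / c
        return Sampler(
            spec.name, lambda rng, n: rng.gamma(shape, scale, n), spec.transform, spec.bounds
        )

    # beta
    sd = (hi - lo) / (2 * 1.96)
    if not (0 < c < 1):
        raise ValueError(f"{spec.name}: beta mean must lie in (0, 1), got {c}")
    if sd**2 >= c * (1 - c):
        raise ValueError(
            f"{spec.name}: infeasible beta moments (mean {c}, sd {sd:.4f}): "
            f"need sd^2 < mean*(1-mean) = {c * (1 - c):.4f}"
        )
    nu = c * (1 - c) / sd**2 - 1
    a, b = c * nu, (1 - c) * nu
    return Sampler(spec.name, lambda rng, n: rng.beta(a, b, n), spec.transform, spec.bounds)


def default_distributions(params: ModelParameters) -> dict[str, ParameterDistribution]:
    """The standard uncertainty set: one entry per uncertain model input.

    Mortality lognormal +/-25%; CKD-mortality RR lognormal over (1.5, 1.77);
    treatment RRR lognormal on the RR scale over (0.63, 0.92); every cost
    gamma +/-25%; CKD utility beta with half-width 0.145. The four
    assumption-based transition probabilities have no stated uncertainty and
    stay fixed unless the caller adds entries for them.
    """
    d: dict[str, ParameterDistribution] = {
        "general_mortality": ParameterDistribution(
            "general_mortality", "lognormal", params.general_mortality,
            pm_fraction=0.25, bounds=(0.0, 1.0),
        ),
        "rr_ckd_mortality": ParameterDistribution(
            "rr_ckd_mortality", "lognormal", params.rr_ckd_mortality, low=1.5, high=1.77,
            bounds=(1.0, math.inf),
        ),
        "rrr_treatment": ParameterDistribution(
            "rrr_treatment", "lognormal",
            central=1.0 - params.rrr_treatment,
            low=1.0 - 0.37, high=1.0 - 0.08,
            transform="one_minus", bounds=(0.0, 1.0),
        ),
        "ras_inhibitor_annual_cost": ParameterDistribution(
            "ras_inhibitor_annual_cost", "gamma", params.ras_inhibitor_annual_cost,
            pm_fraction=0.25,
        ),
        "ckd_annual_cost": ParameterDistribution(
            "ckd_annual_cost", "gamma", params.ckd_annual_cost, pm_fraction=0.25
        ),
        "utility_ckd": ParameterDistribution(
            "utility_ckd", "beta", params.utility_ckd, pm_absolute=0.145, bounds=(0.0, 1.0)
        ),
    }
    for name, cost in params.screening_costs.items():
        d[f"screening_costs.{name}"] = ParameterDistribution(
            f"screening_costs.{name}", "gamma", cost, pm_fraction=0.25
        )
    return d


def default_validity_inputs() -> dict[str, ConfusionTable]:
    """Cohort-study confusion counts for the strategies in the economic model."""
    return {s: TABLE_COUNTS[s] for s in CEA_STRATEGIES}


def _set_param(params: ModelParameters, name: str, value: float) -> ModelParameters:
    if name.startswith("screening_costs."):
        strategy = name.split(".", 1)[1]
        costs = dict(params.screening_costs)
        if strategy not in costs:
            raise KeyError(f"unknown screening-cost entry {strategy!r}")
        costs[strategy] = float(value)
        return params.with_(screening_costs=costs)
    if not hasattr(params, name):
        raise KeyError(f"unknown model parameter {name!r}")
    return params.with_(**{name: float(value)})


def _strategy_validity(
    validity: Mapping[str, Union[ConfusionTable, Tuple[float, float]]], strategy: str
) -> Tuple[float, float]:
    v = validity[strategy]
    if isinstance(v, ConfusionTable):
        return v.tp / (v.tp + v.fn), v.tn / (v.tn + v.fp)
    return float(v[0]), float(v[1])


def one_way_tornado(
    base_params: ModelParameters,
    param_ranges: Optional[Mapping[str, Tuple[float, float]]] = None,
    strategy_pair: Tuple[str, str] = ("DAY1", "DAY1_RANDOM_DAY2"),
    validity: Optional[Mapping[str, Union[ConfusionTable, Tuple[float, float]]]] = None,
    wtp: Optional[float] = None,
) -> pd.DataFrame:
    """One-way sensitivity analysis of the (comparator, intervention) pair.

    Each parameter is set to its low and high bound in turn (others at base);
    the model is re-run deterministically and the incremental cost, effect,
    ICER and incremental NMB of intervention vs comparator recorded. Rows are
    sorted by the absolute incremental-NMB swing, largest first. Default
    ranges come from :func:`default_distributions`; pass ``param_ranges`` to
    vary a custom set (e.g. ``{"discount_rate": (0.0, 0.10)}``).
    """
    if validity is None:
        validity = default_validity_inputs()
    if wtp is None:
        wtp = base_params.wtp_threshold
    if param_ranges is None:
        param_ranges = {}
        for name, spec in default_distributions(base_params).items():
            lo, hi = spec.range_bounds()
            if spec.transform == "one_minus":  # range stated on the complementary scale
                lo, hi = 1.0 - hi, 1.0 - lo
            if spec.bounds is not None:  # keep inputs inside the parameter's domain
                lo, hi = max(lo, spec.bounds[0]), min(hi, spec.bounds[1])
            param_ranges[name] = (lo, hi)
        param_ranges["discount_rate"] = (0.0, 0.10)
    ref, alt = strategy_pair

    def evaluate(params: ModelParameters):
        c0, e0 = total_cost_qalys(params, _strategy_validity(validity, ref), ref)
        c1, e1 = total_cost_qalys(params, _strategy_validity(validity, alt), alt)
        d_c, d_e = c1 - c0, e1 - e0
        icer = d_c / d_e if d_e != 0 else math.nan
        return d_c, d_e, icer, wtp * d_e - d_c

    base_out = evaluate(base_params)
    rows = []
    for name, (lo, hi) in param_ranges.items():
        if not (lo <= hi):
            raise ValueError(f"{name}: low bound {lo} exceeds high bound {hi}")
        out_lo = evaluate(_set_param(base_params, name, lo))
        out_hi = evaluate(_set_param(base_params, name, hi))
        rows.append(
            {
                "parameter": name,
                "low_input": lo,
                "high_input": hi,
                "incr_cost_low": out_lo[0],
                "incr_cost_high": out_hi[0],
                "incr_effect_low": out_lo[1],
                "incr_effect_high": out_hi[1],
                "icer_low": out_lo[2],
                "icer_high": out_hi[2],
                "inmb_low": out_lo[3],
                "inmb_high": out_hi[3],
                "inmb_swing": abs(out_hi[3] - out_lo[3]),
            }
        )
    df = pd.DataFrame(rows).sort_values("inmb_swing", ascending=False, ignore_index=True)
    df.attrs["strategy_pair"] = strategy_pair
    df.attrs["base_incr_cost"], df.attrs["base_incr_effect"] = base_out[0], base_out[1]
    df.attrs["base_icer"], df.attrs["base_inmb"] = base_out[2], base_out[3]
    return df


def run_psa(
    base_params: ModelParameters,
    dists: Optional[Mapping[str, ParameterDistribution]] = None,
    validity: Optional[Mapping[str, Union[ConfusionTable, Tuple[float, float]]]] = None,
    n_iterations: int = 1000,
    seed: int = 0,
    strategies: Sequence[str] = CEA_STRATEGIES,
    sample_validity: bool = True,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis.

    Each draw jointly samples all parameter distributions (independently),
    plus — when ``sample_validity`` and confusion counts are supplied — each
    strategy's sensitivity and specificity from Jeffreys Beta posteriors of
    its counts. All strategies are evaluated on the same draw (common random
    numbers). Returns a long table (iteration, strategy, cost, effect).
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    if dists is None:
        dists = default_distributions(base_params)
    if validity is None:
        validity = default_validity_inputs()
    rng = np.random.default_rng(seed)
    samplers = {name: parameterize_distribution(spec) for name, spec in dists.items()}
    draws = {name: s.draw(rng, n_iterations) for name, s in samplers.items()}

    val_draws: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in strategies:
        v = validity[s]
        if sample_validity and isinstance(v, ConfusionTable):
            sens = rng.beta(v.tp + 0.5, v.fn + 0.5, n_iterations)
            spec = rng.beta(v.tn + 0.5, v.fp + 0.5, n_iterations)
        else:
            sv, sp = _strategy_validity({s: v}, s)
            sens = np.full(n_iterations, sv)
            spec = np.full(n_iterations, sp)
        val_draws[s] = (sens, spec)

    records = []
    for i in range(n_iterations):
        params = base_params
        for name in draws:
            params = _set_param(params, name, draws[name][i])
        for s in strategies:
            cost, effect = total_cost_qalys(params, (val_draws[s][0][i], val_draws[s][1][i]), s)
            records.append((i, s, cost, effect))
    table = pd.DataFrame(records, columns=["iteration", "strategy", "cost", "effect"])
    table.attrs["seed"] = seed
    table.attrs["truncated"] = {name: s.truncated for name, s in samplers.items() if s.truncated}
    return table


def ceac(psa_table: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from a PSA table.

    For each willingness-to-pay value, the acceptability of a strategy is the
    fraction of draws in which it attains the maximal net monetary benefit
    (ties split equally among the tied strategies), so columns sum to 1.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if len(psa_table) == 0:
        raise ValueError("psa_table is empty")
    wide_cost = psa_table.pivot(index="iteration", columns="strategy", values="cost")
    wide_eff = psa_table.pivot(index="iteration", columns="strategy", values="effect")
    strategies = list(wide_cost.columns)
    n = len(wide_cost)
    cost = wide_cost.to_numpy()
    eff = wide_eff.to_numpy()

    rows = []
    for wtp in wtp_grid:
        nmb = wtp * eff - cost
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        rows.append({"wtp": wtp, **dict(zip(strategies, weights.mean(axis=0)))})
    return pd.DataFrame(rows).set_index("wtp")
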