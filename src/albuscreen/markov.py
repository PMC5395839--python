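"""Hybrid decision-tree / Markov cohort model of albuminuria screening.

A screened population is allocated by a one-shot decision tree — prevalence of
persistent albuminuria times each strategy's sensitivity and specificity —
into the initial states of a Markov cohort model, which is then run in annual
cycles over a 30-year horizon, accruing discounted costs (screening, RAS
inhibitor treatment, symptomatic CKD care) and quality-adjusted life years.

The published model has four health states (Negative urine test, Positive
urine test / treated, Symptomatic CKD, Dead). Four states cannot
simultaneously carry truth status (is the occupant actually a persistent
case?), treatment status and discontinuation, all of which change mortality
and cost, so the engine expands them into seven substates and reports the
four-state aggregate:

    neg_true            truly negative, screened annually
    neg_false           undetected persistent case (false negative)
    pos_treated_true    detected case on ACEI/ARB
    pos_treated_false   false positive on ACEI/ARB
    pos_discontinued    detected case who stopped treatment (never restarts)
    symptomatic         symptomatic CKD (stage 3-5 care costs)
    dead                absorbing

Mortality: non-cases die at the general annual probability p0; untreated and
symptomatic cases at the CKD-mortality relative risk RR; treated cases at
RR*(1-RRR) where RRR is the relative risk reduction of treatment. Relative
risks compose on the survival-rate scale by default, p = 1-(1-p0)^RR, which
keeps probabilities in [0,1] for any RR (a plain multiplicative rule is
available via ``mortality_composition``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .validity import ValidityMetrics

__all__ = [
    "STATES",
    "ModelParameters",
    "CohortTrace",
    "initial_distribution",
    "build_transition",
    "run_markov",
    "total_cost_qalys",
    "discount_factor",
]

STATES = (
    "neg_true",
    "neg_false",
    "pos_treated_true",
    "pos_treated_false",
    "pos_discontinued",
    "symptomatic",
    "dead",
)
_IX = {s: i for i, s in enumerate(STATES)}

#: Per-round screening cost (¥) of each strategy carried into the model.
DEFAULT_SCREENING_COSTS: Mapping[str, float] = {
    "DAY1": 24.0,
    "RANDOM": 24.0,
    "DAY1_RANDOM": 48.0,
    "DAY1_RANDOM_DAY2": 72.0,
}

#: Parameters whose values are modelling choices, not study-reported inputs.
NON_PAPER_PARAMETERS = (
    "prevalence_albuminuria",
    "p_fn_redetect",
    "p_progress_symptomatic",
    "p_fp_revert",
    "p_recover",
)


class TransitionConsistencyError(RuntimeError):
    """Raised when a constructed transition row fails stochasticity."""


@dataclass(frozen=True)
class ModelParameters:
    """All model inputs: study-reported values plus documented assumptions.

    Reported inputs (annual general mortality 0.0119; CKD mortality relative
    risk 1.63; treatment relative risk reduction 0.24; screening costs
    ¥24/24/48/72 per round; RAS-inhibitor cost ¥2867.2/yr; symptomatic CKD
    care ¥34205/yr; CKD utility 0.899 against background 1.0; 5% discounting;
    30 one-year cycles; 25% first-cycle then 2% annual treatment
    discontinuation; WTP ¥100,000/QALY) keep their reported defaults.

    The four per-cycle transition probabilities and the population prevalence
    of albuminuria are NOT study-reported (see ``NON_PAPER_PARAMETERS``);
    their defaults are modelling choices documented in the methods note.
    ``p_fn_redetect=None`` means "use the strategy's own sensitivity at the
    annual retest".
    """

    general_mortality: float = 0.0119
    rr_ckd_mortality: float = 1.63
    rrr_treatment: float = 0.24
    screening_costs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCREENING_COSTS)
    )
    ras_inhibitor_annual_cost: float = 2867.2
    ckd_annual_cost: float = 34205.0
    utility_ckd: float = 0.899
    utility_background: float = 1.0
    discount_rate: float = 0.05
    horizon_years: int = 30
    cycle_length_years: float = 1.0
    discontinue_first_cycle: float = 0.25
    discontinue_annual: float = 0.02
    wtp_threshold: float = 100_000.0
    # --- non-paper assumptions ---
    prevalence_albuminuria: float = 0.095
    p_fn_redetect: Optional[float] = None
    p_progress_symptomatic: float = 0.10
    p_fp_revert: float = 0.10
    p_recover: float = 0.05
    # --- numerical / timing conventions ---
    mortality_composition: str = "rate"  # "rate": 1-(1-p0)^RR; "multiplicative": p0*RR
    half_cycle_correction: bool = False
    charge_initial_screen: bool = True

    def __post_init__(self) -> None:
        probs = {
            "general_mortality": self.general_mortality,
            "discontinue_first_cycle": self.discontinue_first_cycle,
            "discontinue_annual": self.discontinue_annual,
            "prevalence_albuminuria": self.prevalence_albuminuria,
            "p_progress_symptomatic": self.p_progress_symptomatic,
            "p_fp_revert": self.p_fp_revert,
            "p_recover": self.p_recover,
            "rrr_treatment": self.rrr_treatment,
        }
        if self.p_fn_redetect is not None:
            probs["p_fn_redetect"] = self.p_fn_redetect
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
        for name in ("utility_ckd", "utility_background"):
            u = getattr(self, name)
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {u!r}")
        for name in ("ras_inhibitor_annual_cost", "ckd_annual_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(c < 0 for c in self.screening_costs.values()):
            raise ValueError("screening costs must be >= 0")
        if self.rr_ckd_mortality < 1.0:
            raise ValueError(f"rr_ckd_mortality must be >= 1, got {self.rr_ckd_mortality!r}")
        if self.discount_rate < 0:
            raise ValueError(f"discount_rate must be >= 0, got {self.discount_rate!r}")
        if self.horizon_years < 1:
            raise ValueError(f"horizon_years must be >= 1, got {self.horizon_years!r}")
        if self.mortality_composition not in ("rate", "multiplicative"):
            raise ValueError("mortality_composition must be 'rate' or 'multiplicative'")

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def death_probabilities(self) -> Tuple[float, float, float]:
        """(non-case, untreated case, treated case) annual death probabilities."""
        p0, rr, rrr = self.general_mortality, self.rr_ckd_mortality, self.rrr_treatment
        if self.mortality_composition == "rate":
            p_case = 1.0 - (1.0 - p0) ** rr
            p_treated = 1.0 - (1.0 - p0) ** (rr * (1.0 - rrr))
        else:
            p_case = min(1.0, p0 * rr)
            p_treated = min(1.0, p0 * rr * (1.0 - rrr))
        return p0, p_case, p_treated


def discount_factor(rate: float, t: int) -> float:
    """Discount multiplier (1+rate)^-t for a reward accrued at end of cycle t."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate!r}")
    if t < 0:
        raise ValueError(f"cycle index must be >= 0, got {t!r}")
    return (1.0 + rate) ** -t


def _resolve_validity(validity: Union[ValidityMetrics, Tuple[float, float]]) -> Tuple[float, float]:
    if isinstance(validity, ValidityMetrics):
        sens, spec = validity.sensitivity, validity.specificity
    else:
        sens, spec = validity
    if sens is None or spec is None:
        raise ValueError("strategy validity has undefined sensitivity or specificity")
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError(f"sensitivity/specificity must lie in [0, 1], got {(sens, spec)}")
    return float(sens), float(spec)


def initial_distribution(
    prevalence: float, validity: Union[ValidityMetrics, Tuple[float, float]]
) -> np.ndarray:
    """Decision-tree allocation of the screened population to initial states.

    True cases (prevalence) split by sensitivity into treated detections and
    undetected false negatives; non-cases split by specificity into true
    negatives and treated false positives.
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence!r}")
    sens, spec = _resolve_validity(validity)
    v = np.zeros(len(STATES))
    v[_IX["pos_treated_true"]] = prevalence * sens
    v[_IX["neg_false"]] = prevalence * (1.0 - sens)
    v[_IX["neg_true"]] = (1.0 - prevalence) * spec
    v[_IX["pos_treated_false"]] = (1.0 - prevalence) * (1.0 - spec)
    return v


def build_transition(params: ModelParameters, cycle_index: int) -> np.ndarray:
    """Row-stochastic annual transition matrix for the given cycle (1-based).

    Cycle 1 applies the first-cycle treatment discontinuation (25% by
    default, dominated by early side effects); later cycles the smaller
    annual noncompliance loss. ``params.p_fn_redetect`` must be resolved to a
    number before calling (``run_markov`` substitutes the strategy
    sensitivity when it is None).
    """
    if cycle_index < 1:
        raise ValueError(f"cycle_index is 1-based, got {cycle_index!r}")
    if params.p_fn_redetect is None:
        raise ValueError(
            "p_fn_redetect is unresolved (None); supply a value or call via run_markov"
        )
    p0, p_case, p_treated = params.death_probabilities()
    d = params.discontinue_first_cycle if cycle_index == 1 else params.discontinue_annual
    redetect = params.p_fn_redetect
    prog = params.p_progress_symptomatic

    P = np.zeros((len(STATES), len(STATES)))

    def put(src: str, **dest: float) -> None:
        row = P[_IX[src]]
        for state, p in dest.items():
            row[_IX[state]] += p
        total = row.sum()
        if abs(total - 1.0) > 1e-12 or (row < -1e-15).any():
            raise TransitionConsistencyError(
                f"transition row {src!r} not stochastic (sum={total!r})"
            )

    s = 1.0 - p0
    put("neg_true", dead=p0, neg_true=s)

    # Redetected false negatives start treatment and immediately face the
    # first-treatment-year side-effect discontinuation (it follows treatment
    # start, not the calendar cycle); thereafter the annual loss applies.
    s = 1.0 - p_case
    d0 = params.discontinue_first_cycle
    put(
        "neg_false",
        dead=p_case,
        pos_treated_true=s * redetect * (1.0 - d0),
        pos_discontinued=s * redetect * d0,
        symptomatic=s * (1.0 - redetect) * prog,
        neg_false=s * (1.0 - redetect) * (1.0 - prog),
    )

    s = 1.0 - p_treated
    put(
        "pos_treated_true",
        dead=p_treated,
        pos_discontinued=s * d,
        neg_true=s * (1.0 - d) * params.p_recover,
        pos_treated_true=s * (1.0 - d) * (1.0 - params.p_recover),
    )

    # False positives are not cases: general mortality, and whether they
    # revert at retest or discontinue the drug they end up simply negative.
    s = 1.0 - p0
    exit_to_neg = params.p_fp_revert + (1.0 - params.p_fp_revert) * d
    put(
        "pos_treated_false",
        dead=p0,
        neg_true=s * exit_to_neg,
        pos_treated_false=s * (1.0 - exit_to_neg),
    )

    s = 1.0 - p_case
    put(
        "pos_discontinued",
        dead=p_case,
        symptomatic=s * prog,
        pos_discontinued=s * (1.0 - prog),
    )

    s = 1.0 - p_case
    put("symptomatic", dead=p_case, symptomatic=s)

    put("dead", dead=1.0)
    return P


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy and reward accruals for one strategy.

    ``trace`` has one row per cycle 0..horizon: the seven occupancies (state
    at the end of the cycle; cycle 0 is the decision-tree allocation) and the
    cycle's undiscounted/discounted cost and QALY accruals. Cycle 0 carries
    the initial screening charge when enabled, and no QALY accrual.
    """

    strategy: str
    trace: pd.DataFrame

    @property
    def total_cost(self) -> float:
        """Cumulative discounted cost (¥ per screened person)."""
        return float(self.trace["cost_discounted"].sum())

    @property
    def total_qalys(self) -> float:
        """Cumulative discounted quality-adjusted life years."""
        return float(self.trace["qaly_discounted"].sum())

    def occupancy(self) -> pd.DataFrame:
        return self.trace[list(STATES)]


def run_markov(
    params: ModelParameters,
    validity: Union[ValidityMetrics, Tuple[float, float]],
    strategy: str,
) -> CohortTrace:
    """Run the cohort model for one strategy over the full horizon.

    ``validity`` supplies the strategy's (sensitivity, specificity) — either
    a :class:`~albuscreen.validity.ValidityMetrics` or a bare pair. Rewards
    accrue at cycle end on the post-transition occupancy and are discounted
    by (1+r)^-t (optionally averaged with the start-of-cycle occupancy when
    ``half_cycle_correction`` is on).
    """
    sens, spec = _resolve_validity(validity)
    if params.p_fn_redetect is None:
        params = params.with_(p_fn_redetect=sens)
    try:
        screen_cost = params.screening_costs[strategy]
    except KeyError:
        raise KeyError(
            f"no screening cost configured for strategy {strategy!r}; "
            f"known: {sorted(params.screening_costs)}"
        ) from None

    cost_vec, qaly_vec = _reward_vectors(params, screen_cost)

    v = initial_distribution(params.prevalence_albuminuria, (sens, spec))
    P1 = build_transition(params, 1)
    P_rest = build_transition(params, 2) if params.horizon_years > 1 else None

    rows = []
    init_cost = screen_cost if params.charge_initial_screen else 0.0
    rows.append(
        dict(zip(STATES, v))
        | {
            "cycle": 0,
            "cost": init_cost,
            "qaly": 0.0,
            "cost_discounted": init_cost,
            "qaly_discounted": 0.0,
        }
    )
    for t in range(1, params.horizon_years + 1):
        P = P1 if t == 1 else P_rest
        v_next = v @ P
        reward_occ = 0.5 * (v + v_next) if params.half_cycle_correction else v_next
        df = discount_factor(params.discount_rate, t)
        cost = float(reward_occ @ cost_vec)
        qaly = float(reward_occ @ qaly_vec) * params.cycle_length_years
        rows.append(
            dict(zip(STATES, v_next))
            | {
                "cycle": t,
                "cost": cost,
                "qaly": qaly,
                "cost_discounted": cost * df,
                "qaly_discounted": qaly * df,
            }
        )
        v = v_next

    trace = pd.DataFrame(rows).set_index("cycle")
    trace["cum_cost_discounted"] = trace["cost_discounted"].cumsum()
    trace["cum_qaly_discounted"] = trace["qaly_discounted"].cumsum()
    return CohortTrace(strategy=strategy, trace=trace)


def _reward_vectors(params: ModelParameters, screen_cost: float) -> Tuple[np.ndarray, np.ndarray]:
    cost_vec = np.zeros(len(STATES))
    cost_vec[_IX["neg_true"]] = screen_cost
    cost_vec[_IX["neg_false"]] = screen_cost
    cost_vec[_IX["pos_treated_true"]] = params.ras_inhibitor_annual_cost
    cost_vec[_IX["pos_treated_false"]] = params.ras_inhibitor_annual_cost
    cost_vec[_IX["symptomatic"]] = params.ckd_annual_cost
    qaly_vec = np.zeros(len(STATES))
    qaly_vec[_IX["neg_true"]] = params.utility_background
    qaly_vec[_IX["pos_treated_false"]] = params.utility_background
    for case_state in ("neg_false", "pos_treated_true", "pos_discontinued", "symptomatic"):
        qaly_vec[_IX[case_state]] = params.utility_ckd
    return cost_vec, qaly_vec


def total_cost_qalys(
    params: ModelParameters,
    validity: Union[ValidityMetrics, Tuple[float, float]],
    strategy: str,
) -> Tuple[float, float]:
    """Discounted (total_cost, total_qalys) without materialising the trace.

    Identical arithmetic to :func:`run_markov`; used in the inner loop of the
    probabilistic sensitivity analysis where only the totals matter.
    """
    sens, spec = _resolve_validity(validity)
    if params.p_fn_redetect is None:
        params = params.with_(p_fn_redetect=sens)
    screen_cost = params.screening_costs[strategy]
    cost_vec, qaly_vec = _reward_vectors(params, screen_cost)

    v = initial_distribution(params.prevalence_albuminuria, (sens, spec))
    P1 = build_transition(params, 1)
    P_rest = build_transition(params, 2) if params.horizon_years > 1 else None

    total_cost = screen_cost if params.charge_initial_screen else 0.0
    total_qaly = 0.0
    df = 1.0
    inv = 1.0 / (1.0 + params.discount_rate)
    for t in range(1, params.horizon_years + 1):
        v_next = v @ (P1 if t == 1 else P_rest)
        occ = 0.5 * (v + v_next) if params.half_cycle_correction else v_next
        df *= inv
        total_cost += float(occ @ cost_vec) * df
        total_qaly += float(occ @ qaly_vec) * params.cycle_length_years * df
        v = v_next
    return total_cost, total_qaly
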