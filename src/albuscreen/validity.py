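"""Screening strategies, confusion tables and diagnostic validity metrics.

Persistent albuminuria is diagnosed by the gold standard: urinary
albumin-to-creatinine ratio (ACR) >= 30 mg/g creatinine on the day-1,
month-2 and month-3 first-morning samples. The five candidate screening
strategies are conjunctions over subsets of the five collected samples; a
strategy calls a patient positive iff every required sample is at or above
the threshold.

Validity metrics are the standard 2x2 proportions (sensitivity, specificity,
PPV, NPV, accuracy, false-positive and false-negative rates), with exact
Clopper-Pearson 95% confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord

__all__ = [
    "StrategyDefinition",
    "STRATEGIES",
    "CEA_STRATEGIES",
    "GOLD",
    "ConfusionTable",
    "ValidityMetrics",
    "apply_strategy",
    "strategy_positive",
    "build_confusion",
    "validity_metrics",
    "validity_table",
    "clopper_pearson",
    "compute_egfr",
    "format_percent",
]

_SAMPLES = ("day1", "random", "day2", "month2", "month3")


@dataclass(frozen=True)
class StrategyDefinition:
    """A screening rule: positive iff all required samples have ACR >= threshold."""

    name: str
    required_samples: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.required_samples:
            raise ValueError(f"strategy {self.name!r}: required_samples must be non-empty")
        unknown = set(self.required_samples) - set(_SAMPLES)
        if unknown:
            raise ValueError(f"strategy {self.name!r}: unknown sample(s) {sorted(unknown)}")

    @property
    def columns(self) -> Tuple[str, ...]:
        return tuple(f"acr_{s}" for s in self.required_samples)


GOLD = StrategyDefinition("GOLD", ("day1", "month2", "month3"))

#: The five candidate strategies plus the gold standard, keyed by name.
STRATEGIES: dict[str, StrategyDefinition] = {
    s.name: s
    for s in (
        StrategyDefinition("DAY1", ("day1",)),
        StrategyDefinition("RANDOM", ("random",)),
        StrategyDefinition("DAY1_RANDOM", ("day1", "random")),
        StrategyDefinition("DAY1_DAY2", ("day1", "day2")),
        StrategyDefinition("DAY1_RANDOM_DAY2", ("day1", "random", "day2")),
        GOLD,
    )
}

#: Strategies carried into the economic model. DAY1_DAY2 is excluded (no
#: validity advantage over DAY1_RANDOM at a longer diagnosis window) and so is
#: the gold standard (a reference classification, not a screening option).
CEA_STRATEGIES = ("DAY1", "RANDOM", "DAY1_RANDOM", "DAY1_RANDOM_DAY2")


def apply_strategy(
    strategy: StrategyDefinition,
    patient: Union[PatientRecord, Mapping[str, float]],
    threshold: float = 30.0,
) -> bool:
    """Classify one patient: True iff every required sample's ACR >= threshold."""
    for col in strategy.columns:
        try:
            value = patient[col]
        except (KeyError, AttributeError) as exc:
            raise KeyError(
                f"strategy {strategy.name!r} requires sample {col!r}, missing from patient"
            ) from exc
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise KeyError(f"strategy {strategy.name!r} requires sample {col!r}, got missing value")
        if value < threshold:
            return False
    return True


def strategy_positive(
    cohort: pd.DataFrame, strategy: StrategyDefinition, threshold: float = 30.0
) -> np.ndarray:
    """Vectorised strategy call over a cohort table (boolean array)."""
    missing = [c for c in strategy.columns if c not in cohort.columns]
    if missing:
        raise KeyError(
            f"strategy {strategy.name!r} requires column(s) {missing} absent from cohort"
        )
    values = cohort[list(strategy.columns)].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"strategy {strategy.name!r}: cohort contains missing ACR values")
    return np.all(values >= threshold, axis=1)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a strategy against the gold standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def build_confusion(
    cohort: pd.DataFrame, strategy: StrategyDefinition, threshold: float = 30.0
) -> ConfusionTable:
    """Cross-classify a strategy against the gold standard on the same records."""
    if len(cohort) == 0:
        raise ValueError("cannot build a confusion table from an empty cohort")
    test = strategy_positive(cohort, strategy, threshold)
    gold = strategy_positive(cohort, GOLD, threshold)
    return ConfusionTable(
        tp=int(np.sum(test & gold)),
        fp=int(np.sum(test & ~gold)),
        tn=int(np.sum(~test & ~gold)),
        fn=int(np.sum(~test & gold)),
    )


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Bounds are beta-distribution quantiles:
    lower = Beta(alpha/2; k, n-k+1), upper = Beta(1-alpha/2; k+1, n-k),
    with lower = 0 at k = 0 and upper = 1 at k = n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, n={n}], got {successes}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


@dataclass(frozen=True)
class ValidityMetrics:
    """Diagnostic-validity proportions (fractions in [0, 1]) with exact CIs.

    A metric whose denominator is zero is ``None`` (undefined), never NaN.
    """

    counts: ConfusionTable
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    false_positive_rate: Optional[float]
    false_negative_rate: Optional[float]
    ci_sensitivity: Optional[Tuple[float, float]]
    ci_specificity: Optional[Tuple[float, float]]
    ci_fp_rate: Optional[Tuple[float, float]]
    ci_fn_rate: Optional[Tuple[float, float]]


def validity_metrics(ct: ConfusionTable, alpha: float = 0.05) -> ValidityMetrics:
    """Compute the five standard validity proportions plus FP/FN rates and CIs.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), accuracy = (TP+TN)/N; the FP and FN rates are the
    complements of specificity and sensitivity respectively.
    """
    pos = ct.tp + ct.fn  # gold-standard positives
    neg = ct.tn + ct.fp
    called_pos = ct.tp + ct.fp
    called_neg = ct.tn + ct.fn

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    sens = ratio(ct.tp, pos)
    spec = ratio(ct.tn, neg)
    return ValidityMetrics(
        counts=ct,
        sensitivity=sens,
        specificity=spec,
        ppv=ratio(ct.tp, called_pos),
        npv=ratio(ct.tn, called_neg),
        accuracy=(ct.tp + ct.tn) / ct.total,
        false_positive_rate=None if spec is None else 1.0 - spec,
        false_negative_rate=None if sens is None else 1.0 - sens,
        ci_sensitivity=clopper_pearson(ct.tp, pos, alpha) if pos > 0 else None,
        ci_specificity=clopper_pearson(ct.tn, neg, alpha) if neg > 0 else None,
        ci_fp_rate=clopper_pearson(ct.fp, neg, alpha) if neg > 0 else None,
        ci_fn_rate=clopper_pearson(ct.fn, pos, alpha) if pos > 0 else None,
    )


def format_percent(fraction: Optional[float], decimals: int = 1) -> str:
    """Render a fraction as a percentage string, half-up at `decimals` places."""
    if fraction is None:
        return "undefined"
    quantum = Decimal(1).scaleb(-decimals)
    return str(Decimal(fraction * 100).quantize(quantum, rounding=ROUND_HALF_UP))


def validity_table(
    cohort: pd.DataFrame,
    strategies: Sequence[str] = ("DAY1", "RANDOM", "DAY1_RANDOM", "DAY1_DAY2", "DAY1_RANDOM_DAY2"),
    threshold: float = 30.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-strategy validity summary (one row per strategy).

    Columns carry counts, the seven metrics as percentages (full precision),
    and the CI bounds for sensitivity, specificity and the FP/FN rates.
    """
    rows = []
    for name in strategies:
        ct = build_confusion(cohort, STRATEGIES[name], threshold)
        m = validity_metrics(ct, alpha)
        row = {
            "strategy": name,
            "tp": ct.tp,
            "fp": ct.fp,
            "tn": ct.tn,
            "fn": ct.fn,
        }
        for metric in (
            "sensitivity",
            "specificity",
            "ppv",
            "npv",
            "accuracy",
            "false_positive_rate",
            "false_negative_rate",
        ):
            value = getattr(m, metric)
            row[f"{metric}_pct"] = np.nan if value is None else 100.0 * value
        for ci in ("ci_sensitivity", "ci_specificity", "ci_fp_rate", "ci_fn_rate"):
            bounds = getattr(m, ci)
            row[f"{ci}_lo_pct"] = np.nan if bounds is None else 100.0 * bounds[0]
            row[f"{ci}_hi_pct"] = np.nan if bounds is None else 100.0 * bounds[1]
        rows.append(row)
    return pd.DataFrame(rows)


def compute_egfr(
    scr: Optional[float] = None,
    age: float = None,
    female: bool = False,
    scr_umol: Optional[float] = None,
) -> float:
    """Estimated GFR (mL/min/1.73 m^2), Chinese-modified MDRD equation.

    eGFR = 175 * SCr^-1.234 * age^-0.179, times 0.79 if female, with serum
    creatinine (SCr) in mg/dL. Pass ``scr_umol`` instead to supply SCr in
    umol/L (divided by 88.4 first).
    """
    if (scr is None) == (scr_umol is None):
        raise ValueError("provide exactly one of scr (mg/dL) or scr_umol (umol/L)")
    if scr_umol is not None:
        scr = scr_umol / 88.4
    if scr <= 0:
        raise ValueError(f"serum creatinine must be > 0, got {scr!r}")
    if age is None or age <= 0:
        raise ValueError(f"age must be > 0, got {age!r}")
    egfr = 175.0 * scr**-1.234 * age**-0.179
    return egfr * 0.79 if female else egfr
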