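"""Run configuration, validation, orchestration and result serialization.

A run is described by a YAML (or JSON) document with four blocks::

    cohort:
      source: simulate          # or "file"
      path: null                # cohort CSV when source is "file"
      params: {n_patients: 157, seed: 0, ...}   # CohortSimParams overrides
    model:                      # ModelParameters overrides
      discount_rate: 0.05
      screening_costs: {DAY1: 24.0, ...}
    analysis:
      threshold: 30.0
      alpha: 0.05
      comparator: DAY1
      wtp: 100000.0
      wtp_grid: {start: 0.0, stop: 200000.0, step: 5000.0}
      psa_iterations: 1000
      seed: 0
      validity_source: cohort   # or "study": the cohort-study counts
    output_dir: results

Unknown keys are rejected by name; omitted values fall back to documented
defaults, and every assumption-based (non-study) default actually used is
echoed to the log and recorded in the run manifest with its provenance tag.

All randomness derives from ``analysis.seed`` through named substreams, so
the cohort simulation and the PSA are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cea import incremental_analysis
from .cohort import CohortSimParams, generate_cohort, read_cohort, write_cohort
from .markov import NON_PAPER_PARAMETERS, ModelParameters, run_markov
from .sensitivity import (
    TABLE_COUNTS,
    ceac,
    default_distributions,
    one_way_tornado,
    run_psa,
)
from .validity import CEA_STRATEGIES, ConfusionTable, build_confusion, STRATEGIES, validity_table

__all__ = ["RunConfig", "AnalysisSettings", "load_config", "run_all"]

log = logging.getLogger("albuscreen")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass(frozen=True)
class AnalysisSettings:
    threshold: float = 30.0
    alpha: float = 0.05
    comparator: str = "DAY1"
    wtp: float = 100_000.0
    wtp_grid: tuple[float, float, float] = (0.0, 200_000.0, 5_000.0)  # start, stop, step
    psa_iterations: int = 1000
    seed: int = 0
    validity_source: str = "cohort"  # "cohort" | "study"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigError(f"analysis.threshold must be > 0, got {self.threshold}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"analysis.alpha must lie in (0, 1), got {self.alpha}")
        if self.comparator not in CEA_STRATEGIES:
            raise ConfigError(
                f"analysis.comparator must be one of {CEA_STRATEGIES}, got {self.comparator!r}"
            )
        if self.psa_iterations < 1:
            raise ConfigError("analysis.psa_iterations must be >= 1")
        if self.validity_source not in ("cohort", "study"):
            raise ConfigError("analysis.validity_source must be 'cohort' or 'study'")
        start, stop, step = self.wtp_grid
        if not (step > 0 and stop >= start >= 0):
            raise ConfigError(f"analysis.wtp_grid invalid: {self.wtp_grid}")

    def wtp_values(self) -> np.ndarray:
        start, stop, step = self.wtp_grid
        return np.arange(start, stop + step / 2, step)


@dataclass(frozen=True)
class RunConfig:
    cohort_source: str  # "simulate" | "file"
    cohort_path: Optional[str]
    sim_params: CohortSimParams
    model_params: ModelParameters
    analysis: AnalysisSettings
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.cohort_source not in ("simulate", "file"):
            raise ConfigError(f"cohort.source must be 'simulate' or 'file', got {self.cohort_source!r}")
        if self.cohort_source == "file" and not self.cohort_path:
            raise ConfigError("cohort.source is 'file' but cohort.path is missing")
        if self.cohort_source == "simulate" and self.cohort_path:
            raise ConfigError("cohort.path given although cohort.source is 'simulate'")


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def _build_dataclass(cls, overrides: Mapping[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(overrides, names, where)
    try:
        return cls(**overrides)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _substream_seed(master: int, stream: int) -> int:
    """A named child seed of the master seed (stable, < 2**31)."""
    return int(np.random.SeedSequence(master, spawn_key=(stream,)).generate_state(1)[0] % (2**31))


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    _check_keys(raw, {"cohort", "model", "analysis", "output_dir"}, "config")
    cohort_block = dict(raw.get("cohort") or {})
    _check_keys(cohort_block, {"source", "path", "params"}, "cohort")
    source = cohort_block.get("source", "simulate")
    sim_overrides = dict(cohort_block.get("params") or {})

    analysis_block = dict(raw.get("analysis") or {})
    if "wtp_grid" in analysis_block:
        g = analysis_block["wtp_grid"]
        if isinstance(g, Mapping):
            _check_keys(g, {"start", "stop", "step"}, "analysis.wtp_grid")
            analysis_block["wtp_grid"] = (g.get("start", 0.0), g["stop"], g.get("step", 5000.0))
        else:
            analysis_block["wtp_grid"] = tuple(g)
    analysis = _build_dataclass(AnalysisSettings, analysis_block, "analysis")

    # the cohort substream keeps the simulation reproducible independently of
    # the PSA; an explicit cohort.params.seed overrides it
    sim_overrides.setdefault("seed", _substream_seed(analysis.seed, 0))
    sim_params = _build_dataclass(CohortSimParams, sim_overrides, "cohort.params")

    model_block = dict(raw.get("model") or {})
    model_params = _build_dataclass(ModelParameters, model_block, "model")
    for name in NON_PAPER_PARAMETERS:
        if name not in model_block:
            log.warning(
                "model.%s not set; using assumption-based default %r (not a study-reported value)",
                name, getattr(model_params, name),
            )

    return RunConfig(
        cohort_source=source,
        cohort_path=cohort_block.get("path"),
        sim_params=sim_params,
        model_params=model_params,
        analysis=analysis,
        output_dir=str(raw.get("output_dir", "results")),
    )


def config_to_dict(config: RunConfig) -> dict:
    """Normalized plain-dict form of a config (round-trips through YAML)."""
    return {
        "cohort": {
            "source": config.cohort_source,
            "path": config.cohort_path,
            "params": dataclasses.asdict(config.sim_params),
        },
        "model": dataclasses.asdict(config.model_params),
        "analysis": dataclasses.asdict(config.analysis),
        "output_dir": config.output_dir,
    }


def _parameter_provenance(model_params: ModelParameters) -> dict[str, dict]:
    """Per-parameter value + provenance tag for the run manifest."""
    out = {}
    for f in dataclasses.fields(ModelParameters):
        value = getattr(model_params, f.name)
        if isinstance(value, Mapping):
            value = dict(value)
        tag = "assumption" if f.name in NON_PAPER_PARAMETERS else "study"
        if f.name in ("mortality_composition", "half_cycle_correction", "charge_initial_screen"):
            tag = "convention"
        out[f.name] = {"value": value, "provenance": tag}
    return out


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write all outputs to ``output_dir``.

    Stages: cohort (simulate or read) -> validity table -> Markov traces ->
    incremental CEA -> tornado -> PSA + CEAC -> manifest. Returns the in-memory
    results keyed by stage. Any stage failure aborts with the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    stage = "cohort"
    try:
        if config.cohort_source == "simulate":
            cohort = generate_cohort(config.sim_params)
        else:
            cohort = read_cohort(config.cohort_path)
        write_cohort(cohort, outdir / "cohort.csv")
        results["cohort"] = cohort

        stage = "validity"
        vtable = validity_table(
            cohort, threshold=config.analysis.threshold, alpha=config.analysis.alpha
        )
        vtable.to_csv(outdir / "validity.csv", index=False)
        results["validity"] = vtable

        stage = "cea"
        if config.analysis.validity_source == "study":
            counts = {s: TABLE_COUNTS[s] for s in CEA_STRATEGIES}
        else:
            counts = {
                s: build_confusion(cohort, STRATEGIES[s], config.analysis.threshold)
                for s in CEA_STRATEGIES
            }
        validity_pairs = {
            s: (ct.tp / (ct.tp + ct.fn), ct.tn / (ct.tn + ct.fp)) for s, ct in counts.items()
        }
        traces = {
            s: run_markov(config.model_params, validity_pairs[s], s) for s in CEA_STRATEGIES
        }
        trace_long = pd.concat(
            [t.trace.assign(strategy=s) for s, t in traces.items()]
        ).reset_index()
        trace_long.to_csv(outdir / "trace.csv", index=False)
        totals = {s: (t.total_cost, t.total_qalys) for s, t in traces.items()}
        cea_table = incremental_analysis(
            totals, comparator=config.analysis.comparator, wtp=config.analysis.wtp
        )
        cea_table.to_csv(outdir / "cea.csv")
        results["traces"], results["cea"] = traces, cea_table

        stage = "tornado"
        tornado = one_way_tornado(
            config.model_params,
            strategy_pair=(config.analysis.comparator, "DAY1_RANDOM_DAY2"),
            validity=counts,
            wtp=config.analysis.wtp,
        )
        tornado.to_csv(outdir / "tornado.csv", index=False)
        results["tornado"] = tornado

        stage = "psa"
        psa = run_psa(
            config.model_params,
            validity=counts,
            n_iterations=config.analysis.psa_iterations,
            seed=_substream_seed(config.analysis.seed, 1),
        )
        psa.to_csv(outdir / "psa.csv", index=False)
        curves = ceac(psa, config.analysis.wtp_values())
        curves.to_csv(outdir / "ceac.csv")
        results["psa"], results["ceac"] = psa, curves

        stage = "manifest"
        manifest = {
            "package": "albuscreen",
            "version": __version__,
            "seed": config.analysis.seed,
            "substream_seeds": {
                "cohort": config.sim_params.seed,
                "psa": _substream_seed(config.analysis.seed, 1),
            },
            "config": config_to_dict(config),
            "model_parameters": _parameter_provenance(config.model_params),
            "psa_truncated_draws": psa.attrs.get("truncated", {}),
            "outputs": sorted(
                p.name
                for p in outdir.iterdir()
                if p.suffix in (".csv", ".json") and p.name != "manifest.json"
            ),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
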