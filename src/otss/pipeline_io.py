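"""End-to-end orchestration: simulate -> aggregate -> fit -> group stats.

Reproducible study runs over the experiment presets, plus ingestion of
externally deposited trial tables through a column-mapping loader (the
deposit's schema is not standardized, so both column names and response /
order codes are remappable).  Trial tables travel as CSV, fits and study
reports as JSON; every report embeds the resolved configuration, its hash,
the seed, and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_inference import (
    SubjectConditionMatrix,
    posthoc_paired_bonferroni,
    rm_anova_2x2,
    rm_anova_oneway,
)
from .indecision_model import FitOptions, FitResult, ModelParams, fit_model
from .observer_sim import (
    ExperimentDesign,
    RESPONSE_LABELS,
    TRIAL_COLUMNS,
    aggregate_counts,
    counts_records,
    design_preset,
    sample_observer_params,
    simulate_trials,
)

logger = logging.getLogger("otss")

__all__ = [
    "RunConfig",
    "DEFAULT_TRUTH",
    "run_synthetic_study",
    "run_reanalysis",
    "fit_observer_conditions",
    "write_trials_csv",
    "read_trials_csv",
    "apply_column_mapping",
    "write_report",
]

# Group-mean truth presets for synthetic studies, built from the published
# condition means: exp1 marginals iso -8.13 / cross -4.89 and flat -7.1 /
# depth -5.9 with the depth effect confined to the iso conditions; exp2
# marginals -1.5/-0.5 and -1.4/-0.6; exp3 condition means printed directly.
# sigma and the criteria use the standard recovery point (5, -1.5, 2.5).
def _p(mu: float) -> ModelParams:
    return ModelParams(mu=mu, sigma=5.0, delta1=-1.5, delta2=2.5)


DEFAULT_TRUTH: dict[str, dict[str, ModelParams]] = {
    "exp1": {
        "IsoFlat": _p(-9.33),
        "IsoDepth": _p(-6.93),
        "CrossFlat": _p(-4.89),
        "CrossDepth": _p(-4.89),
    },
    "exp2": {
        "IsoFlat": _p(-2.0),
        "IsoNear": _p(-1.0),
        "CrossFlat": _p(-0.8),
        "CrossNear": _p(-0.2),
    },
    "exp3": {"Bump": _p(0.89), "Average": _p(2.1), "Near": _p(1.7)},
    "training": {"test_27.75": _p(0.0), "test_32.25": _p(0.0)},
}

# Post-hoc families mirroring the published comparisons: the depth effect
# within each orientation for the 2x2 experiments; all pairs for exp3.
_POSTHOC: dict[str, list[tuple[str, str]]] = {
    "exp1": [("IsoFlat", "IsoDepth"), ("CrossFlat", "CrossDepth")],
    "exp2": [("IsoFlat", "IsoNear"), ("CrossFlat", "CrossNear")],
    "exp3": [("Bump", "Average"), ("Bump", "Near"), ("Average", "Near")],
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved description of one study run."""

    preset: str = "exp1"
    n_observers: int = 8
    seed: int = 0
    truth: Mapping[str, ModelParams] | None = None  # None -> preset default
    observer_mu_sd: float = 1.0
    fit_options: FitOptions = field(default_factory=FitOptions)
    comparisons: Sequence[tuple[str, str]] | None = None  # None -> preset family

    def resolved_truth(self) -> dict[str, ModelParams]:
        truth = self.truth if self.truth is not None else DEFAULT_TRUTH[self.preset]
        return dict(truth)

    def resolved_comparisons(self) -> list[tuple[str, str]]:
        if self.comparisons is not None:
            return [tuple(c) for c in self.comparisons]
        return list(_POSTHOC.get(self.preset, []))

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "n_observers": self.n_observers,
            "seed": self.seed,
            "truth": {c: p.to_dict() for c, p in self.resolved_truth().items()},
            "observer_mu_sd": self.observer_mu_sd,
            "fit_options": {
                "n_restarts": self.fit_options.n_restarts,
                "seed": self.fit_options.seed,
                "prob_floor": self.fit_options.prob_floor,
                "max_iter": self.fit_options.max_iter,
            },
            "comparisons": [list(c) for c in self.resolved_comparisons()],
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {}
        for key in ("preset", "n_observers", "seed", "observer_mu_sd"):
            if key in raw:
                kwargs[key] = raw[key]
        if "truth" in raw:
            kwargs["truth"] = {c: ModelParams(**p) for c, p in raw["truth"].items()}
        if "fit_options" in raw:
            kwargs["fit_options"] = FitOptions(**raw["fit_options"])
        if "comparisons" in raw:
            kwargs["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        return cls(**kwargs)


def _config_hash(config_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Trial-table files
# ---------------------------------------------------------------------------


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing column(s): {sorted(missing)}")
    return df[list(TRIAL_COLUMNS)]


def apply_column_mapping(raw: pd.DataFrame, mapping: Mapping) -> pd.DataFrame:
    """Normalize an external trial table to the package schema.

    ``mapping`` holds a ``columns`` entry ({our_name: source_name}) and
    optional ``response_codes`` / ``order_codes`` dictionaries translating
    the source file's categorical codes to ``ref_higher/ref_lower/dk`` and
    ``ref_first/ref_second``.  Rows with unknown codes are reported by index
    in the error message.
    """
    cols = dict(mapping.get("columns", {}))
    missing_src = [src for src in cols.values() if src not in raw.columns]
    if missing_src:
        raise ValueError(f"source table lacks mapped column(s): {missing_src}")
    df = pd.DataFrame({ours: raw[src] for ours, src in cols.items()})
    for ours, default in (("observer", "obs01"), ("session", 1), ("trial", None)):
        if ours not in df.columns:
            df[ours] = default if default is not None else np.arange(1, len(df) + 1)
    for key, column, valid in (
        ("response_codes", "response", set(RESPONSE_LABELS)),
        ("order_codes", "order", {"ref_first", "ref_second"}),
    ):
        codes = mapping.get(key)
        if codes:
            df[column] = df[column].map(lambda v: codes.get(v, v))
        bad = ~df[column].isin(valid)
        if bad.any():
            rows = list(df.index[bad][:10])
            raise ValueError(
                f"unknown {column} code(s) {sorted(set(df[column][bad]))} "
                f"in rows {rows}{'...' if bad.sum() > 10 else ''}"
            )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mapping does not resolve required field(s): {sorted(missing)}")
    return df[list(TRIAL_COLUMNS)]


# ---------------------------------------------------------------------------
# Fitting stage
# ---------------------------------------------------------------------------


def fit_observer_conditions(
    trials: pd.DataFrame, fit_options: FitOptions | None = None
) -> dict[str, dict[str, FitResult]]:
    """One indecision-model fit per observer x condition, pooling sessions."""
    out: dict[str, dict[str, FitResult]] = {}
    for obs, obs_trials in trials.groupby("observer"):
        agg = aggregate_counts(obs_trials)
        fits = {}
        for cond in agg["condition"].unique():
            t0 = time.perf_counter()
            fits[cond] = fit_model(counts_records(agg, cond), fit_options)
            logger.info(
                "fit %s/%s: mu=%.3f nll=%.2f converged=%s (%.2fs)",
                obs,
                cond,
                fits[cond].params.mu,
                fits[cond].neg_log_likelihood,
                fits[cond].converged,
                time.perf_counter() - t0,
            )
        out[str(obs)] = fits
    return out


def _group_stage(
    fits: dict[str, dict[str, FitResult]],
    condition_labels: Sequence[str],
    factor_coding: Mapping[str, tuple[str, str]] | None,
    comparisons: Sequence[tuple[str, str]],
) -> dict:
    observers = sorted(fits)
    if len(observers) < 2:
        raise ValueError(
            "group statistics need at least 2 observers (df = n - 1 would be 0)"
        )
    values = np.array(
        [[fits[o][c].params.mu for c in condition_labels] for o in observers]
    )
    matrix = SubjectConditionMatrix(
        values=values,
        condition_labels=tuple(condition_labels),
        observer_labels=tuple(observers),
        factor_coding=factor_coding,
    )
    if factor_coding is not None:
        anova = {k: r.to_dict() for k, r in rm_anova_2x2(matrix).items()}
    else:
        anova = {"condition": rm_anova_oneway(matrix).to_dict()}
    posthoc = [c.to_dict() for c in posthoc_paired_bonferroni(matrix, comparisons)]
    return {
        "condition_means": matrix.condition_means(),
        "condition_sems": matrix.condition_sems(),
        "anova": anova,
        "posthoc": posthoc,
    }


# ---------------------------------------------------------------------------
# End-to-end runs
# ---------------------------------------------------------------------------


def run_synthetic_study(config: RunConfig) -> dict:
    """Simulate a full study and analyze it end to end.

    Per-observer parameters are drawn around the truth means, trials are
    simulated per the design preset, one model fit is run per observer and
    condition, and the group stage produces means +/- SEM, the
    repeated-measures ANOVA, and the post-hoc family.  Deterministic given
    the config (including its seed).
    """
    design = design_preset(config.preset)
    truth_means = config.resolved_truth()
    cfg = config.to_dict()
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    observer_truth = sample_observer_params(
        truth_means,
        config.n_observers,
        seed=int(seeds[0].generate_state(1)[0] % 2**31),
        mu_sd=config.observer_mu_sd,
    )
    t0 = time.perf_counter()
    frames = []
    children = seeds[1].spawn(config.n_observers)
    for (obs, truth), ss in zip(observer_truth.items(), children):
        frames.append(
            simulate_trials(
                design, truth, int(ss.generate_state(1)[0] % 2**31), observer=obs
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    logger.info(
        "simulated %d trials x %d observers (%.2fs)",
        design.total_trials,
        config.n_observers,
        time.perf_counter() - t0,
    )
    fits = fit_observer_conditions(trials, config.fit_options)
    group = _group_stage(
        fits, design.conditions, design.factor_coding, config.resolved_comparisons()
    )
    return {
        "kind": "synthetic_study",
        "version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": config.seed,
        "design": {
            "name": design.name,
            "trials_per_session": design.trials_per_session,
            "total_trials": design.total_trials,
        },
        "truth_means": {c: p.to_dict() for c, p in truth_means.items()},
        "observer_truth_mu": {
            o: {c: p.mu for c, p in t.items()} for o, t in observer_truth.items()
        },
        "fits": {o: {c: f.to_dict() for c, f in fs.items()} for o, fs in fits.items()},
        **group,
    }


def run_reanalysis(
    data_path,
    mapping: Mapping | None,
    config: RunConfig,
    factor_coding: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """Analyze an external trial table: aggregate -> fit -> group stats.

    ``mapping`` (a dict or a YAML file path) translates the source schema;
    when None the file must already use the package schema.  The report adds
    each observer's DK-usage fraction alongside the group results.
    """
    if mapping is not None and not isinstance(mapping, Mapping):
        mapping = yaml.safe_load(Path(mapping).read_text())
    raw = pd.read_csv(data_path)
    trials = apply_column_mapping(raw, mapping) if mapping else read_trials_csv(data_path)
    fits = fit_observer_conditions(trials, config.fit_options)
    conditions = sorted(next(iter(fits.values())))
    dk_usage = {
        str(o): float((g["response"] == "dk").mean())
        for o, g in trials.groupby("observer")
    }
    report: dict = {
        "kind": "reanalysis",
        "version": __version__,
        "source": str(data_path),
        "seed": config.seed,
        "n_trials": int(len(trials)),
        "dk_usage": dk_usage,
        "fits": {o: {c: f.to_dict() for c, f in fs.items()} for o, fs in fits.items()},
    }
    if len(fits) >= 2:
        report.update(
            _group_stage(fits, conditions, factor_coding, config.resolved_comparisons())
        )
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
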