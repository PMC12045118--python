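"""Generative simulation of 2-AFC-DK contrast-judgment experiments.

Provides the balanced trial structures of the training task and the three
main experiments (surround orientation x surround depth designs and the
bump/average/near depth-surface design), and samples categorical responses
from the difference-with-indecision model: on each trial the internal
difference signal D ~ Normal(order-signed (x - mu), sigma) is drawn and the
two-criterion rule applied, so simulated tables have exactly the statistical
structure the analytic psychometric functions describe.

Trial tables are pandas DataFrames with columns
``observer, session, trial, condition, order, ref_contrast, test_contrast,
response`` (responses coded ``ref_higher`` / ``ref_lower`` / ``dk``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .indecision_model import ModelParams, Order, ResponseCounts, StimulusCell

__all__ = [
    "ExperimentDesign",
    "design_preset",
    "PRESET_NAMES",
    "simulate_trials",
    "simulate_observers",
    "sample_observer_params",
    "aggregate_counts",
    "counts_records",
    "veridicality_gate",
    "TRIAL_COLUMNS",
    "RESPONSE_LABELS",
]

TRIAL_COLUMNS = (
    "observer",
    "session",
    "trial",
    "condition",
    "order",
    "ref_contrast",
    "test_contrast",
    "response",
)

RESPONSE_LABELS = ("ref_higher", "ref_lower", "dk")


@dataclass(frozen=True)
class ExperimentDesign:
    """Declarative description of one experiment's balanced trial structure.

    ``test_contrasts`` maps each condition label to the physical contrast of
    its test grating (30% in the main experiments; the training task uses
    two test contrasts, represented as two condition labels).
    ``factor_coding`` maps conditions onto a 2x2 factorial
    (orientation x depth) when the design has one.
    """

    name: str
    reference_contrasts: tuple[float, ...]
    test_contrasts: Mapping[str, float]
    repeats_per_session: int
    n_sessions: int
    factor_coding: Mapping[str, tuple[str, str]] | None = None

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.test_contrasts)

    @property
    def orders(self) -> tuple[Order, Order]:
        return (Order.REF_FIRST, Order.REF_SECOND)

    @property
    def trials_per_session(self) -> int:
        return (
            len(self.reference_contrasts)
            * len(self.conditions)
            * 2
            * self.repeats_per_session
        )

    @property
    def total_trials(self) -> int:
        return self.trials_per_session * self.n_sessions


# Main-experiment reference ladder: 18-34% in steps of 2 plus two easy
# anchors at 14 and 38 -> 11 levels around the 30% test contrast.
_MAIN_LADDER = (14.0,) + tuple(float(c) for c in range(18, 35, 2)) + (38.0,)
# Training ladder: 21-39% in steps of 2.25 -> 9 levels.
_TRAINING_LADDER = tuple(21.0 + 2.25 * i for i in range(9))

_PRESETS: dict[str, ExperimentDesign] = {
    "training": ExperimentDesign(
        name="training",
        reference_contrasts=_TRAINING_LADDER,
        test_contrasts={"test_27.75": 27.75, "test_32.25": 32.25},
        repeats_per_session=12,
        n_sessions=1,
    ),
    "exp1": ExperimentDesign(
        name="exp1",
        reference_contrasts=_MAIN_LADDER,
        test_contrasts={c: 30.0 for c in ("IsoFlat", "IsoDepth", "CrossFlat", "CrossDepth")},
        repeats_per_session=5,
        n_sessions=8,
        factor_coding={
            "IsoFlat": ("iso", "flat"),
            "IsoDepth": ("iso", "depth"),
            "CrossFlat": ("cross", "flat"),
            "CrossDepth": ("cross", "depth"),
        },
    ),
    "exp2": ExperimentDesign(
        name="exp2",
        reference_contrasts=_MAIN_LADDER,
        test_contrasts={c: 30.0 for c in ("IsoFlat", "IsoNear", "CrossFlat", "CrossNear")},
        repeats_per_session=5,
        n_sessions=8,
        factor_coding={
            "IsoFlat": ("iso", "flat"),
            "IsoNear": ("iso", "near"),
            "CrossFlat": ("cross", "flat"),
            "CrossNear": ("cross", "near"),
        },
    ),
    "exp3": ExperimentDesign(
        name="exp3",
        reference_contrasts=_MAIN_LADDER,
        test_contrasts={c: 30.0 for c in ("Bump", "Average", "Near")},
        repeats_per_session=6,
        n_sessions=7,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def design_preset(name: str) -> ExperimentDesign:
    """Return the fully enumerated design for a named experiment preset.

    Repeats per session are derived from the published session totals
    (440 = 11 contrasts x 4 conditions x 2 orders x 5 repeats for the 2x2
    experiments; 396 = 11 x 3 x 2 x 6 for the three-condition experiment).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown design preset {name!r}; valid presets: {sorted(_PRESETS)}"
        ) from None


def simulate_trials(
    design: ExperimentDesign,
    truth: Mapping[str, ModelParams],
    seed: int,
    observer: str = "sim01",
) -> pd.DataFrame:
    """Simulate one observer's full balanced trial table.

    Every (reference contrast, condition, order) cell appears exactly
    ``repeats_per_session`` times per session, in a seeded uniform shuffle;
    responses are sampled from the generative indecision model with the
    condition's true parameters.  Identical seeds give identical tables.
    """
    missing = [c for c in design.conditions if c not in truth]
    if missing:
        raise KeyError(f"truth missing parameters for condition(s): {missing}")
    rng = np.random.default_rng(seed)

    cond_labels = list(design.conditions)
    cond_index = {c: i for i, c in enumerate(cond_labels)}
    mu = np.array([truth[c].mu for c in cond_labels])
    sigma = np.array([truth[c].sigma for c in cond_labels])
    d1 = np.array([truth[c].delta1 for c in cond_labels])
    d2 = np.array([truth[c].delta2 for c in cond_labels])

    base = [
        (cond_index[c], ref, o.sign)
        for c in cond_labels
        for ref in design.reference_contrasts
        for o in design.orders
        for _ in range(design.repeats_per_session)
    ]
    base_arr = np.array(base, dtype=float)

    frames = []
    for session in range(1, design.n_sessions + 1):
        perm = rng.permutation(len(base_arr))
        cells = base_arr[perm]
        ci = cells[:, 0].astype(int)
        ref = cells[:, 1]
        sign = cells[:, 2]
        test = np.array([design.test_contrasts[cond_labels[i]] for i in ci])
        x = ref - test
        d_mean = sign * (x - mu[ci])
        d = d_mean + sigma[ci] * rng.standard_normal(len(cells))
        second_lower = d < d1[ci]
        second_higher = d > d2[ci]
        # map interval-frame outcome to reference frame by order
        ref_second = sign > 0
        response = np.where(
            second_lower,
            np.where(ref_second, "ref_lower", "ref_higher"),
            np.where(
                second_higher,
                np.where(ref_second, "ref_higher", "ref_lower"),
                "dk",
            ),
        )
        frames.append(
            pd.DataFrame(
                {
                    "observer": observer,
                    "session": session,
                    "trial": np.arange(1, len(cells) + 1),
                    "condition": [cond_labels[i] for i in ci],
                    "order": np.where(ref_second, Order.REF_SECOND.value, Order.REF_FIRST.value),
                    "ref_contrast": ref,
                    "test_contrast": test,
                    "response": response,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[list(TRIAL_COLUMNS)]


def sample_observer_params(
    truth_means: Mapping[str, ModelParams],
    n_observers: int,
    seed: int,
    mu_sd: float = 1.0,
    log_sigma_sd: float = 0.15,
    midpoint_sd: float = 0.5,
    log_width_sd: float = 0.2,
) -> dict[str, dict[str, ModelParams]]:
    """Draw per-observer parameters around condition-level group means.

    Observer heterogeneity is modelled as Normal perturbations of mu, of the
    criterion midpoint, and of log sigma / log criterion half-width (shared
    across conditions within an observer, as criteria and sensitivity are
    observer traits, while mu perturbations are drawn per condition).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, ModelParams]] = {}
    for i in range(1, n_observers + 1):
        name = f"obs{i:02d}"
        sig_f = float(np.exp(rng.normal(0.0, log_sigma_sd)))
        mid_shift = float(rng.normal(0.0, midpoint_sd))
        wid_f = float(np.exp(rng.normal(0.0, log_width_sd)))
        per_cond = {}
        for cond, p in truth_means.items():
            c = p.criterion_midpoint + mid_shift
            w = p.criterion_halfwidth * wid_f
            per_cond[cond] = ModelParams(
                mu=p.mu + float(rng.normal(0.0, mu_sd)),
                sigma=p.sigma * sig_f,
                delta1=c - w,
                delta2=c + w,
            )
        out[name] = per_cond
    return out


def simulate_observers(
    design: ExperimentDesign,
    truth_by_observer: Mapping[str, Mapping[str, ModelParams]],
    seed: int,
) -> pd.DataFrame:
    """Simulate several observers; each gets an independent child seed."""
    children = np.random.SeedSequence(seed).spawn(len(truth_by_observer))
    frames = [
        simulate_trials(design, truth, int(ss.generate_state(1)[0] % 2**31), observer=obs)
        for (obs, truth), ss in zip(truth_by_observer.items(), children)
    ]
    return pd.concat(frames, ignore_index=True)


def aggregate_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Tally responses per (condition, x, order) cell.

    ``x`` is reference minus test contrast.  Returns a DataFrame with columns
    ``condition, x, order, n_ref_higher, n_ref_lower, n_dk``; count totals
    equal the input row count.  Empty input yields an empty frame.
    """
    if len(trials) == 0:
        return pd.DataFrame(
            columns=["condition", "x", "order", "n_ref_higher", "n_ref_lower", "n_dk"]
        )
    bad = set(trials["response"]) - set(RESPONSE_LABELS)
    if bad:
        raise ValueError(f"unknown response label(s): {sorted(bad)}")
    df = trials.assign(x=trials["ref_contrast"] - trials["test_contrast"])
    tab = (
        df.groupby(["condition", "x", "order"], observed=True)["response"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(RESPONSE_LABELS), fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    return tab.rename(
        columns={"ref_higher": "n_ref_higher", "ref_lower": "n_ref_lower", "dk": "n_dk"}
    )


def counts_records(
    aggregated: pd.DataFrame, condition: str | None = None
) -> list[ResponseCounts]:
    """Convert aggregated tallies to ResponseCounts for model fitting."""
    df = aggregated
    if condition is not None:
        df = df[df["condition"] == condition]
        if len(df) == 0:
            raise KeyError(f"no counts for condition {condition!r}")
    return [
        ResponseCounts(
            cell=StimulusCell(x=float(r.x), order=Order(r.order)),
            n_ref_higher=int(r.n_ref_higher),
            n_ref_lower=int(r.n_ref_lower),
            n_dk=int(r.n_dk),
        )
        for r in df.itertuples()
    ]


def veridicality_gate(
    mu_by_condition: Mapping[str, float], tolerance: float = 1.0
) -> bool:
    """Training-task acceptance rule.

    An observer passes training when every fitted perceived-contrast shift is
    within ``tolerance`` percent contrast of zero, i.e. the estimated
    perceived contrast of each test grating is within +/-1% of its true
    physical contrast.
    """
    return all(abs(m) <= tolerance for m in mu_by_condition.values())
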