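"""Within-subject group statistics on fitted model parameters.

The across-observer analyses operate on a complete observers-by-conditions
matrix of parameter estimates (typically the perceived-contrast shift mu):
a 2x2 repeated-measures ANOVA computed through per-subject contrasts (each
effect's F is the squared paired t on its contrast, with df 1 and n-1), a
one-way repeated-measures ANOVA via the classical within-subject
sums-of-squares decomposition (sphericity assumed, uncorrected df), and
Bonferroni-corrected paired post-hoc t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectConditionMatrix",
    "AnovaResult",
    "PairedComparison",
    "rm_anova_2x2",
    "rm_anova_oneway",
    "posthoc_paired_bonferroni",
]


@dataclass(frozen=True)
class SubjectConditionMatrix:
    """Per-observer, per-condition parameter estimates (complete cases).

    ``factor_coding`` optionally maps each condition label to its
    (orientation, depth) levels in a 2x2 factorial.
    """

    values: np.ndarray  # (n_observers, n_conditions)
    condition_labels: tuple[str, ...]
    observer_labels: tuple[str, ...] = ()
    factor_coding: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))
        if v.ndim != 2 or v.shape[1] != len(self.condition_labels):
            raise ValueError(
                "values must be (n_observers, n_conditions) matching condition_labels"
            )
        if not np.isfinite(v).all():
            raise ValueError("incomplete cases: all observers need every condition")
        if not self.observer_labels:
            object.__setattr__(
                self,
                "observer_labels",
                tuple(f"obs{i+1:02d}" for i in range(v.shape[0])),
            )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        factor_coding: Mapping[str, tuple[str, str]] | None = None,
    ) -> "SubjectConditionMatrix":
        """Build from a long DataFrame with columns observer/condition/value."""
        wide = frame.pivot(index="observer", columns="condition", values="value")
        if wide.isna().any().any():
            missing = wide.isna().stack()
            missing = list(missing[missing].index)
            raise ValueError(f"incomplete cases (no imputation): missing {missing}")
        return cls(
            values=wide.to_numpy(),
            condition_labels=tuple(wide.columns),
            observer_labels=tuple(wide.index),
            factor_coding=factor_coding,
        )

    def column(self, label: str) -> np.ndarray:
        try:
            return self.values[:, self.condition_labels.index(label)]
        except ValueError:
            raise KeyError(
                f"unknown condition {label!r}; have {self.condition_labels}"
            ) from None

    @property
    def n_observers(self) -> int:
        return self.values.shape[0]

    def condition_means(self) -> dict[str, float]:
        return dict(zip(self.condition_labels, self.values.mean(axis=0)))

    def condition_sems(self) -> dict[str, float]:
        n = self.n_observers
        return dict(
            zip(self.condition_labels, self.values.std(axis=0, ddof=1) / np.sqrt(n))
        )


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    degenerate: bool = False  # zero contrast variance in the input

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class PairedComparison:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_corrected: float

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "t": self.t,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
        }


def _contrast_f(effect: str, contrasts: np.ndarray, df_den: int) -> AnovaResult:
    """F test of a per-subject contrast: F = n * mean^2 / var, df (1, n-1).

    Zero contrast variance (degenerate, e.g. deterministic synthetic input)
    yields a flagged F of 0 (when the mean is also 0) or infinity instead of
    raising, so simulation sweeps do not abort.
    """
    n = contrasts.size
    mean = contrasts.mean()
    var = contrasts.var(ddof=1)
    if var == 0.0:
        f = 0.0 if mean == 0.0 else np.inf
        return AnovaResult(effect, f, 1, df_den, 1.0 if f == 0.0 else 0.0, degenerate=True)
    f = n * mean**2 / var
    return AnovaResult(effect, float(f), 1, df_den, float(stats.f.sf(f, 1, df_den)))


def rm_anova_2x2(data: SubjectConditionMatrix) -> dict[str, AnovaResult]:
    """2x2 repeated-measures ANOVA via subject contrasts.

    Returns results keyed ``orientation`` (factor A), ``depth`` (factor B)
    and ``interaction``.  Each effect's per-subject contrast is the
    half-difference of cell values under +/-1 coding, so its F equals the
    squared paired t on that contrast, with df (1, n-1).
    """
    if data.factor_coding is None:
        raise ValueError("factor_coding is required for the 2x2 analysis")
    if data.n_observers < 2:
        raise ValueError("need at least 2 observers (df_den = n - 1)")
    coding = {c: data.factor_coding[c] for c in data.condition_labels}
    a_levels = sorted({a for a, _ in coding.values()})
    b_levels = sorted({b for _, b in coding.values()})
    if len(a_levels) != 2 or len(b_levels) != 2 or len(coding) != 4:
        raise ValueError("factor_coding must describe a full 2x2 design")
    cell = {
        (a, b): data.column(c)
        for c, (a, b) in coding.items()
    }
    a1b1 = cell[(a_levels[0], b_levels[0])]
    a1b2 = cell[(a_levels[0], b_levels[1])]
    a2b1 = cell[(a_levels[1], b_levels[0])]
    a2b2 = cell[(a_levels[1], b_levels[1])]
    df_den = data.n_observers - 1
    return {
        "orientation": _contrast_f(
            "orientation", (a1b1 + a1b2 - a2b1 - a2b2) / 2.0, df_den
        ),
        "depth": _contrast_f("depth", (a1b1 - a1b2 + a2b1 - a2b2) / 2.0, df_den),
        "interaction": _contrast_f(
            "interaction", (a1b1 - a1b2 - a2b1 + a2b2) / 2.0, df_den
        ),
    }


def rm_anova_oneway(data: SubjectConditionMatrix) -> AnovaResult:
    """One-way repeated-measures ANOVA (classical decomposition).

    SS_condition (df k-1) is tested against the condition-by-subject
    residual (df (k-1)(n-1)); sphericity is assumed and no correction is
    applied to the degrees of freedom.
    """
    v = data.values
    n, k = v.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 observers")
    grand = v.mean()
    ss_cond = n * ((v.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((v.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((v - grand) ** 2).sum()
    ss_res = ss_total - ss_cond - ss_subj
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_res = ss_res / df_den
    if ms_res == 0.0:
        f = 0.0 if ss_cond == 0.0 else np.inf
        return AnovaResult(
            "condition", f, df_num, df_den, 1.0 if f == 0.0 else 0.0, degenerate=True
        )
    f = (ss_cond / df_num) / ms_res
    return AnovaResult(
        "condition", float(f), df_num, df_den, float(stats.f.sf(f, df_num, df_den))
    )


def posthoc_paired_bonferroni(
    data: SubjectConditionMatrix, comparisons: Sequence[tuple[str, str]]
) -> list[PairedComparison]:
    """Two-sided paired t tests with Bonferroni correction.

    ``p_corrected = min(1, p_raw * len(comparisons))``; the correction
    family is the set of comparisons passed in.
    """
    m = len(comparisons)
    out = []
    for a, b in comparisons:
        xa, xb = data.column(a), data.column(b)
        diff = xa - xb
        if np.allclose(diff.var(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(xa, xb)
        out.append(
            PairedComparison(
                pair=(a, b),
                t=float(t),
                df=data.n_observers - 1,
                p_raw=float(p),
                p_corrected=float(min(1.0, p * m)),
            )
        )
    return out
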