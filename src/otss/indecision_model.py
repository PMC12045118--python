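"""Difference-with-indecision model for two-interval contrast judgments.

The observer compares the contrast of a reference grating (physical contrast
varying across trials) with a test grating (fixed contrast, possibly embedded
in a suppressive surround).  On each trial the internal evidence is the
perceived-contrast difference between the two presentation intervals,

    D = perceived(second interval) - perceived(first interval),

assumed Gaussian with standard deviation ``sigma``.  A surround that changes
the apparent contrast of the test grating shifts the mean of D by ``mu``
(in percent Michelson contrast).  Two fixed criteria partition D into three
responses: D < delta1 -> "second interval lower", D > delta2 -> "second
interval higher", otherwise "don't know" (DK).  Because the criteria live in
the interval frame, their midpoint absorbs any bias toward a particular
temporal interval; mapping interval-frame responses back to the reference
frame by presentation order is what lets ``mu`` estimate the perceived
contrast shift free of that bias.  ``mu`` coincides with the location of the
maximum of the DK psychometric function averaged over the two orders.

Fitting is multinomial maximum likelihood over per-cell response counts,
jointly across the two presentation orders (six psychometric functions from
four parameters).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "Order",
    "ModelParams",
    "StimulusCell",
    "ResponseCounts",
    "FitResult",
    "FitOptions",
    "DkPeak",
    "NonIdentifiableError",
    "DegenerateModelError",
    "response_probabilities",
    "negative_log_likelihood",
    "fit_model",
    "dk_peak_location",
]

#: Probability floor applied inside logarithms so the objective stays finite
#: at boundary parameter values.  Configurable through FitOptions.
DEFAULT_PROB_FLOOR = 1e-9


class NonIdentifiableError(ValueError):
    """Raised when the data cannot identify the model parameters."""


class DegenerateModelError(ValueError):
    """Raised for parameter settings that make an operation ill-defined."""


class Order(enum.Enum):
    """Presentation order of the reference grating within the trial."""

    REF_FIRST = "ref_first"
    REF_SECOND = "ref_second"

    @property
    def sign(self) -> int:
        """Sign of the reference's contribution to the second-minus-first
        difference signal: +1 when the reference is second, -1 when first."""
        return 1 if self is Order.REF_SECOND else -1


def _as_order(order: "Order | str") -> Order:
    if isinstance(order, Order):
        return order
    return Order(order)


@dataclass(frozen=True)
class ModelParams:
    """The four indecision-model parameters, in percent Michelson contrast.

    mu
        Perceived-contrast shift of the test grating.  Negative values mean
        the surround makes the test look lower in contrast.
    sigma
        Standard deviation of the internal difference signal (> 0).
    delta1, delta2
        Lower and upper decision criteria on the second-minus-first
        difference signal; ``delta1 <= delta2``.  Equality forces the DK
        probability to zero.
    """

    mu: float
    sigma: float
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "delta1", "delta2"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.delta1 > self.delta2:
            raise ValueError(
                f"delta1 must not exceed delta2 (got {self.delta1} > {self.delta2})"
            )

    @property
    def criterion_midpoint(self) -> float:
        """Interval-bias term: midpoint of the two criteria."""
        return 0.5 * (self.delta1 + self.delta2)

    @property
    def criterion_halfwidth(self) -> float:
        """Half-width of the indecision zone."""
        return 0.5 * (self.delta2 - self.delta1)

    def to_dict(self) -> dict[str, float]:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "delta1": self.delta1,
            "delta2": self.delta2,
        }


@dataclass(frozen=True)
class StimulusCell:
    """One design cell: signed contrast difference and presentation order.

    ``x`` is reference minus test physical contrast, in percent.
    """

    x: float
    order: Order

    def __post_init__(self) -> None:
        if not math.isfinite(self.x):
            raise ValueError(f"x must be finite, got {self.x!r}")
        object.__setattr__(self, "order", _as_order(self.order))


@dataclass(frozen=True)
class ResponseCounts:
    """Multinomial response counts for one design cell."""

    cell: StimulusCell
    n_ref_higher: int
    n_ref_lower: int
    n_dk: int

    def __post_init__(self) -> None:
        for name in ("n_ref_higher", "n_ref_lower", "n_dk"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_ref_higher + self.n_ref_lower + self.n_dk


@dataclass(frozen=True)
class FitOptions:
    """Controls for maximum-likelihood fitting.

    n_restarts jittered starts are run in addition to the deterministic
    moment-based start; the best objective wins (ties to the first found).
    """

    n_restarts: int = 8
    seed: int = 0
    prob_floor: float = DEFAULT_PROB_FLOOR
    max_iter: int = 500
    lapse_rate: float = 0.0  # opt-in fixed lapse; default off


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``delta_perceived_contrast`` is the fitted ``mu`` -- the estimated
    perceived-contrast difference between test and reference gratings.
    """

    params: ModelParams
    neg_log_likelihood: float
    converged: bool
    n_restarts_used: int
    criteria_collapsed: bool = False

    @property
    def delta_perceived_contrast(self) -> float:
        return self.params.mu

    def to_dict(self, data: Sequence[ResponseCounts] | None = None) -> dict:
        """JSON-ready summary; with ``data``, includes per-cell observed vs
        predicted response proportions."""
        out: dict = {
            "params": self.params.to_dict(),
            "delta_perceived_contrast": self.delta_perceived_contrast,
            "neg_log_likelihood": self.neg_log_likelihood,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "criteria_collapsed": self.criteria_collapsed,
        }
        if data is not None:
            cells = []
            for rc in data:
                p = response_probabilities(self.params, rc.cell)
                n = max(rc.total, 1)
                cells.append(
                    {
                        "x": rc.cell.x,
                        "order": rc.cell.order.value,
                        "n": rc.total,
                        "observed": [
                            rc.n_ref_higher / n,
                            rc.n_ref_lower / n,
                            rc.n_dk / n,
                        ],
                        "predicted": list(p),
                    }
                )
            out["cells"] = cells
        return out


# ---------------------------------------------------------------------------
# Response probabilities
# ---------------------------------------------------------------------------


def _probabilities_arrays(
    mu: float,
    sigma: float,
    delta1: float,
    delta2: float,
    x: np.ndarray,
    order_sign: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (p_ref_higher, p_ref_lower, p_dk).

    The difference signal D (second minus first interval) has mean
    ``order_sign * (x - mu)`` and sd sigma.  D < delta1 -> "second lower",
    D > delta2 -> "second higher"; interval-frame responses are mapped to
    the reference frame by order.
    """
    d_mean = order_sign * (x - mu)
    p_second_lower = norm.cdf((delta1 - d_mean) / sigma)
    p_second_higher = norm.sf((delta2 - d_mean) / sigma)
    p_dk = 1.0 - p_second_lower - p_second_higher
    # reference second: "second lower" == reference lower
    ref_second = order_sign > 0
    p_ref_lower = np.where(ref_second, p_second_lower, p_second_higher)
    p_ref_higher = np.where(ref_second, p_second_higher, p_second_lower)
    return p_ref_higher, p_ref_lower, np.clip(p_dk, 0.0, 1.0)


def response_probabilities(
    params: ModelParams, cell: StimulusCell
) -> tuple[float, float, float]:
    """Analytic probabilities of the three responses for one design cell.

    Returns ``(p_ref_higher, p_ref_lower, p_dk)``; the triple sums to 1.
    """
    if not isinstance(params, ModelParams):
        params = ModelParams(**params)  # type: ignore[arg-type]
    if not isinstance(cell, StimulusCell):
        raise TypeError("cell must be a StimulusCell")
    ph, pl, pdk = _probabilities_arrays(
        params.mu,
        params.sigma,
        params.delta1,
        params.delta2,
        np.asarray([cell.x], dtype=float),
        np.asarray([cell.order.sign], dtype=float),
    )
    p_higher = float(ph[0])
    p_lower = float(pl[0])
    return p_higher, p_lower, 1.0 - p_higher - p_lower


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _data_arrays(
    data: Iterable[ResponseCounts],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack counts into (x, order_sign, counts[ncell,3]) arrays."""
    data = list(data)
    if not data:
        raise ValueError("data must contain at least one ResponseCounts cell")
    x = np.array([rc.cell.x for rc in data], dtype=float)
    sign = np.array([rc.cell.order.sign for rc in data], dtype=float)
    counts = np.array(
        [[rc.n_ref_higher, rc.n_ref_lower, rc.n_dk] for rc in data], dtype=float
    )
    return x, sign, counts


def _nll_arrays(
    theta: tuple[float, float, float, float],
    x: np.ndarray,
    sign: np.ndarray,
    counts: np.ndarray,
    floor: float,
) -> float:
    mu, sigma, delta1, delta2 = theta
    ph, pl, pdk = _probabilities_arrays(mu, sigma, delta1, delta2, x, sign)
    p = np.stack([ph, pl, pdk], axis=1)
    return float(-(counts * np.log(np.maximum(p, floor))).sum())


def negative_log_likelihood(
    params: ModelParams,
    data: Iterable[ResponseCounts],
    prob_floor: float = DEFAULT_PROB_FLOOR,
) -> float:
    """Multinomial negative log-likelihood of per-cell counts.

    The combinatorial coefficient is omitted (constant in the parameters);
    probabilities are floored at ``prob_floor`` inside the logarithm so the
    value is always finite.  Cells with zero counts contribute 0.
    """
    x, sign, counts = _data_arrays(data)
    return _nll_arrays(
        (params.mu, params.sigma, params.delta1, params.delta2),
        x,
        sign,
        counts,
        prob_floor,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_MIN_LOG_W = -20.0  # exp(-20) percent: numerically zero indecision width


def _unpack_free(theta: np.ndarray, fit_width: bool) -> tuple[float, float, float, float]:
    """Map unconstrained optimizer variables to model parameters.

    theta = (mu, log sigma, criterion midpoint c, log half-width) -- the last
    entry absent when the width is pinned to zero (zero-DK data).
    """
    mu = theta[0]
    sigma = math.exp(min(theta[1], 20.0))
    c = theta[2]
    w = math.exp(min(theta[3], 20.0)) if fit_width else 0.0
    return mu, sigma, c - w, c + w


def _deterministic_start(
    x: np.ndarray, sign: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Moment-based starting point in the unconstrained parameterization."""
    totals = counts.sum(axis=1)
    w_tot = np.maximum(totals, 1.0)
    frac_dk = counts[:, 2] / w_tot
    # mu0: x at the empirical order-averaged DK maximum when DK is used,
    # else the count-weighted mean of the ladder
    if counts[:, 2].sum() > 0:
        levels = np.unique(x)
        dk_by_x = np.array(
            [counts[x == lv, 2].sum() / max(totals[x == lv].sum(), 1.0) for lv in levels]
        )
        mu0 = float(levels[np.argmax(dk_by_x)])
    else:
        mu0 = float(np.average(x, weights=w_tot))
    # sigma0 from the spread of the reference-higher curve: distance between
    # the ladder extremes scaled to a plausible slope
    span = float(x.max() - x.min())
    sigma0 = max(span / 4.0, 0.5)
    # criterion width from the overall DK rate under a mid-ladder Gaussian
    overall_dk = float(counts[:, 2].sum() / max(totals.sum(), 1.0))
    q = min(max((1.0 + overall_dk) / 2.0, 0.5 + 1e-6), 1.0 - 1e-6)
    w0 = max(sigma0 * norm.ppf(q), 1e-3)
    return np.array([mu0, math.log(sigma0), 0.0, math.log(w0)])


def fit_model(
    data: Iterable[ResponseCounts], options: FitOptions | None = None
) -> FitResult:
    """Maximum-likelihood fit of the indecision model to per-cell counts.

    Minimizes :func:`negative_log_likelihood` over (mu, sigma, delta1,
    delta2) subject to ``sigma > 0`` and ``delta1 <= delta2`` via an
    unconstrained reparameterization (mu, log sigma, criterion midpoint,
    log half-width), using a quasi-Newton local search from a deterministic
    moment-based start plus seeded jittered restarts.

    Raises :class:`NonIdentifiableError` when the data contain a single
    presentation order (the criterion midpoint and mu trade off exactly),
    fewer than two reference-contrast levels, or only DK responses.  When
    the data contain no DK responses at all, the criterion half-width is
    pinned to zero and a 3-parameter fit is performed
    (``criteria_collapsed=True`` in the result).
    """
    opts = options or FitOptions()
    data = list(data)
    x, sign, counts = _data_arrays(data)
    if counts.sum() <= 0:
        raise ValueError("data contain no trials")
    if np.unique(x).size < 2:
        raise NonIdentifiableError(
            "data must cover at least two reference-contrast levels"
        )
    present = {s for s, tot in zip(sign, counts.sum(axis=1)) if tot > 0}
    if len(present) < 2:
        raise NonIdentifiableError(
            "single presentation order: the criterion midpoint carries no "
            "information (Fisher information vanishes) and mu is confounded "
            "with interval bias; provide trials from both orders"
        )
    n_dk = counts[:, 2].sum()
    if n_dk == counts.sum():
        raise NonIdentifiableError(
            "all responses are DK: mu and sigma are unidentifiable"
        )
    fit_width = n_dk > 0

    start = _deterministic_start(x, sign, counts)
    if not fit_width:
        start = start[:3]

    def objective(theta: np.ndarray) -> float:
        return _nll_arrays(
            _unpack_free(theta, fit_width), x, sign, counts, opts.prob_floor
        )

    rng = np.random.default_rng(opts.seed)
    span = max(float(x.max() - x.min()), 1.0)
    starts = [start]
    for _ in range(opts.n_restarts):
        jitter = rng.normal(0.0, [span / 8.0, 0.3, span / 16.0, 0.5][: start.size])
        starts.append(start + jitter)

    best = None
    n_used = 0
    any_converged = False
    for s0 in starts:
        n_used += 1
        res = optimize.minimize(
            objective,
            s0,
            method="L-BFGS-B",
            options={"maxiter": opts.max_iter},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    mu, sigma, d1, d2 = _unpack_free(best.x, fit_width)
    params = ModelParams(mu=mu, sigma=sigma, delta1=d1, delta2=d2)
    return FitResult(
        params=params,
        neg_log_likelihood=float(best.fun),
        converged=any_converged,
        n_restarts_used=n_used,
        criteria_collapsed=not fit_width,
    )


# ---------------------------------------------------------------------------
# DK-peak location
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DkPeak:
    """Location(s) of the maximum of the order-averaged DK function."""

    locations: tuple[float, ...]
    unique: bool

    @property
    def location(self) -> float:
        if not self.unique:
            raise ValueError(
                f"DK peak is not unique; candidate locations: {self.locations}"
            )
        return self.locations[0]


def _averaged_dk(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """DK probability averaged over the two presentation orders.

    This function is even in (x - mu); its maximum locates mu when unimodal.
    """
    out = np.zeros_like(x, dtype=float)
    for s in (1.0, -1.0):
        _, _, pdk = _probabilities_arrays(
            params.mu, params.sigma, params.delta1, params.delta2, x, np.full_like(x, s)
        )
        out += pdk
    return 0.5 * out


def dk_peak_location(
    params: ModelParams, n_grid: int = 4001, tol: float = 1e-8
) -> DkPeak:
    """Argmax over x of the order-averaged DK probability.

    Computed on a dense grid spanning all possible peak positions, then
    refined with bounded scalar optimization around each grid maximum.
    When the criteria midpoint is far from zero relative to the indecision
    width and sigma, the averaged curve is bimodal with maxima placed
    symmetrically about mu; the result then carries ``unique=False`` and
    both locations.
    """
    if params.delta1 == params.delta2:
        raise DegenerateModelError(
            "delta1 == delta2 makes P(DK) identically zero; the DK peak is undefined"
        )
    c = params.criterion_midpoint
    w = params.criterion_halfwidth
    half_span = abs(c) + w + 6.0 * params.sigma
    grid = params.mu + np.linspace(-half_span, half_span, n_grid)
    vals = _averaged_dk(params, grid)
    # interior local maxima on the grid
    interior = (vals[1:-1] >= vals[:-2]) & (vals[1:-1] >= vals[2:])
    idx = np.where(interior)[0] + 1
    if idx.size == 0:
        idx = np.array([int(np.argmax(vals))])
    # cluster adjacent plateau indices
    clusters: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i - clusters[-1][-1] <= 1:
            clusters[-1].append(int(i))
        else:
            clusters.append([int(i)])
    peaks = []
    step = grid[1] - grid[0]
    for cl in clusters:
        i = cl[len(cl) // 2]
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            lambda t: -_averaged_dk(params, np.array([t]))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        peaks.append((float(res.x), float(-res.fun)))
    # keep peaks whose height is within numerical tolerance of the best
    best_val = max(v for _, v in peaks)
    keep = [p for p, v in peaks if v >= best_val - 1e-10]
    keep.sort()
    # merge locations that coincide numerically
    merged: list[float] = []
    for p in keep:
        if not merged or abs(p - merged[-1]) > max(10 * step, 1e-6):
            merged.append(p)
    if len(merged) == 1:
        return DkPeak(locations=(merged[0],), unique=True)
    return DkPeak(locations=tuple(merged), unique=False)
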