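"""Progenitor/neuron population dynamics driven by division-mode fractions.

Neural progenitors (P) divide in one of three modes: symmetric proliferative
(PP, two progenitors), asymmetric neurogenic (PN, one progenitor and one
neuron) and symmetric neurogenic (NN, two neurons).  With mode proportions
``alpha_pp + alpha_pn + alpha_nn = 1`` and a common per-progenitor division
rate ``eta``, the two pools obey

    dP/dt = gamma * eta * P
    dN/dt = (1 - gamma) * eta * P

where ``gamma = alpha_pp - alpha_nn`` balances self-expansion (+1) against
self-consumption (-1).  For ``gamma != 0`` the solution is

    P(t) = P(0) * exp(gamma * eta * t)
    N(t) = N(0) + P(0) * (1 - gamma)/gamma * (exp(gamma * eta * t) - 1)

with the analytic limit ``P(t) = P(0)``, ``N(t) = N(0) + eta*P(0)*t`` at
``gamma = 0``.  This module provides the closed form, forward prediction of
the neuron fraction over a developmental window, and a multinomial-bootstrap
uncertainty envelope on that prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ModeFractions",
    "PopulationState",
    "CycleTiming",
    "Trajectory",
    "mode_fractions_from_counts",
    "gamma",
    "closed_form_state",
    "neuron_fraction",
    "predict_fraction_trajectory",
    "bootstrap_prediction_interval",
]

#: |gamma| below this uses the analytic gamma -> 0 limit of the closed form.
GAMMA_EPS = 1e-9

#: Tolerance on the sum of the three mode fractions after normalization.
FRACTION_SUM_TOL = 1e-9

RateConvention = Literal["reciprocal", "log2"]


@dataclass(frozen=True)
class ModeFractions:
    """Proportions of PP, PN and NN divisions; must sum to 1."""

    alpha_pp: float
    alpha_pn: float
    alpha_nn: float

    def __post_init__(self) -> None:
        for name in ("alpha_pp", "alpha_pn", "alpha_nn"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        total = self.alpha_pp + self.alpha_pn + self.alpha_nn
        if abs(total - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"mode fractions must sum to 1 (got {total!r}); "
                "use mode_fractions_from_counts to normalize raw counts"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_pp, self.alpha_pn, self.alpha_nn])


@dataclass(frozen=True)
class PopulationState:
    """Progenitor and neuron pool sizes at a time point (hours).

    Counts are real-valued expectations; integer realizations live in
    :mod:`neurodiv.branching_simulator`.
    """

    progenitors: float
    neurons: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.progenitors < 0 or self.neurons < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> float:
        return self.progenitors + self.neurons


@dataclass(frozen=True)
class CycleTiming:
    """Mean cell cycle duration Tc (hours) and the division rate eta (1/h).

    The default convention is ``eta = 1/Tc`` (a progenitor completes one
    division per mean cycle time); ``rate_convention="log2"`` gives the
    exponential-doubling alternative ``eta = ln 2 / Tc``.
    """

    tc_hours: float
    rate_convention: RateConvention = "reciprocal"

    def __post_init__(self) -> None:
        if self.tc_hours <= 0:
            raise ValueError("cell cycle duration must be positive")
        if self.rate_convention not in ("reciprocal", "log2"):
            raise ValueError(f"unknown rate convention {self.rate_convention!r}")

    @property
    def eta(self) -> float:
        """Division rate per progenitor per hour."""
        if self.rate_convention == "log2":
            return math.log(2.0) / self.tc_hours
        return 1.0 / self.tc_hours


@dataclass(frozen=True)
class Trajectory:
    """Ordered sequence of population states with the parameters that made it."""

    states: tuple[PopulationState, ...]
    gamma_used: float
    timing_used: CycleTiming

    def __post_init__(self) -> None:
        times = [s.time for s in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def progenitors(self) -> np.ndarray:
        return np.array([s.progenitors for s in self.states])

    @property
    def neurons(self) -> np.ndarray:
        return np.array([s.neurons for s in self.states])

    @property
    def neuron_fractions(self) -> np.ndarray:
        return np.array([neuron_fraction(s) for s in self.states])


def mode_fractions_from_counts(
    counts_pp: float, counts_pn: float, counts_nn: float
) -> ModeFractions:
    """Normalize raw class counts (or percentages) into :class:`ModeFractions`.

    Accepts any non-negative weights — cell counts, clone counts or printed
    percentages — and rescales them to sum to 1.
    """
    counts = (counts_pp, counts_pn, counts_nn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total <= 0:
        raise ValueError("at least one division-mode count must be positive")
    return ModeFractions(*(c / total for c in counts))


def gamma(f: ModeFractions) -> float:
    """Proliferation balance ``alpha_pp - alpha_nn`` in [-1, 1]."""
    return f.alpha_pp - f.alpha_nn


def closed_form_state(
    initial: PopulationState,
    f: ModeFractions,
    timing: CycleTiming,
    t: float,
) -> PopulationState:
    """Evaluate the closed-form solution at absolute time ``t`` (hours).

    Elapsed time is ``t - initial.time``; for |gamma| < ``GAMMA_EPS`` the
    analytic gamma -> 0 limit is used (constant P, linear neuron accrual).
    """
    dt = t - initial.time
    if dt < 0:
        raise ValueError(f"t={t} precedes initial.time={initial.time}")
    g = gamma(f)
    eta = timing.eta
    p0, n0 = initial.progenitors, initial.neurons
    if abs(g) < GAMMA_EPS:
        p = p0
        n = n0 + eta * p0 * dt
    else:
        growth = math.expm1(g * eta * dt)  # e^{gamma*eta*dt} - 1, stable near 0
        p = p0 * (1.0 + growth)
        n = n0 + p0 * (1.0 - g) / g * growth
    return PopulationState(progenitors=p, neurons=n, time=t)


def neuron_fraction(state: PopulationState) -> float:
    """Neurons as a fraction of all cells, N / (N + P)."""
    if state.total <= 0:
        raise ValueError("neuron fraction undefined for an empty population")
    return state.neurons / state.total


def _time_grid(t0: float, horizon: float, step: float) -> np.ndarray:
    """Grid from t0 to t0+horizon inclusive; endpoints only if step > horizon."""
    n_steps = int(math.floor(horizon / step + 1e-12))
    times = t0 + step * np.arange(n_steps + 1)
    if times[-1] < t0 + horizon - 1e-12:
        times = np.append(times, t0 + horizon)
    else:
        times[-1] = t0 + horizon
    return times


def predict_fraction_trajectory(
    initial: PopulationState,
    f: ModeFractions,
    timing: CycleTiming,
    horizon: float,
    step: float,
) -> Trajectory:
    """Forward-predict the population over ``horizon`` hours on a uniform grid.

    Returns closed-form states every ``step`` hours from ``initial.time`` to
    ``initial.time + horizon`` (endpoint always included).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    times = _time_grid(initial.time, horizon, step)
    states = tuple(closed_form_state(initial, f, timing, t) for t in times)
    return Trajectory(states=states, gamma_used=gamma(f), timing_used=timing)


@dataclass(frozen=True)
class PredictionEnvelope:
    """Pointwise bootstrap envelope of the predicted neuron fraction."""

    times: np.ndarray
    plug_in: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_boot: int
    trajectory: Trajectory = field(repr=False, default=None)  # type: ignore[assignment]


def bootstrap_prediction_interval(
    mode_counts: Sequence[int],
    initial: PopulationState,
    timing: CycleTiming,
    horizon: float,
    n_boot: int = 2000,
    seed: int = 0,
    step: float = 0.5,
) -> PredictionEnvelope:
    """Multinomial-bootstrap 95% envelope for the neuron-fraction prediction.

    The observed division-mode counts are resampled multinomially at their
    empirical fractions; each resample is normalized and propagated through
    the closed form.  The pointwise 2.5/97.5 percentiles of the resampled
    neuron-fraction curves form the envelope (percentile method).
    """
    counts = np.asarray(mode_counts, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise ValueError("mode_counts must be three non-negative integers")
    total = int(counts.sum())
    if total < 1:
        raise ValueError("total division-mode count must be >= 1")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    f_hat = mode_fractions_from_counts(*counts)
    plug_in = predict_fraction_trajectory(initial, f_hat, timing, horizon, step)
    times = plug_in.times

    rng = np.random.default_rng(seed)
    resampled_counts = rng.multinomial(total, f_hat.as_array(), size=n_boot)
    curves = np.empty((n_boot, times.size))
    for i, c in enumerate(resampled_counts):
        fb = mode_fractions_from_counts(*c)
        curves[i] = predict_fraction_trajectory(
            initial, fb, timing, horizon, step
        ).neuron_fractions
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return PredictionEnvelope(
        times=times,
        plug_in=plug_in.neuron_fractions,
        lo95=lo,
        hi95=hi,
        n_boot=n_boot,
        trajectory=plug_in,
    )
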