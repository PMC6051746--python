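"""Stochastic (Gillespie) realizations of the two model interpretations.

Two continuous-time branching simulators over integer progenitor/neuron
pools:

* ``simulate_probabilistic_fates`` — every progenitor divides at the common
  rate ``eta``; the mode of each division is drawn from the mode fractions
  (PP with probability alpha_pp, etc.).  Its mean field is exactly the ODE
  solved in :mod:`neurodiv.division_dynamics`.
* ``simulate_competing_clocks`` — each progenitor races three independent
  exponential clocks with rates ``alpha_pp*eta``, ``alpha_pn*eta``,
  ``alpha_nn*eta``; the first to ring fixes the fate deterministically.

By the superposition/thinning properties of exponential races the two
constructions induce the same law on (P, N) trajectories — mode-specific
rates with deterministic fates are observationally hidden; only the implied
per-mode cycle times (:mod:`neurodiv.fate_time_model`) distinguish them.
The simulators use deliberately different sampling code paths so their
equivalence is a testable statement, not a tautology.

State updates per division: PP: P -> P+1; PN: N -> N+1; NN: P -> P-1,
N -> N+2.  Every event adds exactly one cell.  Neurons are absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .division_dynamics import CycleTiming, ModeFractions, PopulationState

__all__ = [
    "SimulationConfig",
    "DivisionEvent",
    "ReplicateResult",
    "simulate_probabilistic_fates",
    "simulate_competing_clocks",
    "summarize_replicates",
]

Mode = Literal["PP", "PN", "NN"]
MODES: tuple[Mode, Mode, Mode] = ("PP", "PN", "NN")

#: Abort a replicate whose population exceeds this many cells.
DEFAULT_POPULATION_CAP = 10**6


@dataclass(frozen=True)
class SimulationConfig:
    initial: PopulationState
    fractions: ModeFractions
    timing: CycleTiming
    t_end: float
    n_replicates: int = 1
    seed: int = 0
    population_cap: int = DEFAULT_POPULATION_CAP

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name, v in (
            ("progenitors", self.initial.progenitors),
            ("neurons", self.initial.neurons),
        ):
            if v != int(v):
                raise ValueError(f"initial {name} must be integer-valued, got {v}")


@dataclass(frozen=True)
class DivisionEvent:
    time: float
    mode: Mode


@dataclass(frozen=True)
class ReplicateResult:
    """Event log and end state of one stochastic replicate."""

    events: tuple[DivisionEvent, ...]
    end_state: PopulationState
    initial: PopulationState = field(repr=False, default=None)  # type: ignore[assignment]

    def counts_at(self, t: float) -> tuple[int, int]:
        """(P, N) just after the last event at or before time t."""
        p = int(self.initial.progenitors)
        n = int(self.initial.neurons)
        for ev in self.events:
            if ev.time > t:
                break
            p, n = _apply_mode(p, n, ev.mode)
        return p, n


class PopulationCapExceeded(RuntimeError):
    """Raised when a replicate's population outgrows the configured cap."""


def _apply_mode(p: int, n: int, mode: Mode) -> tuple[int, int]:
    if mode == "PP":
        return p + 1, n
    if mode == "PN":
        return p, n + 1
    return p - 1, n + 2  # NN


def _run_gillespie(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    draw_mode: Callable[[np.random.Generator], Mode],
) -> ReplicateResult:
    eta = cfg.timing.eta
    p = int(cfg.initial.progenitors)
    n = int(cfg.initial.neurons)
    t = 0.0
    events: list[DivisionEvent] = []
    while p > 0:
        t += rng.exponential(1.0 / (eta * p))
        if t > cfg.t_end:
            break
        mode = draw_mode(rng)
        p, n = _apply_mode(p, n, mode)
        events.append(DivisionEvent(time=t, mode=mode))
        if p + n > cfg.population_cap:
            raise PopulationCapExceeded(
                f"population exceeded cap of {cfg.population_cap} cells at t={t:.3f} h; "
                "reduce t_end or raise population_cap"
            )
    end = PopulationState(progenitors=p, neurons=n, time=cfg.t_end)
    return ReplicateResult(events=tuple(events), end_state=end, initial=cfg.initial)


def _replicate_rngs(cfg: SimulationConfig) -> list[np.random.Generator]:
    # one master seed; independent per-replicate streams
    seq = np.random.SeedSequence(cfg.seed)
    return [np.random.default_rng(s) for s in seq.spawn(cfg.n_replicates)]


def simulate_probabilistic_fates(cfg: SimulationConfig) -> list[ReplicateResult]:
    """Common division rate, fate drawn categorically per division."""
    cdf = np.cumsum(cfg.fractions.as_array())

    def draw_mode(rng: np.random.Generator) -> Mode:
        return MODES[min(int(np.searchsorted(cdf, rng.random(), side="right")), 2)]

    return [_run_gillespie(cfg, rng, draw_mode) for rng in _replicate_rngs(cfg)]


def simulate_competing_clocks(cfg: SimulationConfig) -> list[ReplicateResult]:
    """Mode-specific exponential clocks with deterministic fates.

    The waiting time to the next division anywhere in the pool is the
    minimum over P cells of the minimum of three exponential clocks, i.e.
    exponential with rate ``eta * P`` (rates sum to eta per cell); the
    winning mode is sampled as the argmin of three explicit exponential
    draws at rates ``alpha_m * eta``.
    """
    eta = cfg.timing.eta
    rates = cfg.fractions.as_array() * eta

    def draw_mode(rng: np.random.Generator) -> Mode:
        # zero-rate clocks never ring
        ring = np.where(rates > 0, rng.exponential(1.0, size=3) / np.where(rates > 0, rates, 1.0), np.inf)
        return MODES[int(np.argmin(ring))]

    return [_run_gillespie(cfg, rng, draw_mode) for rng in _replicate_rngs(cfg)]


def summarize_replicates(
    replicates: Sequence[ReplicateResult],
    grid: Sequence[float],
) -> pd.DataFrame:
    """Pointwise mean and 95% percentile band of P, N and neuron fraction.

    ``grid`` must lie within [0, t_end] of the replicates.  Returns a
    DataFrame with columns ``time_h, p_mean, p_lo95, p_hi95, n_mean,
    n_lo95, n_hi95, frac_mean, frac_lo95, frac_hi95``.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    grid = np.asarray(grid, dtype=float)
    t_end = max(r.end_state.time for r in replicates)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if grid.min() < 0 or grid.max() > t_end + 1e-12:
        raise ValueError(f"grid must lie within [0, {t_end}]")

    p = np.empty((len(replicates), grid.size))
    n = np.empty_like(p)
    for i, rep in enumerate(replicates):
        # single pass over the event log per replicate
        pi = int(rep.initial.progenitors)
        ni = int(rep.initial.neurons)
        j = 0
        for k, t in enumerate(grid):
            while j < len(rep.events) and rep.events[j].time <= t:
                pi, ni = _apply_mode(pi, ni, rep.events[j].mode)
                j += 1
            p[i, k], n[i, k] = pi, ni
    total = p + n
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, n / total, np.nan)

    def stats(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.nanmean(a, axis=0),
            np.nanpercentile(a, 2.5, axis=0),
            np.nanpercentile(a, 97.5, axis=0),
        )

    pm, pl, ph = stats(p)
    nm, nl, nh = stats(n)
    fm, fl, fh = stats(frac)
    return pd.DataFrame(
        {
            "time_h": grid,
            "p_mean": pm, "p_lo95": pl, "p_hi95": ph,
            "n_mean": nm, "n_lo95": nl, "n_hi95": nh,
            "frac_mean": fm, "frac_lo95": fl, "frac_hi95": fh,
        }
    )
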