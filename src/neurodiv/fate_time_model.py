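"""Deterministic-fate alternative: putative mode-specific cycle times.

The population model is observationally compatible with two readings of the
division-mode fractions: (a) a common division rate with probabilistic fates,
and (b) three sub-populations with deterministic fates, each cycling at a
mode-specific rate proportional to the observed fraction of that mode
(``rate_mode = alpha_mode * eta``).  Under reading (b) the putative cycle
time of each mode is

    T_mode = Tc / alpha_mode

so rare modes require implausibly long cycles (e.g. a 7.8% NN class at
Tc = 12 h implies a ~154 h NN cycle).  Computing these times for measured
fraction tables is a reductio argument: the implied range of cycle times is
far outside anything recorded in neuroepithelia, so fate cannot be set by
mode-specific cycle lengths alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .division_dynamics import CycleTiming, ModeFractions

__all__ = ["FateCycleTimes", "putative_cycle_times", "reproduce_table1"]

HARMONIC_TOL = 1e-9


@dataclass(frozen=True)
class FateCycleTimes:
    """Putative per-mode cycle times (hours) under deterministic fates.

    A zero-fraction mode maps to ``math.inf``: that division mode is
    unachievable by cycling alone.  Finite times satisfy ``T_mode >= Tc`` and
    the harmonic closure ``sum(Tc / T_mode) = 1``.
    """

    t_pp: float
    t_pn: float
    t_nn: float
    tc: float

    def __post_init__(self) -> None:
        if self.tc <= 0:
            raise ValueError("Tc must be positive")
        for name, t in (("t_pp", self.t_pp), ("t_pn", self.t_pn), ("t_nn", self.t_nn)):
            if t < self.tc:
                raise ValueError(f"{name}={t} is below the cycle time Tc={self.tc}")
        closure = sum(
            self.tc / t for t in (self.t_pp, self.t_pn, self.t_nn) if math.isfinite(t)
        )
        if abs(closure - 1.0) > 1e-6:
            raise ValueError(f"harmonic closure violated: sum Tc/T_mode = {closure}")

    def recovered_fractions(self) -> ModeFractions:
        """Invert back to mode fractions via alpha_mode = Tc / T_mode."""
        return ModeFractions(
            *(0.0 if math.isinf(t) else self.tc / t for t in (self.t_pp, self.t_pn, self.t_nn))
        )


def putative_cycle_times(f: ModeFractions, timing: CycleTiming) -> FateCycleTimes:
    """Cycle time each mode would need if fate were set by cycle length alone.

    ``T_mode = Tc / alpha_mode``; a zero fraction yields an infinite
    ("unachievable") time rather than an error, since observed tables can
    contain 0% classes.
    """
    tc = timing.tc_hours

    def t_of(alpha: float) -> float:
        return math.inf if alpha == 0.0 else tc / alpha

    return FateCycleTimes(
        t_pp=t_of(f.alpha_pp),
        t_pn=t_of(f.alpha_pn),
        t_nn=t_of(f.alpha_nn),
        tc=tc,
    )


def reproduce_table1(
    conditions: Iterable[tuple[str, ModeFractions, CycleTiming]],
) -> pd.DataFrame:
    """Tabulate putative cycle times for a list of (label, fractions, timing).

    Returns a DataFrame with one row per condition and columns
    ``condition, T_pp_h, T_pn_h, T_nn_h, Tc_h``, plus ``t_min``/``t_max``
    attrs holding the extreme finite putative times across the table.  Values
    are kept at full precision; round to 1 d.p. for display.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("need at least one condition")
    rows = []
    for label, f, timing in conditions:
        times = putative_cycle_times(f, timing)
        rows.append(
            {
                "condition": label,
                "T_pp_h": times.t_pp,
                "T_pn_h": times.t_pn,
                "T_nn_h": times.t_nn,
                "Tc_h": times.tc,
            }
        )
    table = pd.DataFrame(rows)
    finite = table[["T_pp_h", "T_pn_h", "T_nn_h"]].values
    finite = finite[~pd.isna(finite) & (finite != math.inf)]
    table.attrs["t_min"] = float(finite.min())
    table.attrs["t_max"] = float(finite.max())
    return table
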