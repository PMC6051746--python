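"""Bundled example measurements from chick neural tube experiments.

Small published summary tables used throughout the examples and the
reproduction script: division-mode fractions (Sox2/Tis21 reporter readout,
percent of scored progenitors) per condition and dorso-ventral zone with the
measured mean cell cycle duration, and post-mitotic nuclear fate counts
(apical/basal behaviour versus cell-cycle outcome).  Raw embryo data are not
public; these are the printed summary statistics.
"""

from __future__ import annotations

import pandas as pd

from .division_dynamics import CycleTiming, ModeFractions

__all__ = [
    "division_mode_conditions",
    "condition_list",
    "nuclear_fate_counts",
]


def division_mode_conditions() -> pd.DataFrame:
    """Division-mode percentages per condition x zone, with Tc (hours).

    Columns: ``condition, zone, pct_pp, pct_pn, pct_nn, tc_hours``.  The
    percentages are the Sox2+Tis21-, Sox2+Tis21+ and Sox2-Tis21+ classes
    scored 24 h after electroporation; conditions are the control, the
    CDC25B gain-of-function and the CDK-binding-deficient CDC25B mutant
    (``CDC25B-dCDK``).
    """
    rows = [
        ("control", "dorsal", 66.3, 25.9, 7.8, 12.0),
        ("CDC25B", "dorsal", 38.6, 50.1, 11.3, 12.0),
        ("CDC25B-dCDK", "dorsal", 40.2, 51.1, 8.0, 12.1),
        ("control", "ventral", 29.3, 58.0, 12.7, 12.0),
        ("CDC25B", "ventral", 6.9, 52.3, 40.7, 12.0),
        ("CDC25B-dCDK", "ventral", 16.6, 70.7, 12.7, 12.0),
    ]
    return pd.DataFrame(
        rows, columns=["condition", "zone", "pct_pp", "pct_pn", "pct_nn", "tc_hours"]
    )


def condition_list() -> list[tuple[str, ModeFractions, CycleTiming]]:
    """The same conditions as (label, ModeFractions, CycleTiming) tuples."""
    table = division_mode_conditions()
    out = []
    for _, r in table.iterrows():
        label = f"{r.condition} {r.zone}"
        total = r.pct_pp + r.pct_pn + r.pct_nn
        f = ModeFractions(r.pct_pp / total, r.pct_pn / total, r.pct_nn / total)
        out.append((label, f, CycleTiming(tc_hours=r.tc_hours)))
    return out


def nuclear_fate_counts() -> pd.DataFrame:
    """Post-mitotic nuclear behaviour x cell-cycle outcome counts.

    Columns: ``condition, behavior, s_phase, long_g1, nd`` — counts of
    daughter nuclei classified apical (Ap) or basal (Bs) at 20 min after
    cytokinesis that re-entered S phase, stayed in a long (>10 h) G1, or
    could not be followed long enough (ND).
    """
    rows = [
        ("WT", "Bs", 9, 7, 60),
        ("CDC25B", "Bs", 32, 5, 88),
        ("CDC25B-dCDK", "Bs", 40, 0, 107),
        ("WT", "Ap", 30, 6, 44),
        ("CDC25B", "Ap", 15, 6, 28),
        ("CDC25B-dCDK", "Ap", 16, 4, 45),
    ]
    return pd.DataFrame(rows, columns=["condition", "behavior", "s_phase", "long_g1", "nd"])
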