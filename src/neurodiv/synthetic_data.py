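"""Synthetic-data generators with known ground truth.

Every measurement the analysis modules consume can be generated here with a
known ground truth, enabling closed-loop recovery tests without microscopy
data:

* division-mode class counts (the Sox2/Tis21 reporter readout) — one
  multinomial draw;
* two-cell clone outcomes (the multicolor clonal readout scored by neuronal
  HuC/D immunostaining) — PP -> N-/N-, PN -> N-/N+, NN -> N+/N+;
* labeled-mitoses series from a phase-structured cycle model (see
  :mod:`neurodiv.plm_g2`);
* 1-D drift-diffusion nuclear tracks at 5-min frames with an apical
  reflecting boundary, mixing diffusive (Ap) and advective (Bs) daughters;
* binomial progenitor/neuron snapshot counts.

Defaults mirror the study conditions: mean cycle time 12 h, 5-min frame
interval, basal drift speed 1.10 µm/min.  The apical-daughter diffusivity
default (0.35 µm^2/min) is a calibration chosen so that the generated Ap
mean early frame-speed is about the measured 0.26 µm/min under 5-min
framing with reflection — a derived setting, not a measured diffusivity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .division_dynamics import ModeFractions, mode_fractions_from_counts
from .inm_tracks import NuclearTrack
from .plm_g2 import CellCyclePhases, PLMDataset, simulate_plm

__all__ = [
    "TrackParams",
    "GeneratorSpec",
    "gen_mode_counts",
    "gen_clone_pairs",
    "gen_tracks",
    "gen_plm",
    "gen_population_snapshot",
    "write_sidecar",
]

CLONE_CATEGORIES = ("N-/N-", "N-/N+", "N+/N+")


@dataclass(frozen=True)
class TrackParams:
    """Drift-diffusion parameters of the nuclear-track generator."""

    d_ap: float = 0.35  # µm^2/min, apical (diffusive) daughters — calibrated
    d_bs: float = 0.2  # µm^2/min, basal daughters
    v_bs: float = 1.1  # µm/min basal drift of Bs daughters
    frame_interval: float = 5.0  # min
    duration: float = 60.0  # min
    bs_fraction: float = 0.5  # behaviour mix (fraction of Bs daughters)
    substeps: int = 10  # Euler-Maruyama substeps per frame

    def __post_init__(self) -> None:
        if self.d_ap < 0 or self.d_bs < 0 or self.v_bs < 0:
            raise ValueError("D and v must be non-negative")
        if self.frame_interval <= 0 or self.duration <= 0 or self.substeps < 1:
            raise ValueError("frame interval, duration and substeps must be positive")
        if not (0.0 <= self.bs_fraction <= 1.0):
            raise ValueError("bs_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth for all generators, bundled with the master seed."""

    true_fractions: ModeFractions = field(
        default_factory=lambda: ModeFractions(0.663, 0.259, 0.078)
    )
    n_cells: int = 365
    clone_n: int = 387
    track_params: TrackParams = field(default_factory=TrackParams)
    plm_phases: CellCyclePhases = field(
        default_factory=lambda: CellCyclePhases(t_g1=7.7, t_s=2.0, t_g2=1.817, t_m=0.483)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.clone_n < 1:
            raise ValueError("counts must be >= 1")


def gen_mode_counts(spec: GeneratorSpec) -> tuple[int, int, int]:
    """One multinomial draw of division-mode class counts."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    counts = rng.multinomial(spec.n_cells, spec.true_fractions.as_array())
    return tuple(int(c) for c in counts)  # type: ignore[return-value]


def gen_clone_pairs(spec: GeneratorSpec) -> list[str]:
    """Two-cell clone categories from division modes.

    PP divisions yield two non-neuronal daughters (N-/N-), PN one of each
    (N-/N+), NN two neurons (N+/N+).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    modes = rng.choice(3, size=spec.clone_n, p=spec.true_fractions.as_array())
    return [CLONE_CATEGORIES[m] for m in modes]


def clone_fractions(categories: Sequence[str]) -> ModeFractions:
    """Recover division-mode fractions from clone categories."""
    counts = [sum(c == cat for c in categories) for cat in CLONE_CATEGORIES]
    return mode_fractions_from_counts(*counts)


def _simulate_track(
    rng: np.random.Generator,
    d: float,
    v: float,
    params: TrackParams,
) -> np.ndarray:
    """Euler-Maruyama 1-D drift-diffusion from x(0)=0, reflecting at x=0."""
    n_frames = int(round(params.duration / params.frame_interval))
    dt = params.frame_interval / params.substeps
    sd = np.sqrt(2.0 * d * dt)
    x = 0.0
    out = np.empty(n_frames + 1)
    out[0] = 0.0
    for i in range(1, n_frames + 1):
        for _ in range(params.substeps):
            x = abs(x + v * dt + sd * rng.standard_normal())
        out[i] = x
    return out


def gen_tracks(spec: GeneratorSpec, n_pairs: int = 100) -> list[NuclearTrack]:
    """Sibling-pair nuclear tracks with an Ap (diffusive) / Bs (advective) mix.

    Each daughter independently is Bs with probability
    ``track_params.bs_fraction`` (drift ``v_bs``, diffusivity ``d_bs``) and
    Ap otherwise (no drift, diffusivity ``d_ap``).  Cytokinesis is at the
    apical surface (x = 0) with a reflecting boundary there.
    """
    params = spec.track_params
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    times = tuple(
        params.frame_interval * i
        for i in range(int(round(params.duration / params.frame_interval)) + 1)
    )
    tracks: list[NuclearTrack] = []
    for pair in range(n_pairs):
        for daughter in ("a", "b"):
            is_bs = rng.random() < params.bs_fraction
            d = params.d_bs if is_bs else params.d_ap
            v = params.v_bs if is_bs else 0.0
            x = _simulate_track(rng, d, v, params)
            tracks.append(
                NuclearTrack(
                    nucleus_id=f"n{pair:04d}{daughter}",
                    pair_id=f"p{pair:04d}",
                    times=times,
                    positions=tuple(float(xi) for xi in x),
                    fate_label="ND",
                )
            )
    return tracks


def gen_plm(
    spec: GeneratorSpec,
    exposure_times: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    n_per_time: int = 100,
) -> PLMDataset:
    """Labeled-mitoses series sampled from the phase-structured cycle model."""
    return simulate_plm(
        spec.plm_phases,
        exposure_times,
        n_per_time,
        seed=int(np.random.SeedSequence([spec.seed, 4]).generate_state(1)[0] % (2**31)),
    )


def gen_population_snapshot(
    true_p: float, true_n: float, sample_n: int, seed: int = 0
) -> tuple[int, int]:
    """Observed (progenitors, neurons) among ``sample_n`` scored cells.

    Binomial draw of neurons at the true neuron fraction N/(N+P).
    """
    if sample_n < 1:
        raise ValueError("sample_n must be >= 1")
    if true_p + true_n <= 0:
        raise ValueError("true population must be non-empty")
    rng = np.random.default_rng(seed)
    frac = true_n / (true_p + true_n)
    neurons = int(rng.binomial(sample_n, frac))
    return sample_n - neurons, neurons


def write_sidecar(path: str | Path, spec: GeneratorSpec, **extra: object) -> Path:
    """Write ground-truth metadata as JSON next to a generated file.

    For a data file ``foo.csv`` this writes ``foo.truth.json`` recording the
    generator spec (fractions, counts, track and phase parameters, seed) and
    any extra key/value pairs, so recovery tests can compare estimates to
    the generating truth.
    """
    path = Path(path)
    sidecar = path.with_suffix(".truth.json")
    payload = {"generator": dataclasses.asdict(spec)}
    payload.update(extra)
    sidecar.write_text(json.dumps(payload, indent=2, default=str))
    return sidecar
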