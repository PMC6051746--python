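"""Interkinetic nuclear migration (INM) track statistics.

Daughter-nucleus tracks along the apico-basal axis, anchored at cytokinesis
(t = 0 at the apical surface, position in µm increasing basally, 5-min
frames by default).  Provides:

* Ap/Bs classification — a daughter is "basal" (Bs) if its nucleus sits
  strictly more than 10 µm from the apical surface 20 min after mitosis,
  "apical" (Ap) otherwise; sibling pairs combine to Ap/Ap, Ap/Bs or Bs/Bs.
* Mean squared displacement (MSD) profiling with bootstrap confidence
  intervals, and drift-diffusion model fitting: MSD(tau) = 2*D*tau for
  diffusive motion, MSD(tau) = v^2*tau^2 + 2*D*tau for advective motion.
* Mean nuclear speed over the first 20 min after mitosis.
* Contingency tabulation of behaviour class against cell-cycle fate
  (S-phase re-entry, long G1, not determined).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "NuclearTrack",
    "MSDProfile",
    "MotionFit",
    "ClassifierConfig",
    "classify_daughter",
    "pair_behavior",
    "msd_profile",
    "fit_motion_model",
    "mean_early_speed",
    "tabulate_fates",
]

Behavior = Literal["Ap", "Bs"]
FateLabel = Literal["S-phase", "LongG1", "ND"]


@dataclass(frozen=True)
class NuclearTrack:
    """Apico-basal positions (µm) of one daughter nucleus over time (min).

    Times are relative to cytokinesis (= 0); position 0 is the apical
    surface.  Frames must be evenly spaced.
    """

    nucleus_id: str
    pair_id: str
    times: tuple[float, ...]
    positions: tuple[float, ...]
    fate_label: FateLabel = "ND"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        if t.size != x.size:
            raise ValueError("times and positions must align")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(x < 0):
            raise ValueError("positions are distances from the apical surface (>= 0)")
        dt = np.diff(t)
        if dt.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("frame interval must be constant within a track")

    @property
    def frame_interval(self) -> float:
        dt = np.diff(np.asarray(self.times))
        return float(dt[0]) if dt.size else 0.0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times else 0.0

    def position_at_or_after(self, t: float) -> float:
        """Position at the nearest frame at or after time t."""
        times = np.asarray(self.times)
        idx = np.searchsorted(times, t - 1e-9)
        if idx >= times.size:
            raise ValueError(f"track {self.nucleus_id} ends before t={t} min")
        return float(self.positions[idx])


@dataclass(frozen=True)
class ClassifierConfig:
    """Ap/Bs decision rule: basal iff > ``basal_threshold`` µm from the
    apical surface at ``assessment_delay`` min after cytokinesis."""

    basal_threshold: float = 10.0
    assessment_delay: float = 20.0
    #: if set, the threshold is this fraction of the apico-basal length
    #: instead of the absolute ``basal_threshold``
    relative_fraction: float | None = None
    apicobasal_length: float | None = None

    def __post_init__(self) -> None:
        if self.basal_threshold <= 0 or self.assessment_delay <= 0:
            raise ValueError("threshold and delay must be positive")
        if self.relative_fraction is not None and self.apicobasal_length is None:
            raise ValueError("relative threshold mode needs apicobasal_length")

    @property
    def threshold(self) -> float:
        if self.relative_fraction is not None:
            return self.relative_fraction * float(self.apicobasal_length)
        return self.basal_threshold


class ClassificationFailure(ValueError):
    """Track does not span the assessment delay."""


def classify_daughter(track: NuclearTrack, cfg: ClassifierConfig | None = None) -> Behavior:
    """Classify a daughter nucleus as apical (Ap) or basal (Bs).

    Bs iff the position at the nearest frame at or after the assessment
    delay strictly exceeds the threshold ("more than" read strictly, so a
    nucleus at exactly 10 µm is Ap).
    """
    cfg = cfg or ClassifierConfig()
    try:
        x = track.position_at_or_after(cfg.assessment_delay)
    except ValueError as exc:
        raise ClassificationFailure(
            f"track {track.nucleus_id} too short to assess at "
            f"{cfg.assessment_delay} min"
        ) from exc
    return "Bs" if x > cfg.threshold else "Ap"


def pair_behavior(a: Behavior, b: Behavior) -> str:
    """Unordered sibling-pair behaviour: Ap/Ap, Ap/Bs or Bs/Bs."""
    for v in (a, b):
        if v not in ("Ap", "Bs"):
            raise ValueError(f"unknown behaviour {v!r}")
    return "/".join(sorted((a, b)))  # 'Ap' < 'Bs' lexicographically


@dataclass(frozen=True)
class MSDProfile:
    """Lag-indexed mean squared displacement with bootstrap 95% CI."""

    lags: np.ndarray  # minutes, starting at 0
    msd: np.ndarray  # µm^2
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_contributing: np.ndarray  # tracks contributing per lag
    #: bootstrap-resampled MSD curves (n_boot x n_lags); carried so model
    #: fitting can propagate the correlated per-lag uncertainty
    boot_msd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.msd[0] != 0.0 or self.lags[0] != 0.0:
            raise ValueError("MSD profile must start at (lag 0, MSD 0)")
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")


def _track_msd(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Per-track mean squared displacement over all overlapping pairs.

    Entry k is mean((x[i+k] - x[i])^2) over valid i; NaN where the track is
    too short.
    """
    out = np.full(n_lags + 1, np.nan)
    out[0] = 0.0
    for k in range(1, min(n_lags, x.size - 1) + 1):
        d = x[k:] - x[:-k]
        out[k] = float(np.mean(d * d))
    return out


def msd_profile(
    tracks: Sequence[NuclearTrack],
    max_lag: float = 60.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MSDProfile:
    """Average MSD across nuclei with a bootstrap-over-nuclei 95% CI.

    Uses all overlapping same-track displacement pairs per lag, averages
    within each track first, then across tracks.  The usable lag range is
    capped at half the shortest contributing track (long-lag estimates from
    few pairs are unreliable); the resampling unit of the bootstrap is the
    nucleus, since increments within a track are dependent.
    """
    tracks = [t for t in tracks if len(t.times) >= 2]
    if not tracks:
        raise ValueError("need at least one track with >= 2 frames")
    dt = tracks[0].frame_interval
    if any(abs(t.frame_interval - dt) > 1e-9 for t in tracks):
        raise ValueError("all tracks must share the same frame interval")
    shortest = min(t.duration for t in tracks)
    lag_cap = min(max_lag, shortest / 2.0)
    n_lags = max(1, int(np.floor(lag_cap / dt + 1e-9)))
    lags = dt * np.arange(n_lags + 1)

    per_track = np.vstack(
        [_track_msd(np.asarray(t.positions, dtype=float), n_lags) for t in tracks]
    )
    msd = np.nanmean(per_track, axis=0)
    n_contrib = np.sum(~np.isnan(per_track), axis=0)

    rng = np.random.default_rng(seed)
    n = len(tracks)
    boot = np.empty((n_boot, n_lags + 1))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = np.nanmean(per_track[idx], axis=0)
    lo, hi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    # the point estimate is the all-track mean; clip the band around it
    lo = np.minimum(lo, msd)
    hi = np.maximum(hi, msd)
    return MSDProfile(
        lags=lags, msd=msd, ci_low=lo, ci_high=hi, n_contributing=n_contrib,
        boot_msd=boot,
    )


@dataclass(frozen=True)
class MotionFit:
    """Fitted drift-diffusion parameters for an MSD profile."""

    d: float  # effective diffusivity, µm^2/min
    v: float  # advection speed, µm/min
    selected_model: Literal["diffusive", "advective"]
    fit_residual: float  # weighted RSS, µm^4

    def __post_init__(self) -> None:
        if self.d < 0 or self.v < 0:
            raise ValueError("D and v must be non-negative")
        if self.selected_model == "diffusive" and self.v != 0.0:
            raise ValueError("diffusive fit must have v = 0")


def fit_motion_model(profile: MSDProfile) -> MotionFit:
    """Weighted least-squares fit of diffusive vs advective MSD models.

    Fits MSD(tau) = 2*D*tau and MSD(tau) = v^2*tau^2 + 2*D*tau (both
    through the origin, non-negative coefficients) with weights from the
    bootstrap CI widths.  The advective model is selected iff it reduces
    the residual and its quadratic coefficient v^2 exceeds twice its
    standard error — mirroring the qualitative linear-vs-parabolic
    dichotomy.  An all-zero profile returns a diffusive fit with D = 0.
    """
    tau = np.asarray(profile.lags, dtype=float)[1:]  # drop the trivial lag 0
    y = np.asarray(profile.msd, dtype=float)[1:]
    if tau.size < 2:
        raise ValueError("need at least 3 lags (including lag 0) to fit")
    if np.all(y == 0):
        return MotionFit(d=0.0, v=0.0, selected_model="diffusive", fit_residual=0.0)

    sigma = (np.asarray(profile.ci_high) - np.asarray(profile.ci_low))[1:] / (2 * 1.96)
    if np.any(sigma <= 0):
        sigma = np.ones_like(y)  # degenerate/noise-free profile: unweighted
    w = 1.0 / sigma

    # diffusive: y = a * tau with a = 2D >= 0
    a_diff = max(0.0, float(np.sum(w**2 * tau * y) / np.sum(w**2 * tau * tau)))
    rss_diff = float(np.sum((w * (y - a_diff * tau)) ** 2))

    # advective: y = a * tau + b * tau^2, a = 2D >= 0, b = v^2 >= 0
    a_mat = np.column_stack([w * tau, w * tau**2])
    coef, _ = nnls(a_mat, w * y)
    a_adv, b_adv = float(coef[0]), float(coef[1])
    resid = w * y - a_mat @ coef
    rss_adv = float(np.sum(resid**2))

    # SE of the quadratic coefficient: refit on the bootstrap MSD curves
    # when available (correlated per-lag errors make the analytic WLS
    # covariance anti-conservative); analytic fallback otherwise
    if profile.boot_msd is not None and len(profile.boot_msd) > 1:
        design = np.column_stack([w * tau, w * tau**2])
        b_boot = [
            np.linalg.lstsq(design, w * yb[1:], rcond=None)[0][1]
            for yb in np.asarray(profile.boot_msd)
        ]
        se_b = float(np.std(b_boot, ddof=1))
    else:
        xtx = a_mat.T @ a_mat
        dof = max(1, tau.size - 2)
        try:
            cov = np.linalg.inv(xtx) * rss_adv / dof
            se_b = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            se_b = np.inf

    advective = rss_adv < rss_diff and b_adv > 2.0 * se_b
    if advective:
        return MotionFit(
            d=a_adv / 2.0,
            v=float(np.sqrt(b_adv)),
            selected_model="advective",
            fit_residual=rss_adv,
        )
    return MotionFit(
        d=a_diff / 2.0, v=0.0, selected_model="diffusive", fit_residual=rss_diff
    )


def mean_early_speed(
    track: NuclearTrack,
    window: float = 20.0,
    method: Literal["per_frame", "net"] = "per_frame",
) -> float:
    """Mean nuclear speed (µm/min) over the first ``window`` min after mitosis.

    ``per_frame`` (default) averages |dx|/dt over consecutive frame pairs
    whose endpoints both lie in [0, window]; ``net`` uses the net
    displacement over the window divided by the elapsed time.
    """
    t = np.asarray(track.times, dtype=float)
    x = np.asarray(track.positions, dtype=float)
    mask = (t >= 0) & (t <= window + 1e-9)
    if mask.sum() < 2:
        raise ValueError(
            f"track {track.nucleus_id} has fewer than 2 frames in [0, {window}] min"
        )
    tw, xw = t[mask], x[mask]
    if method == "net":
        return float(abs(xw[-1] - xw[0]) / (tw[-1] - tw[0]))
    if method != "per_frame":
        raise ValueError(f"unknown method {method!r}")
    return float(np.mean(np.abs(np.diff(xw)) / np.diff(tw)))


def tabulate_fates(
    classified: Iterable[tuple[Behavior, FateLabel]],
) -> pd.DataFrame:
    """Contingency table of behaviour (Ap/Bs) against cell-cycle fate.

    Input is (behaviour, fate) per daughter nucleus; fates are ``S-phase``
    (re-entered S during the movie), ``LongG1`` (G1 longer than 10 h without
    S re-entry) and ``ND`` (not determined).  Returns counts ``n_<fate>``
    and row percentages ``pct_<fate>`` (summing to 100 per behaviour row)
    plus the row total ``n_total``.
    """
    items = list(classified)
    if not items:
        raise ValueError("no classified daughters to tabulate")
    fates: tuple[FateLabel, ...] = ("S-phase", "LongG1", "ND")
    counts: dict[Behavior, Counter] = {"Ap": Counter(), "Bs": Counter()}
    for behavior, fate in items:
        if behavior not in counts:
            raise ValueError(f"unknown behaviour {behavior!r}")
        if fate not in fates:
            raise ValueError(f"unknown fate label {fate!r}")
        counts[behavior][fate] += 1
    rows = []
    for behavior in ("Ap", "Bs"):
        c = counts[behavior]
        total = sum(c.values())
        if total == 0:
            continue
        row: dict[str, object] = {"behavior": behavior, "n_total": total}
        for fate in fates:
            key = fate.replace("-", "_").lower()
            row[f"n_{key}"] = c[fate]
            row[f"pct_{key}"] = 100.0 * c[fate] / total
        rows.append(row)
    return pd.DataFrame(rows)
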