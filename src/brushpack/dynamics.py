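"""Drift-corrected mean-squared displacement and effective diffusion.

Tracks are (frame, id, x, y) tables at a fixed frame interval (15 fps in
the experiments, i.e. 0.0667 s).  Stage drift is removed by subtracting,
frame by frame, the ensemble-mean displacement of all particles present in
consecutive frames; the MSD is the time- and ensemble-averaged
⟨(r_i(t0+Δt) − r_i(t0))²⟩ and the effective diffusion coefficient is read
off at a reference lag, D_eff = ⟨Δr²(Δt ≈ 55 s)⟩ / (4Δt).

Note that subtracting the ensemble mean of N_p particles removes a
(1/N_p) share of each particle's own displacement, biasing the corrected
MSD down by a factor of about (1 − 1/N_p); this is negligible for the
hundreds of particles per field of view the method targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "MSDCurve",
    "drift_correct",
    "msd",
    "effective_diffusion",
]


@dataclass
class TrackSet:
    """Per-particle trajectories.

    ``data`` holds columns ``frame`` (int), ``id`` (int), ``x``, ``y``;
    frames are strictly increasing within each track.
    """

    data: pd.DataFrame
    frame_interval: float = 1.0 / 15.0

    def __post_init__(self) -> None:
        required = {"frame", "id", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.data = self.data.sort_values(["id", "frame"]).reset_index(drop=True)
        grp = self.data.groupby("id")["frame"]
        if (grp.diff().dropna() <= 0).any():
            raise ValueError("frames must be strictly increasing within a track")

    @property
    def n_tracks(self) -> int:
        return self.data["id"].nunique()


@dataclass(frozen=True)
class MSDCurve:
    """Time/ensemble-averaged mean-squared displacement per lag."""

    lag_times: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray


def drift_correct(ts: TrackSet, estimator: str = "mean") -> TrackSet:
    """Remove collective (stage) drift from all tracks.

    For each pair of consecutive frames the ensemble displacement of the
    particles present in both is estimated (``mean`` default, ``median``
    robust option) and its cumulative sum subtracted from every position.
    Relative positions within a frame are unchanged.  A single shared
    particle still defines the estimate (with a warning, since drift and
    diffusion are then indistinguishable); steps with no shared particle
    reuse the previous step's drift.
    """
    if estimator not in ("mean", "median"):
        raise ValueError("estimator must be 'mean' or 'median'")
    df = ts.data
    frames = np.sort(df["frame"].unique())
    if len(frames) < 2:
        return TrackSet(df.copy(), ts.frame_interval)
    reduce = np.mean if estimator == "mean" else np.median
    by_frame = {
        f: g.set_index("id")[["x", "y"]] for f, g in df.groupby("frame")
    }
    drift = {frames[0]: np.zeros(2)}
    last_step = np.zeros(2)
    warned = False
    for f_prev, f_next in zip(frames[:-1], frames[1:]):
        prev, nxt = by_frame[f_prev], by_frame[f_next]
        shared = prev.index.intersection(nxt.index)
        if len(shared) >= 1:
            disp = nxt.loc[shared].to_numpy() - prev.loc[shared].to_numpy()
            last_step = reduce(disp, axis=0)
        if len(shared) < 2 and not warned:
            warnings.warn(
                "fewer than two particles shared between consecutive frames; "
                "drift estimate is poorly constrained there"
            )
            warned = True
        drift[f_next] = drift[f_prev] + last_step
    corr = df.copy()
    shift = np.stack([drift[f] for f in corr["frame"]])
    corr[["x", "y"]] = corr[["x", "y"]].to_numpy() - shift
    return TrackSet(corr, ts.frame_interval)


def msd(ts: TrackSet, max_lag: int | None = None) -> MSDCurve:
    """Time- and ensemble-averaged MSD over all valid (t0, particle) pairs.

    Lags run over all integer frame multiples up to ``max_lag`` (default:
    a quarter of the longest track, for variance control).  Lags with no
    valid pair are reported with count 0 and MSD NaN.
    """
    df = ts.data
    longest = int(df.groupby("id")["frame"].count().max())
    if max_lag is None:
        max_lag = max(longest // 4, 1)
    if max_lag >= longest:
        raise ValueError("max_lag must be smaller than the longest track")
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for _, g in df.groupby("id"):
        f = g["frame"].to_numpy()
        xy = g[["x", "y"]].to_numpy()
        if len(f) > 1 and np.all(np.diff(f) == 1):  # contiguous fast path
            for lag in range(1, min(max_lag, len(f) - 1) + 1):
                d = xy[lag:] - xy[:-lag]
                sums[lag] += np.einsum("ij,ij->", d, d)
                counts[lag] += len(d)
        else:  # gap-tolerant path
            idx = {fi: k for k, fi in enumerate(f)}
            for lag in range(1, max_lag + 1):
                d2 = [
                    ((xy[idx[fi + lag]] - xy[k]) ** 2).sum()
                    for k, fi in enumerate(f)
                    if fi + lag in idx
                ]
                if d2:
                    sums[lag] += np.sum(d2)
                    counts[lag] += len(d2)
    counts[0] = len(df)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    vals[0] = 0.0
    lags = np.arange(max_lag + 1) * ts.frame_interval
    return MSDCurve(lag_times=lags, msd=vals, n_pairs=counts)


def effective_diffusion(curve: MSDCurve, t_ref: float = 55.0) -> float:
    """D_eff = MSD(Δt)/4Δt at the sampled lag closest to ``t_ref`` seconds.

    The actual lag used may differ from ``t_ref`` by up to half a frame
    spacing; the division uses the actual lag so a pure Brownian curve
    returns its true D at any t_ref.
    """
    valid = (curve.n_pairs > 0) & np.isfinite(curve.msd)
    valid[0] = False
    if not valid.any():
        raise ValueError("MSD curve has no valid lags")
    lag_valid = curve.lag_times[valid]
    if not (lag_valid.min() - 1e-12 <= t_ref <= lag_valid.max() + 1e-12):
        raise ValueError(
            f"t_ref = {t_ref} s outside the curve range "
            f"[{lag_valid.min():.4g}, {lag_valid.max():.4g}] s"
        )
    i = np.argmin(np.abs(lag_valid - t_ref))
    return float(curve.msd[valid][i] / (4.0 * lag_valid[i]))
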