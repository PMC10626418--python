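"""Single-particle tracking: trajectory linking, MSD, two-population fits,
and inverse-FRAP dispersal quantitation.

The mobility model is two-population free Brownian motion.  The mean squared
displacement of a 2-D Brownian walker observed with static localization
error sigma is MSD(t) = 4 D t + 4 sigma^2; the diffusion coefficient is
estimated from the first two MSD lag points.  Mixtures of a fast and a slow
population are resolved from the step-size distribution: the cumulative
probability of a squared displacement smaller than r^2 at lag t is

    P(r^2, t) = 1 - F exp(-r^2 / (4 D1 t)) - (1 - F) exp(-r^2 / (4 D2 t)),

fitted jointly across several lags for the fast fraction F and the two
coefficients D1 >= D2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, linear_sum_assignment

log = logging.getLogger("memnano")

__all__ = [
    "MSDCurve",
    "BinaryDiffusionFit",
    "IFRAPResult",
    "link_trajectories",
    "msd",
    "step_cdf",
    "fit_binary",
    "ifrap_analyze",
]


def link_trajectories(
    t: pd.DataFrame,
    max_jump_nm: float = 800.0,
    max_gap_frames: int = 1,
    max_steps: int = 50,
) -> pd.DataFrame:
    """Link localizations into trajectories by per-frame optimal assignment.

    For every frame, active track ends (last seen within ``max_gap_frames``)
    are matched to the frame's detections by minimising the summed
    displacement (Hungarian assignment) among pairs within ``max_jump_nm``.
    Unmatched detections open new tracks.  Tracks are truncated at
    ``max_steps`` steps for analysis.  Deterministic, and invariant to the
    input row order within a frame up to track numbering.
    """
    df = t.sort_values(["frame", "x_nm", "y_nm"], kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy(int)
    xy = df[["x_nm", "y_nm"]].to_numpy(float)
    track_of = np.full(len(df), -1, dtype=int)

    # active tracks: id -> (last frame, last xy, n_steps)
    act_id: list[int] = []
    act_frame: list[int] = []
    act_xy: list[np.ndarray] = []
    act_len: list[int] = []
    next_id = 0

    for f in np.unique(frames):
        rows = np.nonzero(frames == f)[0]
        pts = xy[rows]
        # retire stale or full tracks
        alive = [
            k
            for k in range(len(act_id))
            if f - act_frame[k] <= max_gap_frames and act_len[k] < max_steps
        ]
        assigned_rows = np.full(len(rows), False)
        if alive and len(rows):
            prev = np.array([act_xy[k] for k in alive])
            cost = np.linalg.norm(prev[:, None, :] - pts[None, :, :], axis=2)
            big = max_jump_nm * 1e6
            cost_g = np.where(cost <= max_jump_nm, cost, big)
            ri, ci = linear_sum_assignment(cost_g)
            for a, b in zip(ri, ci):
                if cost[a, b] <= max_jump_nm:
                    k = alive[a]
                    track_of[rows[b]] = act_id[k]
                    act_frame[k] = f
                    act_xy[k] = pts[b]
                    act_len[k] += 1
                    assigned_rows[b] = True
        for j, r in enumerate(rows):
            if not assigned_rows[j]:
                track_of[r] = next_id
                act_id.append(next_id)
                act_frame.append(f)
                act_xy.append(pts[j])
                act_len.append(0)
                next_id += 1

    out = df[["frame", "x_nm", "y_nm"]].copy()
    out.insert(0, "track_id", track_of)
    return out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


def _displacements(tracks: pd.DataFrame, lag: int) -> np.ndarray:
    """Squared displacements (nm^2) at an integer frame lag, pooled over all
    tracks and start points."""
    out = []
    for _, g in tracks.groupby("track_id", sort=False):
        fr = g["frame"].to_numpy(int)
        xy = g[["x_nm", "y_nm"]].to_numpy(float)
        order = np.argsort(fr)
        fr, xy = fr[order], xy[order]
        # fixed frame interval assumed; use positional lag on consecutive frames
        if len(fr) <= lag:
            continue
        d = xy[lag:] - xy[:-lag]
        ok = (fr[lag:] - fr[:-lag]) == lag * (fr[1] - fr[0]) if len(fr) > 1 else np.ones(0, bool)
        out.append((d[ok] ** 2).sum(axis=1))
    return np.concatenate(out) if out else np.zeros(0)


@dataclass
class MSDCurve:
    lags_ms: np.ndarray
    msd_um2: np.ndarray
    d_um2_s: float
    offset_um2: float
    n_per_lag: np.ndarray


def msd(tracks: pd.DataFrame, dt_ms: float = 10.5, max_lag: int = 10) -> MSDCurve:
    """Ensemble MSD over all tracks and start points; D from the first two
    lag points of MSD = 4 D t + 4 sigma^2."""
    vals, ns = [], []
    for lag in range(1, max_lag + 1):
        sq = _displacements(tracks, lag)
        vals.append(sq.mean() / 1e6 if len(sq) else np.nan)  # nm^2 -> um^2
        ns.append(len(sq))
    msd_um2 = np.asarray(vals)
    lags_ms = np.arange(1, max_lag + 1) * dt_ms
    if np.isnan(msd_um2[:2]).any():
        raise ValueError("need displacements at the first two lags")
    slope = (msd_um2[1] - msd_um2[0]) / (dt_ms / 1000.0)
    d = max(slope / 4.0, 0.0)
    offset = msd_um2[0] - slope * dt_ms / 1000.0
    return MSDCurve(lags_ms, msd_um2, float(d), float(offset), np.asarray(ns))


def step_cdf(tracks: pd.DataFrame, lags: Sequence[int], min_n: int = 50) -> dict[int, np.ndarray]:
    """Sorted squared displacements per lag (the empirical CDF support);
    lags with fewer than ``min_n`` displacements are dropped with a warning."""
    out = {}
    for lag in lags:
        sq = _displacements(tracks, lag)
        if len(sq) < min_n:
            log.warning("lag %d dropped: only %d displacements", lag, len(sq))
            continue
        out[lag] = np.sort(sq)
    return out


@dataclass
class BinaryDiffusionFit:
    fast_fraction: float
    d1_um2_s: float
    d2_um2_s: float
    residual: float
    n_lags: int
    degenerate: bool = False  # single-population input; D2 unconstrained


def _cdf_model(r2_nm2, t_s, alpha, d1, d2):
    # D in um^2/s, r^2 in nm^2: 4 D t in um^2 -> nm^2 via 1e6
    s1 = 4.0 * d1 * t_s * 1e6
    s2 = 4.0 * d2 * t_s * 1e6
    return 1.0 - alpha * np.exp(-r2_nm2 / s1) - (1.0 - alpha) * np.exp(-r2_nm2 / np.maximum(s2, 1e-12))


def fit_binary(
    cdfs: dict[int, np.ndarray],
    dt_ms: float = 10.5,
    n_eval: int = 200,
) -> BinaryDiffusionFit:
    """Joint least-squares fit of the two-population step-size CDF across lags.

    ``cdfs`` maps integer frame lags to sorted squared displacements (nm^2)
    as produced by :func:`step_cdf`.  Each lag's empirical CDF is evaluated
    on ``n_eval`` quantile points and all lags are fitted simultaneously with
    shared parameters (F, D1, D2).  When the fitted fraction is ~1 (or ~0)
    the second coefficient is unconstrained and the result is flagged.
    """
    if len(cdfs) < 2:
        raise ValueError("need >= 2 lags for the binary fit")
    xs, ys, ts = [], [], []
    for lag, sq in sorted(cdfs.items()):
        q = np.linspace(0.5 / n_eval, 1 - 0.5 / n_eval, n_eval)
        r2 = np.quantile(sq, q)
        xs.append(r2)
        ys.append(q)
        ts.append(np.full(n_eval, lag * dt_ms / 1000.0))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t_s = np.concatenate(ts)

    # moment-based start: single-D estimate, split up/down
    d0 = max(np.mean(x / (4.0 * t_s * 1e6)), 1e-6)

    def resid(p):
        a = 1.0 / (1.0 + np.exp(-p[0]))
        d1 = np.exp(p[1])
        d2 = np.exp(p[2])
        return _cdf_model(x, t_s, a, d1, d2) - y

    best = None
    for a0 in (0.5, 0.8):
        p0 = np.array([np.log(a0 / (1 - a0)), np.log(3 * d0), np.log(max(d0 / 10, 1e-6))])
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("binary diffusion fit failed to converge")
    a = 1.0 / (1.0 + np.exp(-best.x[0]))
    d1, d2 = np.exp(best.x[1]), np.exp(best.x[2])
    if d2 > d1:  # enforce D1 >= D2 by relabelling
        d1, d2, a = d2, d1, 1.0 - a
    degenerate = a >= 0.95 or a <= 0.05
    if a <= 0.05:
        # single-population input: the minority "fast" component is spurious,
        # so collapse onto the dominant coefficient (second one unconstrained)
        a, d1, d2 = 1.0, d2, 0.0
    return BinaryDiffusionFit(float(a), float(d1), float(d2), float(2 * best.cost), len(cdfs), degenerate)


@dataclass
class IFRAPResult:
    time_s: np.ndarray
    i_in: np.ndarray  # bleach-corrected, background-subtracted mean inside the converted region
    i_out: np.ndarray
    out_in_ratio: np.ndarray
    i_in_normalized: np.ndarray


def ifrap_analyze(
    stack: np.ndarray,
    roi_in: tuple[slice, slice],
    roi_out: tuple[slice, slice],
    frame_interval_s: float = 1.0,
    bleach_per_frame: float = 0.03,
    background: float = 0.0,
) -> IFRAPResult:
    """Inverse-FRAP dispersal analysis of an image time series.

    Mean background-subtracted intensities are extracted from the
    photo-converted region (``roi_in``) and a distal control region
    (``roi_out``); frame k is divided by (1 - bleach_per_frame)^k to correct
    acquisition photobleaching.  Reports the out/in ratio trace and the
    normalized decay of the converted region.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need an image stack with >= 2 frames")
    n = stack.shape[0]
    corr = (1.0 - bleach_per_frame) ** np.arange(n)
    i_in = np.array([s[roi_in].mean() for s in stack]) - background
    i_out = np.array([s[roi_out].mean() for s in stack]) - background
    i_in = np.clip(i_in, 0, None) / corr
    i_out = np.clip(i_out, 0, None) / corr
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i_in > 0, i_out / i_in, np.inf)
    norm = i_in / i_in[0] if i_in[0] > 0 else i_in
    return IFRAPResult(np.arange(n) * frame_interval_s, i_in, i_out, ratio, norm)
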