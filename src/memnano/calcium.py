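"""Ratiometric calcium-trace processing and dose-response statistics.

Fura-2 340/380 ratio traces are normalized to the median of a negative
control, an activation threshold is placed by a receiver-operating-curve
between positive- and negative-control per-cell summaries, and each cell is
classified as activated (>= 80% of its frames above the threshold),
non-activated (>= 80% below), or oscillatory (neither).  Activated fractions
versus ligand density are fitted with the logistic dose-response

    Y = Bottom + X^n (Top - Bottom) / (X^n + T_A^n)

to extract the activation threshold T_A (density at half-maximal response);
two conditions are compared by a case-resampling bootstrap of the ratio
T_A1 / T_A2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


log = logging.getLogger("memnano")

__all__ = [
    "ActivationClassification",
    "DoseResponseFit",
    "normalize_traces",
    "roc_threshold",
    "classify",
    "fit_dose_response",
    "bootstrap_ratio_test",
]


def _trace_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cells = df["cell_id"].unique()
    mat = [df.loc[df["cell_id"] == c].sort_values("frame")["ratio"].to_numpy(float) for c in cells]
    return cells, mat


def normalize_traces(
    traces: pd.DataFrame,
    negative_control: Optional[pd.DataFrame] = None,
    mode: str = "control_median",
) -> pd.DataFrame:
    """Normalize ratio traces to the pooled median of a negative control
    (default), or each trace to its own first value (``mode='self_start'``)."""
    out = traces.copy()
    if mode == "control_median":
        if negative_control is None or len(negative_control) == 0:
            raise ValueError("control traces required for control-median normalization")
        med = float(np.median(negative_control["ratio"]))
        if med == 0:
            raise ValueError("control median is zero")
        out["ratio"] = out["ratio"] / med
    elif mode == "self_start":
        firsts = (
            out.sort_values("frame").groupby("cell_id")["ratio"].first().rename("start")
        )
        out = out.join(firsts, on="cell_id")
        out["ratio"] = out["ratio"] / out.pop("start")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out


def peak_summary(trace: np.ndarray, window: int = 10) -> float:
    """Median of the window [peak frame, peak frame + 10] of one trace."""
    i = int(np.argmax(trace))
    return float(np.median(trace[i : i + window + 1]))


def roc_threshold(positive: pd.DataFrame, negative: pd.DataFrame) -> float:
    """Activation threshold maximizing Youden's J between the positive- and
    negative-control per-cell peak summaries.

    The threshold is the midpoint between neighbouring summary values at the
    optimal cut.  Identical distributions trigger a warning and return the
    shared median.
    """
    if len(positive) == 0 or len(negative) == 0:
        raise ValueError("both control sets must be non-empty")
    _, pos_m = _trace_matrix(positive)
    _, neg_m = _trace_matrix(negative)
    pos = np.array([peak_summary(t) for t in pos_m])
    neg = np.array([peak_summary(t) for t in neg_m])
    if np.array_equal(np.sort(pos), np.sort(neg)):
        log.warning("positive and negative summaries identical; threshold at shared median")
        return float(np.median(pos))
    allv = np.unique(np.concatenate([pos, neg]))
    cand = (allv[:-1] + allv[1:]) / 2.0
    j = np.array([(pos > c).mean() - (neg > c).mean() for c in cand])
    return float(cand[int(np.argmax(j))])


@dataclass
class ActivationClassification:
    labels: pd.Series  # index cell_id; activated / oscillatory / non-activated
    threshold: float
    peak_summaries: pd.Series

    def fraction(self, label: str) -> float:
        return float((self.labels == label).mean())


def classify(traces: pd.DataFrame, threshold: float, rule_fraction: float = 0.8):
    """Classify each cell: activated if >= 80% of frames are above the
    threshold, non-activated if >= 80% are below, otherwise oscillatory."""
    cells, mats = _trace_matrix(traces)
    labels, peaks = {}, {}
    for c, tr in zip(cells, mats):
        above = (tr > threshold).mean()
        if above >= rule_fraction:
            labels[c] = "activated"
        elif (1.0 - above) >= rule_fraction:
            labels[c] = "non-activated"
        else:
            labels[c] = "oscillatory"
        peaks[c] = peak_summary(tr)
    return ActivationClassification(pd.Series(labels), threshold, pd.Series(peaks))


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    t_a: float  # density at half-maximal response
    hill: float
    sse: float
    t_a_sd: float = np.nan
    wide_ci: bool = False  # data span < half the response range


def _profile_sse(x, y, t_a, hill):
    """For fixed (T_A, n) the model is linear in (Bottom, Top); solve the
    2-parameter least squares in closed form, vectorized over candidate T_A
    values.  Returns (sse, bottom, top) arrays matching ``t_a``."""
    t_a = np.atleast_1d(np.asarray(t_a, float))
    xh = x**hill
    w = xh[None, :] / (xh[None, :] + t_a[:, None] ** hill)
    u = 1.0 - w
    s_aa = (u * u).sum(axis=1)
    s_ab = (u * w).sum(axis=1)
    s_bb = (w * w).sum(axis=1)
    s_ay = (u * y[None, :]).sum(axis=1)
    s_by = (w * y[None, :]).sum(axis=1)
    det = s_aa * s_bb - s_ab**2
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    bottom = (s_bb * s_ay - s_ab * s_by) / det
    top = (s_aa * s_by - s_ab * s_ay) / det
    sse = (y**2).sum() - bottom * s_ay - top * s_by
    return sse, bottom, top


def fit_dose_response(
    densities: Sequence[float],
    activated_fractions: Sequence[float],
    fix_hill: bool = True,
) -> DoseResponseFit:
    """Least-squares logistic dose-response fit (three-parameter with
    hillslope n = 1 when ``fix_hill``, else four-parameter).

    Bottom and Top are profiled out in closed form; T_A (and n) are found by
    golden-section refinement of a log-spaced scan, which keeps a bootstrap
    of thousands of refits cheap.
    """
    x = np.asarray(densities, float)
    y = np.asarray(activated_fractions, float)
    if len(x) < 4:
        raise ValueError("need >= 4 dose levels")
    if np.any(x <= 0):
        raise ValueError("densities must be > 0")
    lo, hi = np.log(x.min() / 10.0), np.log(x.max() * 10.0)
    hills = [1.0] if fix_hill else np.geomspace(0.3, 5.0, 12)
    best = None
    for n in hills:
        g_lo, g_hi = lo, hi
        for _ in range(4):  # coarse grid + zoom refinement, all vectorized
            grid = np.linspace(g_lo, g_hi, 33)
            sse, bottom, top = _profile_sse(x, y, np.exp(grid), n)
            i = int(np.nanargmin(sse))
            step = grid[1] - grid[0]
            g_best = grid[i]
            g_lo, g_hi = g_best - step, g_best + step
        if best is None or sse[i] < best[0]:
            best = (float(sse[i]), float(bottom[i]), float(top[i]), float(np.exp(g_best)), float(n))
    sse, bottom, top, t_a, hill = best
    if not np.isfinite(sse):
        raise RuntimeError("dose-response fit failed")
    span = y.max() - y.min()
    wide = span < 0.5 * abs(top - bottom) if top != bottom else True
    if wide:
        log.warning("data span < half the fitted response range; T_A poorly constrained")
    return DoseResponseFit(top, bottom, t_a, hill, sse, wide_ci=wide)


def bootstrap_ratio_test(
    densities1,
    n_cells1,
    activated1,
    densities2,
    n_cells2,
    activated2,
    n_boot: int = 1000,
    fix_hill: bool = True,
    seed=None,
):
    """Bootstrap ratio test for H0: T_A1 / T_A2 = 1.

    Each dataset is given per dose level as (densities, cells measured,
    cells activated).  Cells are case-resampled within each dose level
    (binomial resampling of the per-cell activation outcomes), both fits are
    repeated per replicate, and the two-sided percentile p-value of the
    bootstrap log-ratio distribution is returned together with the bootstrap
    sd of each T_A.  Errors out if more than 20% of replicate fits fail.
    """
    rng = np.random.default_rng(seed)
    d1, n1, a1 = (np.asarray(v, float) for v in (densities1, n_cells1, activated1))
    d2, n2, a2 = (np.asarray(v, float) for v in (densities2, n_cells2, activated2))
    base1 = fit_dose_response(d1, a1 / n1, fix_hill).t_a
    base2 = fit_dose_response(d2, a2 / n2, fix_hill).t_a
    log_ratios = []
    t1s, t2s = [], []
    failures = 0
    for _ in range(n_boot):
        try:
            f1 = rng.binomial(n1.astype(int), a1 / n1) / n1
            f2 = rng.binomial(n2.astype(int), a2 / n2) / n2
            t1 = fit_dose_response(d1, f1, fix_hill).t_a
            t2 = fit_dose_response(d2, f2, fix_hill).t_a
            log_ratios.append(np.log(t1 / t2))
            t1s.append(t1)
            t2s.append(t2)
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap replicate fits failed")
    lr = np.asarray(log_ratios)
    # two-sided percentile p for the null log-ratio 0
    p_low = (lr <= 0).mean()
    p_high = (lr >= 0).mean()
    p = min(1.0, 2.0 * min(p_low, p_high))
    return {
        "p_value": float(p),
        "t_a1": float(base1),
        "t_a2": float(base2),
        "t_a1_sd": float(np.std(t1s, ddof=1)),
        "t_a2_sd": float(np.std(t2s, ddof=1)),
        "n_boot_used": len(lr),
    }
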