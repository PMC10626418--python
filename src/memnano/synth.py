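"""Synthetic single-molecule data generators.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the downstream estimators assume: spatially random (or
deliberately clustered) molecular point patterns, localization tables with
fluorophore blinking, finite localization precision and optional Brownian
motion, single-particle trajectories from a two-population diffusion model,
single-spot brightness samples built from mixtures of N-mer convolutions, and
ratiometric calcium traces of activated / oscillatory / non-activated cells.

Defaults emulate membrane-resident MHC class II molecules imaged by
high-speed PALM on live antigen-presenting cells: surface densities of tens
to a few thousand molecules per um^2, a localization precision of 51 +/- 12 nm,
and binary Brownian diffusion with a fast fraction of 0.6-0.85
(D1 ~ 0.15-0.55 um^2/s, D2 ~ 0.02-0.05 um^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PointPattern",
    "ClusterSpec",
    "BlinkStatistics",
    "DiffusionModel",
    "gen_point_pattern",
    "gen_localizations",
    "gen_trajectories",
    "gen_brightness_sample",
    "gen_calcium_traces",
]


@dataclass
class ClusterSpec:
    """Nanocluster geometry: disk radius (nm), fraction of molecules inside
    clusters, and cluster-center density (per um^2)."""

    radius_nm: float
    fraction: float
    clusters_per_um2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("cluster fraction must be in [0, 1]")
        if self.radius_nm <= 0:
            raise ValueError("cluster radius must be > 0")
        if self.clusters_per_um2 < 0:
            raise ValueError("cluster density must be >= 0")


@dataclass
class PointPattern:
    """Molecule positions inside a rectangular ROI (nm, origin lower-left)."""

    x: np.ndarray
    y: np.ndarray
    width_nm: float
    height_nm: float
    labels: Optional[np.ndarray] = None  # cluster index per point, -1 = dispersed

    def __len__(self) -> int:
        return len(self.x)

    @property
    def area_um2(self) -> float:
        return self.width_nm * self.height_nm / 1e6

    @property
    def density_um2(self) -> float:
        return len(self) / self.area_um2


@dataclass
class BlinkStatistics:
    """Empirical distribution of detections per molecule N (N >= 1) plus an
    off-gap distribution (frames between successive detections).

    The detections-per-molecule table is the quantity obtained from a blinking
    calibration of the photoswitchable label on immobilized platforms; the
    default here is a stand-in (geometric-like, mean ~2 detections) and should
    be replaced with a measured table when one is available.  The off gap
    defaults to a geometric distribution with mean 2 frames truncated at the
    blink-merge gate, which is the minimum needed to place detections on
    frames.
    """

    probabilities: np.ndarray  # P(N = 1), P(N = 2), ...
    gap_mean_frames: float = 2.0
    max_gap_frames: int = 20

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or len(p) == 0 or np.any(p < 0):
            raise ValueError("probabilities must be a non-empty 1-D array >= 0")
        s = p.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            p = p / s
        self.probabilities = p

    @classmethod
    def default(cls) -> "BlinkStatistics":
        # Stand-in detections-per-molecule table, mean N ~ 2. User-replaceable.
        p = np.array([0.50, 0.25, 0.12, 0.07, 0.04, 0.02])
        return cls(probabilities=p / p.sum())

    @classmethod
    def no_blinking(cls) -> "BlinkStatistics":
        return cls(probabilities=np.array([1.0]))

    @classmethod
    def from_counts(cls, counts: Sequence[int], **kw) -> "BlinkStatistics":
        counts = np.asarray(counts, dtype=int)
        if np.any(counts < 1):
            raise ValueError("detection counts must be >= 1")
        nmax = counts.max()
        p = np.bincount(counts, minlength=nmax + 1)[1:].astype(float)
        return cls(probabilities=p / p.sum(), **kw)

    @property
    def mean_detections(self) -> float:
        n = np.arange(1, len(self.probabilities) + 1)
        return float(np.sum(n * self.probabilities))

    def sample_counts(self, size: int, rng: np.random.Generator) -> np.ndarray:
        n = np.arange(1, len(self.probabilities) + 1)
        return rng.choice(n, size=size, p=self.probabilities)

    def sample_gaps(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Off gaps in frames (>= 1), geometric with the configured mean,
        truncated at the merge gate."""
        if size == 0:
            return np.zeros(0, dtype=int)
        p = 1.0 / max(self.gap_mean_frames, 1.0)
        g = rng.geometric(p, size=size)
        return np.minimum(g, self.max_gap_frames)


@dataclass
class DiffusionModel:
    """Two-population Brownian diffusion: a fast fraction ``fast_fraction``
    with coefficient ``d1_um2_s`` and a slow remainder with ``d2_um2_s``,
    sampled at a fixed frame interval, with static localization noise
    ``sigma_nm`` added to every position."""

    fast_fraction: float = 0.83
    d1_um2_s: float = 0.284
    d2_um2_s: float = 0.046
    dt_ms: float = 10.5
    sigma_nm: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fast_fraction <= 1.0):
            raise ValueError("fast_fraction must be in [0, 1]")
        if self.d1_um2_s < self.d2_um2_s or self.d2_um2_s < 0:
            raise ValueError("require D1 >= D2 >= 0")

    @property
    def mean_d(self) -> float:
        f = self.fast_fraction
        return f * self.d1_um2_s + (1 - f) * self.d2_um2_s

    def step_sigma_nm(self, d_um2_s: float, dt_ms: Optional[float] = None) -> float:
        """Per-axis standard deviation (nm) of a Brownian step over dt."""
        dt = self.dt_ms if dt_ms is None else dt_ms
        return float(np.sqrt(2.0 * d_um2_s * dt / 1000.0) * 1000.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_point_pattern(
    density_um2: float,
    roi_nm: tuple[float, float] = (3000.0, 3000.0),
    spec: Optional[ClusterSpec] = None,
    seed=None,
) -> PointPattern:
    """Draw a molecular point pattern at the requested surface density.

    Without a :class:`ClusterSpec` the pattern is completely spatially random
    (Poisson count, uniform positions).  With a spec, cluster centers are
    Poisson at the stated rate, the in-cluster fraction of molecules is placed
    uniformly within disks of the stated radius around random centers (wrapped
    toroidally so that density stays exact near edges), and the remainder is
    uniform.
    """
    if density_um2 <= 0:
        raise ValueError("density must be > 0")
    rng = _as_rng(seed)
    w, h = float(roi_nm[0]), float(roi_nm[1])
    area_um2 = w * h / 1e6
    n = int(rng.poisson(density_um2 * area_um2))
    labels = np.full(n, -1, dtype=int)
    if spec is None or spec.fraction == 0.0 or n == 0:
        x = rng.uniform(0, w, n)
        y = rng.uniform(0, h, n)
        return PointPattern(x, y, w, h, labels)

    n_in = int(round(spec.fraction * n))
    if n_in > n:
        raise ValueError("in-cluster count exceeds total molecule count")
    n_centers = int(rng.poisson(spec.clusters_per_um2 * area_um2))
    if n_in > 0 and n_centers == 0:
        n_centers = 1
    cx = rng.uniform(0, w, n_centers)
    cy = rng.uniform(0, h, n_centers)
    assign = rng.integers(0, n_centers, n_in) if n_centers else np.zeros(0, int)
    # uniform in disk
    r = spec.radius_nm * np.sqrt(rng.uniform(0, 1, n_in))
    th = rng.uniform(0, 2 * np.pi, n_in)
    xin = np.mod(cx[assign] + r * np.cos(th), w)
    yin = np.mod(cy[assign] + r * np.sin(th), h)
    xout = rng.uniform(0, w, n - n_in)
    yout = rng.uniform(0, h, n - n_in)
    x = np.concatenate([xin, xout])
    y = np.concatenate([yin, yout])
    labels[: n_in] = assign
    return PointPattern(x, y, w, h, labels)


def gen_localizations(
    pattern: PointPattern,
    blinks: Optional[BlinkStatistics] = None,
    precision_mean_sd_nm: tuple[float, float] = (51.0, 12.0),
    diffusion: Optional[DiffusionModel] = None,
    n_frames: int = 3050,
    psf_sigma_nm: float = 160.0,
    seed=None,
) -> pd.DataFrame:
    """Turn a molecular point pattern into a localization table.

    Each molecule yields N detections drawn from the blinking statistics; the
    detections occupy consecutive frames separated by drawn off gaps, starting
    at a random frame.  Every detection is displaced isotropically by a normal
    localization error whose per-molecule standard deviation is drawn from
    ``precision_mean_sd_nm``.  If a diffusion model is given, each molecule is
    assigned to the fast population with probability F and performs a Brownian
    walk between its detection frames; positions wrap toroidally in the ROI so
    that the density stays exact.

    Returns the canonical localization table with columns
    ``frame, x_nm, y_nm, sigma_nm, uncertainty_nm, intensity``.
    """
    if precision_mean_sd_nm[0] <= 0:
        raise ValueError("precision mean must be > 0")
    rng = _as_rng(seed)
    blinks = blinks or BlinkStatistics.no_blinking()
    n_mol = len(pattern)
    counts = blinks.sample_counts(n_mol, rng)
    total = int(counts.sum())
    mol_idx = np.repeat(np.arange(n_mol), counts)

    # per-molecule localization precision, truncated away from zero
    prec = rng.normal(precision_mean_sd_nm[0], precision_mean_sd_nm[1], n_mol)
    prec = np.clip(prec, 1e-12, None)  # truncate rare negative draws

    # frame assignment: random start, consecutive detections separated by gaps
    gaps = blinks.sample_gaps(total, rng)
    frames = np.empty(total, dtype=int)
    pos = 0
    starts = rng.integers(1, max(n_frames, 2), n_mol)
    for i in range(n_mol):
        c = counts[i]
        g = gaps[pos : pos + c]
        g[0] = 0
        frames[pos : pos + c] = starts[i] + np.cumsum(g)
        pos += c

    x = pattern.x[mol_idx].astype(float).copy()
    y = pattern.y[mol_idx].astype(float).copy()

    if diffusion is not None and total:
        fast = rng.uniform(size=n_mol) < diffusion.fast_fraction
        d = np.where(fast, diffusion.d1_um2_s, diffusion.d2_um2_s)
        pos = 0
        for i in range(n_mol):
            c = counts[i]
            if c > 1:
                dframes = np.diff(frames[pos : pos + c]).astype(float)
                dt_ms = dframes * diffusion.dt_ms
                s = np.sqrt(2.0 * d[i] * dt_ms / 1000.0) * 1000.0  # nm
                x[pos + 1 : pos + c] += np.cumsum(rng.normal(0, s))
                y[pos + 1 : pos + c] += np.cumsum(rng.normal(0, s))
            pos += c
        x = np.mod(x, pattern.width_nm)
        y = np.mod(y, pattern.height_nm)

    # localization error
    err = prec[mol_idx]
    x = np.mod(x + rng.normal(0, 1, total) * err, pattern.width_nm)
    y = np.mod(y + rng.normal(0, 1, total) * err, pattern.height_nm)

    df = pd.DataFrame(
        {
            "frame": frames,
            "x_nm": x,
            "y_nm": y,
            "sigma_nm": np.full(total, float(psf_sigma_nm)),
            "uncertainty_nm": err,
            "intensity": np.full(total, np.nan),
        }
    )
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def gen_trajectories(
    model: DiffusionModel,
    n_tracks: int,
    steps: int,
    seed=None,
    return_labels: bool = False,
):
    """Simulate two-population Brownian trajectories.

    Each track joins the fast population with probability F; per-axis
    displacements are normal with variance 2 D dt; static localization noise
    sigma is added independently to every position.  Returns a trajectory
    table ``track_id, frame, x_nm, y_nm`` (and optionally the per-track
    fast/slow assignment).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    rng = _as_rng(seed)
    fast = rng.uniform(size=n_tracks) < model.fast_fraction
    d = np.where(fast, model.d1_um2_s, model.d2_um2_s)
    step_sd_nm = np.sqrt(2.0 * d * model.dt_ms / 1000.0) * 1000.0
    n_pos = steps + 1
    dx = rng.normal(0, 1, (n_tracks, steps)) * step_sd_nm[:, None]
    dy = rng.normal(0, 1, (n_tracks, steps)) * step_sd_nm[:, None]
    x = np.concatenate([np.zeros((n_tracks, 1)), np.cumsum(dx, axis=1)], axis=1)
    y = np.concatenate([np.zeros((n_tracks, 1)), np.cumsum(dy, axis=1)], axis=1)
    if model.sigma_nm > 0:
        x = x + rng.normal(0, model.sigma_nm, (n_tracks, n_pos))
        y = y + rng.normal(0, model.sigma_nm, (n_tracks, n_pos))
    df = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n_tracks), n_pos),
            "frame": np.tile(np.arange(1, n_pos + 1), n_tracks),
            "x_nm": x.ravel(),
            "y_nm": y.ravel(),
        }
    )
    if return_labels:
        return df, fast
    return df


def gen_brightness_sample(
    weights: Sequence[float],
    monomer_mean: float = 100.0,
    monomer_sd: float = 20.0,
    n: int = 500,
    seed=None,
) -> np.ndarray:
    """Draw single-spot brightness values from a monomer/N-mer mixture.

    ``weights`` are the multiplicity probabilities (alpha_1 ... alpha_Nmax);
    each draw picks a multiplicity k and returns the sum of k independent
    monomer brightness draws (normal law, truncated at zero).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("mixture weights must be >= 0")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("mixture weights must sum to 1")
    rng = _as_rng(seed)
    k = rng.choice(np.arange(1, len(w) + 1), size=n, p=w)
    total = int(k.sum())
    mono = np.clip(rng.normal(monomer_mean, monomer_sd, total), 1e-9, None)
    out = np.zeros(n)
    pos = 0
    for i, ki in enumerate(k):
        out[i] = mono[pos : pos + ki].sum()
        pos += ki
    return out


def gen_calcium_traces(
    n_cells: int,
    class_mix: tuple[float, float, float] = (0.3, 0.1, 0.6),
    baseline: float = 1.0,
    activated_level: float = 2.5,
    noise_sd: float = 0.08,
    length: int = 60,
    seed=None,
):
    """Simulate normalized Fura-2 ratio traces.

    ``class_mix`` gives the (activated, oscillatory, non-activated) fractions.
    Non-activated traces fluctuate around the baseline; activated traces rise
    to ``activated_level`` within the first frames and stay high; oscillatory
    traces alternate between high and baseline with roughly equal dwell so
    that neither 80% rule applies.  Returns a trace table
    ``cell_id, frame, ratio`` and the per-cell ground-truth labels.
    """
    mix = np.asarray(class_mix, dtype=float)
    if not np.isclose(mix.sum(), 1.0, atol=1e-9):
        raise ValueError("class fractions must sum to 1")
    rng = _as_rng(seed)
    labels = rng.choice(3, size=n_cells, p=mix)  # 0=act, 1=osc, 2=non
    t = np.arange(length)
    traces = np.empty((n_cells, length))
    for i, lab in enumerate(labels):
        if lab == 0:
            onset = rng.integers(0, max(1, length // 20) + 1)
            level = activated_level * rng.uniform(0.85, 1.15)
            tr = np.where(t >= onset, level, baseline).astype(float)
        elif lab == 1:
            # square-wave oscillation, ~50% duty cycle
            period = int(rng.integers(6, 13))
            phase = rng.integers(0, period)
            high = ((t + phase) // (period // 2)) % 2 == 0
            level = activated_level * rng.uniform(0.8, 1.1)
            tr = np.where(high, level, baseline).astype(float)
        else:
            tr = np.full(length, baseline)
        traces[i] = tr + rng.normal(0, noise_sd, length) if noise_sd > 0 else tr
    df = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n_cells), length),
            "frame": np.tile(np.arange(1, length + 1), n_cells),
            "ratio": np.clip(traces.ravel(), 1e-6, None),
        }
    )
    names = np.array(["activated", "oscillatory", "non-activated"])
    return df, names[labels]
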