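"""Engineered trajectory features for diffusion-mode classification.

The feature vector ("Set A") has eight entries, in fixed column order:

1. ``alpha`` — anomalous exponent, slope of the log-log fit to the
   time-averaged MSD (TAMSD); alpha = 2H for fractional Brownian motion.
2. ``D`` — diffusion coefficient (μm²/s) from the same fit, using the 2D
   convention ``rho(n) = 4 D (n dt)^alpha``.
3. ``msd_ratio`` — mean of ``rho(n)/rho(n+1) - n/(n+1)``; measures the
   curvature of the TAMSD (0 in expectation for free diffusion).
4. ``efficiency`` — net-squared over N times sum-of-squared steps;
   1 for straight constant-speed motion.
5. ``straightness`` — net displacement over path length.
6. ``vac1`` — empirical velocity autocorrelation at lag 1 in point n=1
   (un-normalised, μm²); negative for anti-persistent motion (H < 1/2).
7. ``max_excursion`` — largest single step relative to the net
   displacement; flags jumps that are long compared with the overall
   motion.
8. ``p_var_stat`` — ternary statistic from the p-variation profiles
   ``V_m(p)``: 0 if no profile changes monotonicity in m, otherwise +1/−1
   if the profile for the largest such p is convex/concave.

TAMSD-based features use a maximum lag of 10% of the trajectory length by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trajectory import Trajectory2D

__all__ = [
    "FEATURE_COLUMNS",
    "TAMSDCurve",
    "FeatureVector",
    "tamsd",
    "fit_alpha_diffusivity",
    "msd_ratio",
    "geometry_features",
    "velocity_autocorr",
    "p_variation_profile",
    "default_m_grid",
    "monotonicity_stat",
    "feature_vector",
    "features_table",
]

#: Fixed column order of the feature table.
FEATURE_COLUMNS: Tuple[str, ...] = (
    "alpha",
    "D",
    "msd_ratio",
    "efficiency",
    "straightness",
    "vac1",
    "max_excursion",
    "p_var_stat",
)

DEFAULT_P_GRID: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)

#: Minimum number of steps accepted by :func:`feature_vector`.
MIN_FEATURE_STEPS = 10


@dataclass(frozen=True)
class TAMSDCurve:
    """Time-averaged MSD ``rho(n)`` for lags n = 1..n_max (in μm²)."""

    lags: np.ndarray
    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if lags.size != values.size:
            raise ValueError("lags and values must have the same length")
        if lags.size < 2:
            raise ValueError("a TAMSD curve needs at least 2 lags")
        if np.any(values < 0):
            raise ValueError("TAMSD values must be nonnegative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class FeatureVector:
    """The Set A statistics of one trajectory, in fixed field order."""

    alpha: float
    D: float
    msd_ratio: float
    efficiency: float
    straightness: float
    vac1: float
    max_excursion: float
    p_var_stat: int

    def to_dict(self, include_D: bool = True) -> Dict[str, float]:
        d = {name: getattr(self, name) for name in FEATURE_COLUMNS}
        if not include_D:
            del d["D"]
        return d

    def to_array(self, include_D: bool = True) -> np.ndarray:
        return np.array(list(self.to_dict(include_D).values()), dtype=float)


def tamsd(traj: Trajectory2D, max_lag_fraction: float = 0.1) -> TAMSDCurve:
    """Time-averaged mean square displacement of a single track.

    ``rho(n) = (1/(N-n+1)) * sum_i ||X_{i+n} - X_i||^2`` for
    ``n = 1..n_max`` with ``n_max = max(2, floor(max_lag_fraction * N))``.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValueError(
            f"max_lag_fraction must lie in (0, 1], got {max_lag_fraction}"
        )
    pos = traj.positions
    n_steps = pos.shape[0] - 1
    if pos.shape[0] < 3:
        raise ValueError(
            "TAMSD needs at least 3 positions (2 steps), "
            f"got {pos.shape[0]}"
        )
    n_max = max(2, int(np.floor(max_lag_fraction * n_steps)))
    lags = np.arange(1, n_max + 1)
    values = np.empty(n_max)
    for i, n in enumerate(lags):
        disp = pos[n:] - pos[:-n]
        values[i] = np.mean(np.einsum("ij,ij->i", disp, disp))
    return TAMSDCurve(lags=lags, values=values, dt=traj.dt)


def fit_alpha_diffusivity(curve: TAMSDCurve) -> Tuple[float, float]:
    """Anomalous exponent and diffusion coefficient from a TAMSD curve.

    Ordinary least squares of ``log rho(n)`` on ``log(n dt)``: alpha is
    the slope, D = exp(intercept)/4 (2D convention rho = 4 D t^alpha).
    Zero-valued lags are dropped; with fewer than two positive lags the
    fit degenerates and (0, 0) is returned.
    """
    keep = curve.values > 0
    if keep.sum() < 2:
        return 0.0, 0.0
    x = np.log(curve.lags[keep] * curve.dt)
    y = np.log(curve.values[keep])
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(np.exp(intercept) / 4.0)


def msd_ratio(curve: TAMSDCurve) -> float:
    """Mean MSD ratio ``kappa`` over consecutive lag pairs.

    ``kappa = mean_n [rho(n)/rho(n+1) - n/(n+1)]`` for n = 1..n_max-1.
    Pairs with ``rho(n+1) = 0`` are skipped (reducing the divisor); an
    all-zero curve returns 0.
    """
    rho = curve.values
    n = curve.lags
    valid = rho[1:] > 0
    if not np.any(valid):
        return 0.0
    terms = rho[:-1][valid] / rho[1:][valid] - n[:-1][valid] / n[1:][valid]
    return float(np.mean(terms))


def geometry_features(traj: Trajectory2D) -> Tuple[float, float, float]:
    """Efficiency, straightness and maximal excursion of a track.

    * efficiency ``E = ||X_N - X_0||^2 / (N * sum_i ||X_i - X_{i-1}||^2)``
    * straightness ``S = ||X_N - X_0|| / sum_i ||X_i - X_{i-1}||``
    * maximal excursion ``ME = max_i ||X_i - X_{i-1}|| / ||X_N - X_0||``

    A track with zero net displacement has ME = 0 by convention; a fully
    stationary track returns (0, 0, 0) with a warning.
    """
    steps = traj.increments()
    n = steps.shape[0]
    step_len = np.sqrt(np.einsum("ij,ij->i", steps, steps))
    sum_sq = float(np.sum(step_len**2))
    path_len = float(np.sum(step_len))
    net = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    if path_len == 0.0:
        warnings.warn(
            "trajectory has no movement at all; geometry features set to 0",
            stacklevel=2,
        )
        return 0.0, 0.0, 0.0
    efficiency = net**2 / (n * sum_sq)
    straightness = net / path_len
    max_exc = float(np.max(step_len)) / net if net > 0 else 0.0
    return float(efficiency), float(straightness), max_exc


def velocity_autocorr(traj: Trajectory2D) -> float:
    """Velocity autocorrelation at lag 1 evaluated at point n = 1.

    ``chi = (1/(N-2)) * sum_i (X_{i+2} - X_{i+1}) . (X_{i+1} - X_i)``
    over the N−2 consecutive increment pairs; un-normalised (μm²).
    """
    if traj.positions.shape[0] < 4:
        raise ValueError(
            "velocity autocorrelation needs at least 4 positions, got "
            f"{traj.positions.shape[0]}"
        )
    steps = traj.increments()
    dots = np.einsum("ij,ij->i", steps[1:], steps[:-1])
    return float(np.mean(dots))


def default_m_grid(n_steps: int, max_points: int = 50) -> np.ndarray:
    """Block sizes for the p-variation profiles of an N-step track.

    ``m = 1..min(floor(N/2), max(3, floor(N/10)))``, evenly thinned to at
    most ``max_points`` values so long tracks stay cheap.  The lower
    bound of 3 grid points keeps the monotonicity statistic defined for
    short tracks.
    """
    m_max = min(n_steps // 2, max(3, n_steps // 10))
    if m_max < 1:
        raise ValueError(f"trajectory too short for p-variation: N={n_steps}")
    grid = np.arange(1, m_max + 1)
    if grid.size > max_points:
        grid = np.unique(
            np.round(np.linspace(1, m_max, max_points)).astype(int)
        )
    return grid


def p_variation_profile(
    traj: Trajectory2D, p: float, m_grid: Sequence[int]
) -> np.ndarray:
    """Sample p-variation ``V_m(p)`` over block sizes m.

    ``V_m(p) = sum_{i=0}^{floor(N/m)-1} ||X_{(i+1)m} - X_{im}||^p`` with
    the Euclidean norm of the 2D displacement.
    """
    if not p > 0:
        raise ValueError(f"p must be positive, got {p}")
    pos = traj.positions
    n_steps = pos.shape[0] - 1
    m_grid = np.asarray(m_grid, dtype=int)
    if np.any(m_grid < 1) or np.any(np.diff(m_grid) <= 0):
        raise ValueError("m_grid must be strictly increasing positive integers")
    if m_grid.max() > n_steps // 2:
        raise ValueError(
            f"largest block size {m_grid.max()} exceeds N/2 = {n_steps // 2}"
        )
    out = np.empty(m_grid.size)
    for i, m in enumerate(m_grid):
        sub = pos[::m][: n_steps // m + 1]
        disp = np.diff(sub, axis=0)
        out[i] = np.sum(np.sqrt(np.einsum("ij,ij->i", disp, disp)) ** p)
    return out


def monotonicity_stat(profiles: Mapping[float, Sequence[float]]) -> int:
    """Ternary summary of how the p-variation profiles bend in m.

    A profile *changes monotonicity* iff its successive differences
    contain both a strictly positive and a strictly negative value.
    Among the p whose profile changes monotonicity, the largest p is
    classified by the sign of the sum of its second differences:
    +1 convex, −1 concave (an exact zero ties to 0).  If no profile
    changes monotonicity the statistic is 0.
    """
    changed = []
    for p in sorted(profiles):
        v = np.asarray(profiles[p], dtype=float)
        if v.size < 3:
            raise ValueError(
                f"profile for p={p} needs at least 3 points, got {v.size}"
            )
        d = np.diff(v)
        if np.any(d > 0) and np.any(d < 0):
            changed.append(p)
    if not changed:
        return 0
    v = np.asarray(profiles[max(changed)], dtype=float)
    curvature = float(np.sum(np.diff(v, n=2)))
    if curvature > 0:
        return 1
    if curvature < 0:
        return -1
    return 0


def feature_vector(
    traj: Trajectory2D,
    include_D: bool = True,
    max_lag_fraction: float = 0.1,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
) -> FeatureVector:
    """Assemble the full Set A feature vector for one trajectory.

    ``include_D`` only controls the later export (``to_dict``/table
    columns); the vector itself always carries D so the same object can
    serve both classifier variants.  Requires at least 10 steps so the
    default 10%-lag TAMSD keeps two lags.
    """
    n_steps = traj.positions.shape[0] - 1
    if n_steps < MIN_FEATURE_STEPS:
        raise ValueError(
            f"feature extraction needs >= {MIN_FEATURE_STEPS} steps, got {n_steps}"
        )
    try:
        curve = tamsd(traj, max_lag_fraction)
        alpha, D = fit_alpha_diffusivity(curve)
        kappa = msd_ratio(curve)
        eff, straight, max_exc = geometry_features(traj)
        chi = velocity_autocorr(traj)
        m_grid = default_m_grid(n_steps)
        profiles = {p: p_variation_profile(traj, p, m_grid) for p in p_grid}
        pstat = monotonicity_stat(profiles)
    except ValueError as err:
        raise ValueError(f"feature extraction failed: {err}") from err
    vec = FeatureVector(
        alpha=alpha,
        D=D,
        msd_ratio=kappa,
        efficiency=eff,
        straightness=straight,
        vac1=chi,
        max_excursion=max_exc,
        p_var_stat=pstat,
    )
    arr = vec.to_array()
    if not np.all(np.isfinite(arr)):
        bad = [c for c, v in zip(FEATURE_COLUMNS, arr) if not np.isfinite(v)]
        raise ValueError(f"non-finite feature(s): {bad}")
    return vec


def features_table(
    trajectories: Iterable[Trajectory2D],
    labels: Optional[Sequence[str]] = None,
    traj_ids: Optional[Sequence] = None,
    include_D: bool = True,
    max_lag_fraction: float = 0.1,
) -> pd.DataFrame:
    """Feature table (one row per trajectory) in the fixed column order.

    Columns: ``traj_id``, the Set A features (without ``D`` when
    ``include_D`` is off) and, when labels are given, a ``mode`` column.
    """
    rows: List[Dict] = []
    trajs = list(trajectories)
    if traj_ids is None:
        traj_ids = list(range(len(trajs)))
    for tid, traj in zip(traj_ids, trajs):
        row = {"traj_id": tid}
        row.update(
            feature_vector(traj, max_lag_fraction=max_lag_fraction).to_dict(
                include_D=include_D
            )
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if labels is not None:
        df["mode"] = list(labels)
    return df
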