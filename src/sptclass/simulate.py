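"""Exact simulators for the three diffusion models.

All three processes are sampled on a uniform grid ``t_i = i*dt`` with
independent x and y coordinates:

* fractional Brownian motion (FBM): ``dX = sigma * dB^H``; the anomalous
  exponent of the mean squared displacement is ``alpha = 2H``, so H < 1/2
  gives subdiffusion, H > 1/2 superdiffusion and H = 1/2 free diffusion;
* directed Brownian motion (DBM): ``dX = v dt + sigma dB^{1/2}`` — drifting
  (superdiffusive) transport, Brownian for v = 0;
* Ornstein–Uhlenbeck (OU): ``dX = -lambda (X - theta) dt + sigma dB^{1/2}``
  — confined (subdiffusive) motion in a potential well, Brownian for
  lambda = 0.

FBM increments (fractional Gaussian noise) are generated *exactly* by
circulant embedding of the covariance (Davies–Harte); if the embedding is
not nonnegative definite a Cholesky factorisation of the covariance matrix
is used instead.  The OU process uses its exact Gaussian transition
kernel, not an Euler scheme, which matters because dt = 1 s is not small
against reversion rates up to 1/s.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
from scipy.signal import lfilter

from .trajectory import Trajectory2D

__all__ = [
    "fbm_trajectory",
    "dbm_trajectory",
    "ou_trajectory",
    "fractional_gaussian_noise",
]

SeedLike = Union[int, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact sample of ``n`` unit-variance fGn increments.

    Uses Davies–Harte circulant embedding: the (2n)-point circulant
    extension of the fGn autocovariance is diagonalised by the FFT; its
    eigenvalues are nonnegative for every H in (0, 1), which makes the
    construction exact.  A Cholesky fallback guards against numerically
    negative eigenvalues.
    """
    if not 0 < hurst < 1:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n + 1, dtype=float)
    # autocovariance gamma(k) of unit-variance fGn
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    m = 2 * n
    circ = np.concatenate([gamma[:n], gamma[n:n + 1], gamma[n - 1:0:-1]])
    eigvals = np.fft.fft(circ).real
    if eigvals.min() < -1e-8 * eigvals.max():
        return _fgn_cholesky(n, gamma, rng)
    eigvals = np.clip(eigvals, 0.0, None)
    gn = rng.standard_normal(m)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(eigvals[0] / m) * gn[0]
    w[n] = np.sqrt(eigvals[n] / m) * gn[n]
    w[1:n] = np.sqrt(eigvals[1:n] / (2 * m)) * (gn[1:n] + 1j * gn[n + 1:])
    w[n + 1:] = np.conj(w[n - 1:0:-1])
    return np.fft.fft(w)[:n].real


def _fgn_cholesky(
    n: int, gamma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    cov = gamma[idx]
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


def fbm_trajectory(
    n_steps: int,
    hurst: float,
    scale: float = 1.0,
    dt: float = 1.0,
    seed: SeedLike = None,
) -> Trajectory2D:
    """Simulate 2D fractional Brownian motion started at the origin.

    Each coordinate is an independent exact realisation of
    ``sigma * B^H`` at times ``i*dt``: a zero-mean Gaussian process with
    covariance ``sigma^2 * (t^{2H} + s^{2H} - |t-s|^{2H}) / 2``.

    Parameters
    ----------
    n_steps : int
        Number of steps N; the trajectory has N+1 positions.
    hurst : float
        Hurst exponent H in (0, 1).
    scale : float
        Scale coefficient sigma in μm·s^(−1/2); D = sigma²/2.
    dt : float
        Time step in seconds.
    seed : int, Generator or None
        Randomness source.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if not 0 < hurst < 1:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    _check_positive("scale", scale)
    _check_positive("dt", dt)
    rng = _rng(seed)
    # self-similarity: increments over dt are dt^H * unit-grid fGn
    step_scale = scale * dt**hurst
    if hurst == 0.5:
        incr = step_scale * rng.standard_normal((n_steps, 2))
    else:
        incr = np.column_stack(
            [
                fractional_gaussian_noise(n_steps, hurst, rng),
                fractional_gaussian_noise(n_steps, hurst, rng),
            ]
        )
        incr *= step_scale
    positions = np.vstack([np.zeros((1, 2)), np.cumsum(incr, axis=0)])
    return Trajectory2D(positions=positions, dt=dt)


def dbm_trajectory(
    n_steps: int,
    drift: Tuple[float, float],
    scale: float = 1.0,
    dt: float = 1.0,
    seed: SeedLike = None,
) -> Trajectory2D:
    """Simulate 2D directed Brownian motion started at the origin.

    ``X_{i+1} = X_i + v dt + sigma sqrt(dt) xi_i`` with i.i.d. standard
    2D Gaussian ``xi_i`` (this discretisation is exact for constant drift).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    _check_positive("scale", scale)
    _check_positive("dt", dt)
    rng = _rng(seed)
    v = np.asarray(drift, dtype=float)
    incr = v * dt + scale * np.sqrt(dt) * rng.standard_normal((n_steps, 2))
    positions = np.vstack([np.zeros((1, 2)), np.cumsum(incr, axis=0)])
    return Trajectory2D(positions=positions, dt=dt)


def ou_trajectory(
    n_steps: int,
    reversion: Tuple[float, float],
    mean: Tuple[float, float] = (0.0, 0.0),
    scale: float = 1.0,
    dt: float = 1.0,
    seed: SeedLike = None,
    x0: Optional[Tuple[float, float]] = None,
) -> Trajectory2D:
    """Simulate a 2D Ornstein–Uhlenbeck process with the exact transition.

    Per coordinate, ``X_{t+dt} = theta + (X_t - theta) e^{-lambda dt} +
    eta`` with ``eta ~ N(0, sigma^2 (1 - e^{-2 lambda dt}) / (2 lambda))``;
    a coordinate with lambda = 0 uses the Brownian limit variance
    ``sigma^2 dt``.  The start point defaults to theta (the origin for
    the dataset recipe, where theta = 0).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    _check_positive("scale", scale)
    _check_positive("dt", dt)
    lam = np.asarray(reversion, dtype=float)
    if np.any(lam < 0):
        raise ValueError(f"reversion rates must be >= 0, got {reversion}")
    theta = np.asarray(mean, dtype=float)
    start = theta if x0 is None else np.asarray(x0, dtype=float)
    rng = _rng(seed)

    decay = np.exp(-lam * dt)
    step_var = np.where(
        lam > 0,
        scale**2 * (1.0 - np.exp(-2.0 * lam * dt)) / np.where(lam > 0, 2.0 * lam, 1.0),
        scale**2 * dt,
    )
    eta = rng.standard_normal((n_steps, 2)) * np.sqrt(step_var)
    positions = np.empty((n_steps + 1, 2))
    positions[0] = start
    for j in range(2):
        # AR(1) recursion y_i = decay*y_{i-1} + eta_i on deviations from theta
        dev0 = start[j] - theta[j]
        driven = lfilter([1.0], [1.0, -decay[j]], eta[:, j])
        ar = dev0 * decay[j] ** np.arange(1, n_steps + 1) + driven
        positions[1:, j] = theta[j] + ar
    return Trajectory2D(positions=positions, dt=dt)
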