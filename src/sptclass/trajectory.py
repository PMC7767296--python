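"""Domain types for 2D single-particle-tracking trajectories.

A trajectory is a uniformly sampled 2D track: positions in micrometres,
time step ``dt`` in seconds.  The generating stochastic model (fractional
Brownian motion, directed Brownian motion or an Ornstein--Uhlenbeck
process) is described by a :class:`ModelSpec`, and every simulated track
carries a ground-truth diffusion mode out of ``normal``, ``subdiffusion``
and ``superdiffusion``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "MODES",
    "MODELS",
    "Trajectory2D",
    "ModelSpec",
]

#: Diffusion-mode labels, in canonical (alphabetical) order.
MODES: Tuple[str, ...] = ("normal", "subdiffusion", "superdiffusion")

#: Generating-model identifiers.
MODELS: Tuple[str, ...] = ("fbm", "dbm", "ou")


@dataclass(frozen=True)
class Trajectory2D:
    """A uniformly sampled 2D track.

    Parameters
    ----------
    positions : ndarray of shape (N+1, 2)
        Particle positions in μm; the implied observation times are
        ``t0 + i*dt`` for ``i = 0..N``.
    dt : float
        Time step between consecutive positions, in seconds.
    t0 : float, optional
        Time of the first position, in seconds (default 0).
    """

    positions: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError(
                f"positions must have shape (N+1, 2), got {pos.shape}"
            )
        if pos.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 positions")
        if not np.all(np.isfinite(pos)):
            raise ValueError("all coordinates must be finite")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_steps(self) -> int:
        """Number of steps N (one less than the number of positions)."""
        return self.positions.shape[0] - 1

    @property
    def times(self) -> np.ndarray:
        """Observation times ``t0 + i*dt``."""
        return self.t0 + self.dt * np.arange(self.positions.shape[0])

    def increments(self) -> np.ndarray:
        """Step displacements ``X_{i+1} - X_i``, shape (N, 2)."""
        return np.diff(self.positions, axis=0)

    def with_positions(self, positions: np.ndarray) -> "Trajectory2D":
        """Copy of this trajectory with replaced positions."""
        return replace(self, positions=positions)


@dataclass(frozen=True)
class ModelSpec:
    """Generating model and parameters of a simulated trajectory.

    ``sigma`` is the scale coefficient in μm·s^(−1/2); it relates to the
    diffusion coefficient via ``D = sigma**2 / 2`` (so ``sigma =
    sqrt(2*D)``), in μm²/s.  ``hurst`` applies to FBM only, ``drift`` (v,
    μm/s) to DBM only, and ``reversion`` (λ, 1/s) together with ``mean``
    (θ, μm) to the OU process only.
    """

    model: str
    sigma: float
    hurst: Optional[float] = None
    drift: Optional[Tuple[float, float]] = None
    reversion: Optional[Tuple[float, float]] = None
    mean: Optional[Tuple[float, float]] = field(default=None)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.model == "fbm":
            if self.hurst is None or not 0 < self.hurst < 1:
                raise ValueError(
                    f"FBM requires a Hurst exponent in (0, 1), got {self.hurst}"
                )
        if self.model == "dbm" and self.drift is None:
            raise ValueError("DBM requires a drift vector v")
        if self.model == "ou":
            if self.reversion is None:
                raise ValueError("OU requires a reversion vector lambda")
            if any(lam < 0 for lam in self.reversion):
                raise ValueError(
                    f"OU reversion rates must be >= 0, got {self.reversion}"
                )

    @property
    def diffusion_coefficient(self) -> float:
        """D = sigma² / 2, in μm²/s."""
        return 0.5 * self.sigma**2

    @staticmethod
    def sigma_from_D(D: float) -> float:
        """Scale coefficient for a given diffusion coefficient: √(2D)."""
        if not D > 0:
            raise ValueError(f"D must be positive, got {D}")
        return float(np.sqrt(2.0 * D))
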