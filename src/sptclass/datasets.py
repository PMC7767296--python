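"""Labelled synthetic trajectory sets for classifier training.

The base recipe mixes the three generating models across the three
diffusion modes (counts for the full-size set):

====================  ======  ==========================  ========
mode                  model   parameter law               count
====================  ======  ==========================  ========
normal                FBM     H ~ U[0.5-c, 0.5+c]          20,000
normal                DBM     v1,v2 ~ U[0, c]              10,000
normal                OU      lam1,lam2 ~ U[0, c], θ=0     10,000
subdiffusion          FBM     H ~ U[0.1, 0.5-c)            20,000
subdiffusion          OU      lam1,lam2 ~ U(c, 1], θ=0     20,000
superdiffusion        FBM     H ~ U(0.5+c, 0.9]            20,000
superdiffusion        DBM     v1,v2 ~ U(c, 1]              20,000
====================  ======  ==========================  ========

with cutoff c = 0.1, sigma = 1 μm·s^(−1/2), dt = 1 s, and lengths drawn
uniformly from 50..500 steps.  The cutoff c is the half-width of the
parameter band around the Brownian point inside which weak anomalous
motion is deliberately labelled *normal*.  Variants cover localisation
noise (per-trajectory signal-to-noise ratio Q ~ U[1,9]), a smaller scale
sigma = 0.38, per-trajectory diffusivity D ~ U[1,9], and a sweep of c.

Every trajectory gets its own random generator seeded from (master seed,
trajectory index), so datasets are reproducible and order-independent,
and variants built from the same master seed share their underlying
random draws (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .simulate import dbm_trajectory, fbm_trajectory, ou_trajectory
from .trajectory import MODES, ModelSpec, Trajectory2D

__all__ = [
    "BASE_COUNTS",
    "DatasetConfig",
    "LabeledTrajectorySet",
    "assign_mode_label",
    "build_dataset",
    "noise_std_from_Q",
    "add_localization_noise",
    "split_dataset",
    "split_indices",
]

#: Full-size per-(mode, model) trajectory counts of the base recipe.
BASE_COUNTS: Dict[Tuple[str, str], int] = {
    ("normal", "fbm"): 20_000,
    ("normal", "dbm"): 10_000,
    ("normal", "ou"): 10_000,
    ("subdiffusion", "fbm"): 20_000,
    ("subdiffusion", "ou"): 20_000,
    ("superdiffusion", "fbm"): 20_000,
    ("superdiffusion", "dbm"): 20_000,
}


@dataclass(frozen=True)
class DatasetConfig:
    """Recipe for a labelled synthetic trajectory set.

    ``sigma`` is used for every trajectory unless ``diffusivity_range``
    is set, in which case each trajectory draws D ~ U[a, b] and uses
    sigma = sqrt(2D).  ``snr_range`` switches on localisation noise with
    a per-trajectory signal-to-noise ratio Q ~ U[q_min, q_max].
    """

    counts: Dict[Tuple[str, str], int] = field(
        default_factory=lambda: dict(BASE_COUNTS)
    )
    length_range: Tuple[int, int] = (50, 500)
    cutoff: float = 0.1
    dt: float = 1.0
    sigma: float = 1.0
    diffusivity_range: Optional[Tuple[float, float]] = None
    snr_range: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, n in self.counts.items():
            if cell not in BASE_COUNTS:
                raise ValueError(f"unknown (mode, model) cell {cell}")
            if n < 0:
                raise ValueError(f"count for {cell} must be >= 0, got {n}")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(
                f"length_range must satisfy 2 <= L_min <= L_max, got {self.length_range}"
            )
        if self.cutoff < 0:
            raise ValueError(f"cutoff must be >= 0, got {self.cutoff}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.diffusivity_range is not None:
            a, b = self.diffusivity_range
            if not 0 < a < b:
                raise ValueError(
                    f"diffusivity_range needs 0 < a < b, got {self.diffusivity_range}"
                )
        if self.snr_range is not None:
            q_min, q_max = self.snr_range
            if not 0 < q_min < q_max:
                raise ValueError(
                    f"snr_range needs 0 < q_min < q_max, got {self.snr_range}"
                )
        if self.cutoff >= 0.4 and self.counts.get(("subdiffusion", "fbm"), 0) > 0:
            raise ValueError(
                "cutoff >= 0.4 empties the subdiffusive FBM band [0.1, 0.5-c)"
            )

    @classmethod
    def base(cls, scale: float = 1.0, **overrides) -> "DatasetConfig":
        """The base recipe, with counts optionally scaled by ``scale``."""
        counts = {
            cell: int(round(n * scale)) for cell, n in BASE_COUNTS.items()
        }
        return cls(counts=counts, **overrides)

    @property
    def n_trajectories(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> Dict:
        return {
            "counts": {f"{mode}/{model}": n for (mode, model), n in self.counts.items()},
            "length_range": list(self.length_range),
            "cutoff": self.cutoff,
            "dt": self.dt,
            "sigma": self.sigma,
            "diffusivity_range": (
                list(self.diffusivity_range) if self.diffusivity_range else None
            ),
            "snr_range": list(self.snr_range) if self.snr_range else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "DatasetConfig":
        counts = {
            tuple(key.split("/")): n for key, n in d["counts"].items()
        }
        return cls(
            counts=counts,  # type: ignore[arg-type]
            length_range=tuple(d["length_range"]),
            cutoff=d["cutoff"],
            dt=d["dt"],
            sigma=d["sigma"],
            diffusivity_range=(
                tuple(d["diffusivity_range"]) if d.get("diffusivity_range") else None
            ),
            snr_range=tuple(d["snr_range"]) if d.get("snr_range") else None,
            seed=d.get("seed", 0),
        )


@dataclass
class LabeledTrajectorySet:
    """Trajectories with their generating specs and ground-truth modes."""

    trajectories: List[Trajectory2D]
    specs: List[ModelSpec]
    modes: np.ndarray
    config: Optional[DatasetConfig] = None

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=object)
        if not (len(self.trajectories) == len(self.specs) == self.modes.size):
            raise ValueError("trajectories, specs and modes must align")

    def __len__(self) -> int:
        return len(self.trajectories)

    def counts_by_mode(self) -> Dict[str, int]:
        return {m: int(np.sum(self.modes == m)) for m in MODES}

    def subset(self, indices: Sequence[int]) -> "LabeledTrajectorySet":
        idx = np.asarray(indices, dtype=int)
        return LabeledTrajectorySet(
            trajectories=[self.trajectories[i] for i in idx],
            specs=[self.specs[i] for i in idx],
            modes=self.modes[idx],
            config=self.config,
        )


def assign_mode_label(spec: ModelSpec, cutoff: float) -> str:
    """Ground-truth diffusion mode of a generating spec under cutoff c.

    FBM: H within c of 1/2 is normal, below subdiffusion, above
    superdiffusion.  DBM: normal iff both drift components lie in [0, c],
    else superdiffusion.  OU: normal iff both reversion rates lie in
    [0, c], else subdiffusion.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    if spec.model == "fbm":
        h = spec.hurst
        if h < 0.5 - cutoff:
            return "subdiffusion"
        if h > 0.5 + cutoff:
            return "superdiffusion"
        return "normal"
    if spec.model == "dbm":
        if all(0 <= v <= cutoff for v in spec.drift):
            return "normal"
        return "superdiffusion"
    # OU
    if all(0 <= lam <= cutoff for lam in spec.reversion):
        return "normal"
    return "subdiffusion"


def _uniform_excluding_low(rng: np.random.Generator, low: float, high: float) -> float:
    """U(low, high]: closed uniform with rejection of the excluded endpoint."""
    while True:
        x = rng.uniform(low, high)
        if x != low:
            return x


def _uniform_excluding_high(rng: np.random.Generator, low: float, high: float) -> float:
    """U[low, high): closed uniform with rejection of the excluded endpoint."""
    while True:
        x = rng.uniform(low, high)
        if x != high:
            return x


def _draw_spec(
    rng: np.random.Generator, mode: str, model: str, cutoff: float, sigma: float
) -> ModelSpec:
    c = cutoff
    if model == "fbm":
        if mode == "normal":
            h = rng.uniform(0.5 - c, 0.5 + c) if c > 0 else 0.5
        elif mode == "subdiffusion":
            h = _uniform_excluding_high(rng, 0.1, 0.5 - c)
        else:
            h = _uniform_excluding_low(rng, 0.5 + c, 0.9)
        return ModelSpec(model="fbm", sigma=sigma, hurst=h)
    if model == "dbm":
        if mode == "normal":
            v = tuple(rng.uniform(0.0, c, size=2)) if c > 0 else (0.0, 0.0)
        else:
            v = (
                _uniform_excluding_low(rng, c, 1.0),
                _uniform_excluding_low(rng, c, 1.0),
            )
        return ModelSpec(model="dbm", sigma=sigma, drift=v)
    if model == "ou":
        if mode == "normal":
            lam = tuple(rng.uniform(0.0, c, size=2)) if c > 0 else (0.0, 0.0)
        else:
            lam = (
                _uniform_excluding_low(rng, c, 1.0),
                _uniform_excluding_low(rng, c, 1.0),
            )
        return ModelSpec(
            model="ou", sigma=sigma, reversion=lam, mean=(0.0, 0.0)
        )
    raise ValueError(f"unknown model {model!r}")


def _simulate(spec: ModelSpec, n_steps: int, dt: float, rng) -> Trajectory2D:
    if spec.model == "fbm":
        return fbm_trajectory(n_steps, spec.hurst, spec.sigma, dt, rng)
    if spec.model == "dbm":
        return dbm_trajectory(n_steps, spec.drift, spec.sigma, dt, rng)
    return ou_trajectory(
        n_steps, spec.reversion, spec.mean, spec.sigma, dt, rng
    )


def noise_std_from_Q(spec: ModelSpec, dt: float, Q: float) -> float:
    """Localisation-noise standard deviation from a signal-to-noise ratio.

    ``sigma_Gn = sqrt(D dt + |v|^2 dt^2) / Q`` for DBM (|v| the Euclidean
    drift magnitude) and ``sqrt(D dt) / Q`` otherwise, with D = sigma²/2.
    """
    if not Q > 0:
        raise ValueError(f"Q must be positive, got {Q}")
    D = spec.diffusion_coefficient
    if spec.model == "dbm":
        v_sq = spec.drift[0] ** 2 + spec.drift[1] ** 2
        return float(math.sqrt(D * dt + v_sq * dt**2) / Q)
    return float(math.sqrt(D * dt) / Q)


def add_localization_noise(
    traj: Trajectory2D,
    noise_std: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> Trajectory2D:
    """Copy of ``traj`` with i.i.d. N(0, noise_std²) on every coordinate."""
    if noise_std < 0:
        raise ValueError(f"noise_std must be >= 0, got {noise_std}")
    if noise_std == 0:
        return traj.with_positions(traj.positions.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = traj.positions + noise_std * rng.standard_normal(traj.positions.shape)
    return traj.with_positions(noisy)


def build_dataset(config: DatasetConfig) -> LabeledTrajectorySet:
    """Simulate and label the trajectory set described by ``config``.

    Each trajectory ``i`` uses its own generator seeded from
    ``(config.seed, i)`` and draws, in order: its length (uniform on the
    configured step range), its model parameters, its diffusivity (when
    varying) and, when noise is on, its signal-to-noise ratio Q.
    Ground-truth labels come from :func:`assign_mode_label` applied to
    the generating spec — noise never changes a label.
    """
    lo, hi = config.length_range
    trajectories: List[Trajectory2D] = []
    specs: List[ModelSpec] = []
    modes: List[str] = []
    index = 0
    for (mode, model), count in config.counts.items():
        for _ in range(count):
            rng = np.random.default_rng([config.seed, index])
            try:
                n_steps = int(rng.integers(lo, hi + 1))
                sigma = config.sigma
                if config.diffusivity_range is not None:
                    D = rng.uniform(*config.diffusivity_range)
                    sigma = ModelSpec.sigma_from_D(D)
                spec = _draw_spec(rng, mode, model, config.cutoff, sigma)
                traj = _simulate(spec, n_steps, config.dt, rng)
                if config.snr_range is not None:
                    Q = rng.uniform(*config.snr_range)
                    traj = add_localization_noise(
                        traj, noise_std_from_Q(spec, config.dt, Q), rng
                    )
            except ValueError as err:
                raise ValueError(
                    f"trajectory {index} ({mode}/{model}): {err}"
                ) from err
            label = assign_mode_label(spec, config.cutoff)
            assert label == mode, (label, mode, spec)
            trajectories.append(traj)
            specs.append(spec)
            modes.append(mode)
            index += 1
    return LabeledTrajectorySet(
        trajectories=trajectories,
        specs=specs,
        modes=np.asarray(modes, dtype=object),
        config=config,
    )


def split_indices(
    modes: Sequence[str], train_frac: float, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test index split.

    Within each ground-truth mode the items are shuffled and
    ``round(train_frac * n_class)`` of them go to the training side, so
    balanced inputs stay exactly balanced on both sides.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must lie in (0, 1), got {train_frac}")
    modes = np.asarray(modes, dtype=object)
    if modes.size == 0:
        raise ValueError("cannot split an empty set")
    rng = np.random.default_rng(seed)
    train: List[np.ndarray] = []
    test: List[np.ndarray] = []
    for mode in sorted(set(modes.tolist())):
        idx = np.flatnonzero(modes == mode)
        if idx.size == 0:
            raise ValueError(f"class {mode!r} is empty")
        rng.shuffle(idx)
        n_train = int(round(train_frac * idx.size))
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def split_dataset(
    tset: LabeledTrajectorySet, train_frac: float = 0.7, seed: int = 0
) -> Tuple[LabeledTrajectorySet, LabeledTrajectorySet]:
    """Random stratified partition of a labelled set into train and test."""
    train_idx, test_idx = split_indices(tset.modes, train_frac, seed)
    return tset.subset(train_idx), tset.subset(test_idx)
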