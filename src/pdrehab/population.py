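"""Cosine-tuned motor-cortex population and population-vector decoding.

The forward model of a single center-out reach: a target direction drives
each neuron through a rectified cosine tuning curve peaked at its encoding
preferred direction (PD); signal-dependent Gaussian noise corrupts the
activity; and the reach itself is read out as the population vector (PV) —
the activity-weighted sum of decoding-PD unit vectors, whose angle models
reach direction and whose norm models reach speed.

All angles are degrees at the API boundary (radians only inside trig
calls).  PDs wrap to [0, 360); angular differences wrap to (-180, 180].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import Condition, ConfigurationError, decoding_pd

#: the eight standard radially distributed reach targets, degrees
STANDARD_TARGETS = tuple(float(k * 45) for k in range(8))


def wrap_deg(a):
    """Wrap angles to [0, 360)."""
    return np.asarray(a, dtype=float) % 360.0


def wrap_signed_deg(a):
    """Wrap angular differences to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = (a + 180.0) % 360.0 - 180.0
    # map -180 to +180 so the interval is (-180, 180]
    out = np.where(out == -180.0, 180.0, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Population:
    """A motor-cortex population for one hemisphere.

    Fields are aligned per-neuron arrays: ``base_pd`` is the unimanual
    encoding PD (degrees, wrapped to [0, 360)), ``rotation_offset`` the
    quenched bimanual rotation (0 in unimanual), ``depth`` the nonnegative
    modulation depth, and ``alive`` marks neurons surviving the lesion.
    Dead neurons stay in the arrays — they contribute no activity and are
    never updated by learning.
    """

    base_pd: np.ndarray
    rotation_offset: np.ndarray = field(default=None)  # type: ignore[assignment]
    depth: np.ndarray = field(default=None)  # type: ignore[assignment]
    alive: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bp = wrap_deg(np.atleast_1d(self.base_pd))
        n = len(bp)
        ro = self.rotation_offset
        ro = np.zeros(n) if ro is None else np.asarray(ro, dtype=float)
        dp = self.depth
        dp = np.ones(n) if dp is None else np.asarray(dp, dtype=float)
        al = self.alive
        al = np.ones(n, dtype=bool) if al is None else np.asarray(al, dtype=bool)
        if not (len(ro) == len(dp) == len(al) == n):
            raise ValueError("population arrays must share one length")
        if np.any(dp < 0):
            raise ValueError("modulation depths must be nonnegative")
        object.__setattr__(self, "base_pd", bp)
        object.__setattr__(self, "rotation_offset", ro)
        object.__setattr__(self, "depth", dp)
        object.__setattr__(self, "alive", al)

    @property
    def n(self) -> int:
        """Total neuron count, including lesioned neurons."""
        return len(self.base_pd)

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive))

    def with_(self, **kw) -> "Population":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    # -- construction -----------------------------------------------------

    @classmethod
    def uniform(
        cls,
        n: int,
        layout: str = "grid",
        depth: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> "Population":
        """A fresh intact population with uniformly distributed base PDs.

        ``layout='grid'`` places PDs equally spaced (deterministic, the
        default); ``layout='random'`` draws them i.i.d. uniform on the
        circle from ``rng``.
        """
        if layout == "grid":
            pds = np.arange(n) * (360.0 / n)
        elif layout == "random":
            if rng is None:
                raise ValueError("layout='random' needs an rng")
            pds = rng.uniform(0.0, 360.0, size=n)
        else:
            raise ConfigurationError(f"unknown PD layout {layout!r}")
        return cls(base_pd=pds, depth=np.full(n, float(depth)))

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n),
                "base_pd_deg": self.base_pd,
                "rotation_offset_deg": self.rotation_offset,
                "depth": self.depth,
                "alive": self.alive.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Population":
        df = pd.read_csv(path)
        return cls(
            base_pd=df["base_pd_deg"].to_numpy(float),
            rotation_offset=df["rotation_offset_deg"].to_numpy(float),
            depth=df["depth"].to_numpy(float),
            alive=df["alive"].to_numpy(bool),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "base_pd_deg": self.base_pd.tolist(),
                    "rotation_offset_deg": self.rotation_offset.tolist(),
                    "depth": self.depth.tolist(),
                    "alive": self.alive.astype(bool).tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Population":
        d = json.loads(Path(path).read_text())
        return cls(
            base_pd=np.asarray(d["base_pd_deg"], float),
            rotation_offset=np.asarray(d["rotation_offset_deg"], float),
            depth=np.asarray(d["depth"], float),
            alive=np.asarray(d["alive"], bool),
        )


@dataclass(frozen=True)
class NoiseModel:
    """Signal-dependent activity noise.

    Gaussian noise with variance ``k * mean`` is added to each neuron's
    mean activity and the result re-rectified at 0.  ``k = 0`` makes all
    sampled activities equal their means; a silent neuron (mean 0) has
    zero variance and stays silent.
    """

    k: float = 0.1
    form: str = "proportional"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError("noise strength k must be nonnegative")
        if self.form != "proportional":
            raise ConfigurationError(f"unknown noise form {self.form!r}")


@dataclass(frozen=True)
class PV:
    """A population vector: direction models the reach, norm its speed."""

    x: float
    y: float

    @property
    def norm(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def defined(self) -> bool:
        """False when the norm is 0 and the angle is meaningless."""
        return self.norm > 0.0

    @property
    def angle(self) -> float:
        """Angle in [0, 360) degrees; NaN when undefined."""
        if not self.defined:
            return float("nan")
        return float(np.rad2deg(np.arctan2(self.y, self.x)) % 360.0)


def encoding_pd(pop: Population, condition: Condition) -> np.ndarray:
    """Encoding PDs in force under ``condition``, degrees in [0, 360).

    Unimanual movement leaves the base PDs untouched; the bimanual
    rotation regimes add the per-neuron quenched (or annealed, refreshed
    by the trial loop) offset.
    """
    if condition.rotates_encoding:
        return wrap_deg(pop.base_pd + pop.rotation_offset)
    return pop.base_pd.copy()


def mean_activity(
    pop: Population, condition: Condition, target: float
) -> np.ndarray:
    """Noise-free activity of every neuron for a reach toward ``target``.

    activity_i = rectify(depth_i * cos(target - encoding_pd_i)); dead
    neurons are fixed at 0.
    """
    enc = np.deg2rad(encoding_pd(pop, condition))
    d = condition.effective_depth(pop)
    a = np.maximum(0.0, d * np.cos(np.deg2rad(target) - enc))
    a[~pop.alive] = 0.0
    return a


def sample_activity(
    mean: np.ndarray, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Add signal-dependent noise to mean activities and re-rectify.

    The added noise is zero-mean Gaussian with variance ``k * mean`` per
    neuron, so silent neurons stay exactly silent.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("mean activities must be nonnegative")
    if noise.k == 0:
        return mean.copy()
    sd = np.sqrt(noise.k * mean)
    return np.maximum(0.0, mean + rng.normal(0.0, 1.0, size=mean.shape) * sd)


def population_vector(
    pop: Population, activities: np.ndarray, condition: Condition
) -> PV:
    """Decode activities into a population vector.

    Sums activity-weighted decoding-PD unit vectors over *alive* neurons
    but normalizes by the original (pre-lesion) neuron count, so a lesion
    shrinks the PV norm — the model's account of post-stroke slowing.
    """
    activities = np.asarray(activities, dtype=float)
    if len(activities) != pop.n:
        raise ValueError("activities must align with the population")
    dec = np.deg2rad(decoding_pd(pop, condition))
    w = activities * pop.alive
    x = float(np.sum(w * np.cos(dec)) / pop.n)
    y = float(np.sum(w * np.sin(dec)) / pop.n)
    return PV(x, y)


def forward_reach(
    pop: Population,
    condition: Condition,
    target: float,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, PV]:
    """One noisy reach: sampled activities and the resulting PV."""
    a = sample_activity(mean_activity(pop, condition, target), noise, rng)
    return a, population_vector(pop, a, condition)
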