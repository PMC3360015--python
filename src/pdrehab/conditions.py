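"""Movement-condition variants for unimanual and bimanual reaching.

During bimanual movement the tuning curves of motor-cortex neurons change:
each neuron's *encoding* preferred direction (PD) is rotated by a quenched
(trial-invariant) Gaussian offset, while the *decoding* PD — the direction
the neuron's activity contributes to the population vector, fixed by
cortical-spinal-muscle connectivity — stays put.  This module constructs the
variants of that manipulation used by the experiments:

- quenched encoding-PD rotations (the main bimanual condition),
- annealed (per-trial) rotations,
- modulation-depth-only changes with no PD rotation,
- rotation of both encoding and decoding PDs,

plus the closed-form inter-hemispheric-inhibition account of *why* bimanual
movement rotates encoding PDs: inhibitory input driven by the opposite
hemisphere adds negative cosine terms to a neuron's tuning curve, and the
resultant cosine has a shifted phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .population import Population

REGIMES = (
    "unimanual",
    "bimanual_quenched",
    "bimanual_annealed",
    "bimanual_depth_only",
    "bimanual_enc_dec",
)

#: regimes in which the encoding PD is base_pd + rotation_offset
_ROTATED_ENCODING = {"bimanual_quenched", "bimanual_annealed", "bimanual_enc_dec"}


class ConfigurationError(ValueError):
    """Raised when a condition, lesion or learning setting is invalid."""


@dataclass(frozen=True)
class Condition:
    """Which movement regime is simulated and how it perturbs the population.

    Parameters
    ----------
    regime:
        One of :data:`REGIMES`.
    sigma:
        Standard deviation, in degrees, of the Gaussian encoding-PD
        rotation (quenched or annealed).  Ignored by the depth-only regime.
    depth_sigma:
        Spread of the multiplicative modulation-depth change (log-normal
        scale parameter) in the depth-only regime.
    seed:
        Seed for the quenched draws (rotation offsets / depth factors).
    depth_factor:
        Per-neuron multiplicative depth factors.  ``None`` means no change.
    """

    regime: str = "unimanual"
    sigma: float = 0.0
    depth_sigma: float = 0.0
    seed: int = 0
    depth_factor: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigurationError(
                f"unknown condition regime {self.regime!r}; expected one of {REGIMES}"
            )
        if self.sigma < 0:
            raise ConfigurationError("rotation sigma must be nonnegative")
        if self.depth_sigma < 0:
            raise ConfigurationError("depth_sigma must be nonnegative")

    @property
    def rotates_encoding(self) -> bool:
        return self.regime in _ROTATED_ENCODING

    @property
    def rotates_decoding(self) -> bool:
        return self.regime == "bimanual_enc_dec"

    @property
    def annealed(self) -> bool:
        return self.regime == "bimanual_annealed"

    def effective_depth(self, pop: "Population") -> np.ndarray:
        """Modulation depths in force under this condition."""
        if self.depth_factor is None:
            return pop.depth
        if len(self.depth_factor) != pop.n:
            raise ConfigurationError(
                "depth_factor length does not match population size"
            )
        return pop.depth * self.depth_factor


def unimanual() -> Condition:
    """The baseline condition: no rotation, no depth change."""
    return Condition(regime="unimanual")


def make_quenched_rotations(
    n: int, sigma: float, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Draw the quenched per-neuron encoding-PD rotation offsets.

    Offsets are i.i.d. Gaussian(0, sigma^2) in degrees and fixed for the
    lifetime of the condition: the same ``(n, sigma, seed)`` always yields
    the same vector.
    """
    if sigma < 0:
        raise ConfigurationError("rotation sigma must be nonnegative")
    if sigma == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sigma, size=n)


def resample_annealed_rotations(
    n: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Redraw rotation offsets from the per-trial stream (annealed variant)."""
    if sigma < 0:
        raise ConfigurationError("rotation sigma must be nonnegative")
    if sigma == 0:
        return np.zeros(n)
    return rng.normal(0.0, sigma, size=n)


def make_depth_change(
    n: int, depth_sigma: float, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Quenched multiplicative modulation-depth factors, always positive.

    Factors are exp(Gaussian(0, depth_sigma^2)) so that depths stay
    positive; ``depth_sigma = 0`` gives factors of exactly 1.
    """
    if depth_sigma < 0:
        raise ConfigurationError("depth_sigma must be nonnegative")
    if depth_sigma == 0:
        return np.ones(n)
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(0.0, depth_sigma, size=n))


def build_condition(
    regime: str,
    n: int,
    sigma: float = 0.0,
    depth_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Condition, np.ndarray]:
    """Build a condition plus the quenched rotation offsets it implies.

    Returns ``(condition, offsets)`` where ``offsets`` is the per-neuron
    quenched rotation vector to attach to the population (zeros for the
    unimanual, annealed and depth-only regimes — annealed offsets are
    redrawn inside the trial loop).
    """
    cond = Condition(regime=regime, sigma=sigma, depth_sigma=depth_sigma, seed=seed)
    if regime in ("bimanual_quenched", "bimanual_enc_dec"):
        offsets = make_quenched_rotations(n, sigma, seed)
    else:
        offsets = np.zeros(n)
    if regime == "bimanual_depth_only":
        factors = make_depth_change(n, depth_sigma, seed)
        cond = Condition(
            regime=regime,
            sigma=sigma,
            depth_sigma=depth_sigma,
            seed=seed,
            depth_factor=factors,
        )
    return cond, offsets


def decoding_pd(pop: "Population", condition: Condition) -> np.ndarray:
    """Decoding PDs, degrees in [0, 360).

    The decoding PD equals the (unrotated) base PD in every regime except
    the encoding+decoding-rotation variant, where the quenched offset is
    applied to decoding as well.
    """
    from .population import wrap_deg

    if condition.rotates_decoding:
        return wrap_deg(pop.base_pd + pop.rotation_offset)
    return pop.base_pd.copy()


# --------------------------------------------------------------------------
# Inter-hemispheric inhibition: closed-form effective tuning
# --------------------------------------------------------------------------

def cosine_sum(
    terms: Sequence[tuple[float, float]]
) -> tuple[float, float, bool]:
    """Resultant of a sum of equal-frequency cosines.

    Each term ``(a, p)`` stands for ``a * cos(theta - p)`` with ``p`` in
    degrees.  Treating each as the planar vector ``(a cos p, a sin p)`` and
    summing gives the resultant ``A cos(theta - P)``.

    Returns
    -------
    (amplitude, phase_deg, defined) :
        ``defined`` is False when the resultant amplitude is 0, in which
        case the phase is meaningless (returned as 0.0).
    """
    if len(terms) == 0:
        raise ValueError("cosine_sum needs at least one term")
    amps = np.asarray([t[0] for t in terms], dtype=float)
    phases = np.deg2rad([t[1] for t in terms])
    x = float(np.sum(amps * np.cos(phases)))
    y = float(np.sum(amps * np.sin(phases)))
    amp = float(np.hypot(x, y))
    # amplitudes cancelling to rounding error count as a zero resultant
    if amp <= 1e-12 * max(float(np.abs(amps).sum()), 1e-300):
        return 0.0, 0.0, False
    phase = float(np.rad2deg(np.arctan2(y, x))) % 360.0
    return amp, phase, True


@dataclass(frozen=True)
class InhibitionParams:
    """Inter-hemispheric inhibition acting on a left-hemisphere neuron.

    ``c`` is the inhibition strength (corpus-callosum weight times the
    interneuron-to-neuron weight); ``right_pds`` are the PDs of the K
    right-hemisphere neurons projecting to the neuron's inhibitory
    interneuron.  ``c = 0`` recovers unimanual tuning exactly.
    """

    c: float
    right_pds: np.ndarray

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ConfigurationError("inhibition strength c must be nonnegative")

    @property
    def K(self) -> int:
        return len(self.right_pds)


@dataclass(frozen=True)
class InhibitionResult:
    effective_depth: float
    effective_pd: float
    rotation: float
    degenerate: bool


def inhibition_rotation(
    base_pd: float, depth: float, params: InhibitionParams
) -> InhibitionResult:
    """Effective tuning of a neuron under inter-hemispheric inhibition.

    During bimanual movement the right hemisphere is active too; through
    excitatory callosal projections it drives an inhibitory interneuron
    whose input to this neuron is a sum of cosines at the right-hemisphere
    PDs, with weight -c each.  The neuron's effective tuning is then the
    cosine resultant of its own ``depth * cos(theta - base_pd)`` and those
    K inhibitory terms — still a cosine, but with a rotated phase: the
    bimanual encoding PD.

    With sparse connectivity (small K) the rotation is a random,
    neuron-specific angle whose spread grows with c.  With dense
    connectivity and c scaled as c/K the inhibitory terms average out by
    the law of large numbers and the rotation vanishes.

    Returns a result whose ``rotation`` is the signed PD shift in
    (-180, 180].  If inhibition overwhelms the tuning (resultant amplitude
    0), the result is flagged degenerate and the rotation is NaN.
    """
    from .population import wrap_signed_deg

    terms = [(float(depth), float(base_pd))]
    terms += [(-params.c, float(p)) for p in np.atleast_1d(params.right_pds)]
    amp, phase, defined = cosine_sum(terms)
    if not defined:
        return InhibitionResult(0.0, float("nan"), float("nan"), True)
    rotation = float(wrap_signed_deg(phase - base_pd))
    return InhibitionResult(amp, phase, rotation, False)


def inhibition_rotation_profile(
    base_pds: np.ndarray,
    depth: float,
    c: float,
    K: int,
    rng: np.random.Generator,
    scale_by_K: bool = False,
) -> np.ndarray:
    """Signed rotations for a population of neurons, one connectivity draw each.

    Right-hemisphere PDs are drawn i.i.d. uniform on the circle,
    independently per neuron.  ``scale_by_K`` divides c by K (the dense
    regime).  Degenerate (over-inhibited) neurons yield NaN.
    """
    c_eff = c / K if (scale_by_K and K > 0) else c
    out = np.empty(len(base_pds))
    for i, pd in enumerate(base_pds):
        right = rng.uniform(0.0, 360.0, size=K)
        res = inhibition_rotation(float(pd), depth, InhibitionParams(c_eff, right))
        out[i] = res.rotation
    return out


def write_inhibition_profile(
    base_pds: np.ndarray,
    depth: float,
    c: float,
    K: int,
    rng: np.random.Generator,
    out_path,
    scale_by_K: bool = False,
):
    """Emit a per-neuron CSV of the inhibition analysis.

    Columns: neuron, base_pd_deg, rotation_deg, effective_depth.
    """
    import pandas as pd

    c_eff = c / K if (scale_by_K and K > 0) else c
    rows = []
    for i, pd_i in enumerate(base_pds):
        right = rng.uniform(0.0, 360.0, size=K)
        res = inhibition_rotation(float(pd_i), depth, InhibitionParams(c_eff, right))
        rows.append((i, float(pd_i), res.rotation, res.effective_depth))
    frame = pd.DataFrame(
        rows, columns=["neuron", "base_pd_deg", "rotation_deg", "effective_depth"]
    )
    frame.to_csv(out_path, index=False)
    return frame
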