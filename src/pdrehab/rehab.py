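"""Lesion construction and trial-by-trial reorganization of the population.

The stroke is a directional lesion: every neuron whose base encoding PD
falls in a wedge around the lesion center is depleted.  Rehabilitation is
then modeled as stochastic gradient descent, one reach per trial, on

    E = err^2 + lambda * sum_i a_i^2

where ``err`` is the wrapped angular error (degrees) between the population
vector and the target — the supervised term — and the activity penalty is
the unsupervised metabolic term.  The gradient is taken with respect to the
surviving neurons' base encoding PDs, with the trial's noise realization
held fixed (the learning rule sees the same activities that produced the
movement).  Optionally a zero-mean Gaussian "synaptic drift" is added to
every update.

Degrees everywhere at the API: errors in degrees, learning rates scaled so
that an update of 1 moves a PD by 1 degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import Condition, ConfigurationError, decoding_pd, resample_annealed_rotations
from .population import (
    STANDARD_TARGETS,
    NoiseModel,
    Population,
    encoding_pd,
    mean_activity,
    population_vector,
    sample_activity,
    wrap_deg,
    wrap_signed_deg,
)

#: error assigned when the PV norm is 0 and its angle undefined
UNDEFINED_PV_ERROR = 180.0


@dataclass(frozen=True)
class LesionSpec:
    """A directional lesion: deplete the wedge |wrap(base_pd - center)| <= fraction*180."""

    center: float = 90.0
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction < 1.0):
            raise ConfigurationError("lesion fraction must be in [0, 1)")

    def half_width(self) -> float:
        return self.fraction * 180.0

    def in_wedge(self, pds: np.ndarray) -> np.ndarray:
        """Boolean mask of PDs inside the lesion wedge."""
        return np.abs(wrap_signed_deg(np.asarray(pds, float) - self.center)) <= self.half_width()


def apply_lesion(pop: Population, spec: LesionSpec) -> Population:
    """Deplete the lesion wedge; returns a new population, other fields untouched."""
    killed = spec.in_wedge(pop.base_pd)
    return pop.with_(alive=pop.alive & ~killed)


def angular_error(pv_angle: float, target: float) -> float:
    """Signed angular error in (-180, 180] degrees; 180 for an undefined PV angle."""
    if pv_angle is None or not np.isfinite(pv_angle):
        return UNDEFINED_PV_ERROR
    return float(wrap_signed_deg(pv_angle - target))


def trial_cost(
    pv_angle: float, target: float, activities: np.ndarray, lam: float
) -> float:
    """Supervised squared angular error plus the metabolic activity penalty."""
    if lam < 0:
        raise ConfigurationError("regularization weight lam must be nonnegative")
    err = angular_error(pv_angle, target)
    return float(err**2 + lam * np.sum(np.asarray(activities, float) ** 2))


@dataclass(frozen=True)
class LearningConfig:
    """Learning rates and options for the reorganization rule.

    ``eta_sup`` and ``eta_unsup`` are the supervised and unsupervised
    learning rates (degree-scaled); ``lam`` weights the metabolic term in
    the cost; ``drift_sigma`` is the SD in degrees of the Gaussian synaptic
    drift added to each update.  ``gradient_mode`` selects the analytic
    gradient or a central finite-difference fallback; ``update_targets``
    chooses whether gradients flow through the encoding dependence only
    (the default — decoding unit vectors are constants within a step) or
    through the decoding readout as well.
    """

    eta_sup: float = 0.1
    eta_unsup: float = 0.1
    lam: float = 0.01
    drift_sigma: float = 0.0
    gradient_mode: str = "analytic"
    update_targets: str = "encoding_only"

    def __post_init__(self) -> None:
        if self.eta_sup < 0 or self.eta_unsup < 0:
            raise ConfigurationError("learning rates must be nonnegative")
        if self.lam < 0:
            raise ConfigurationError("lam must be nonnegative")
        if self.drift_sigma < 0:
            raise ConfigurationError("drift_sigma must be nonnegative")
        if self.gradient_mode not in ("analytic", "finite_difference"):
            raise ConfigurationError(f"unknown gradient_mode {self.gradient_mode!r}")
        if self.update_targets not in ("encoding_only", "encoding_and_decoding"):
            raise ConfigurationError(f"unknown update_targets {self.update_targets!r}")


def _cost_terms_of_pds(
    pop: Population,
    condition: Condition,
    target: float,
    eps: np.ndarray,
    base_pd: np.ndarray,
    dec_fixed: np.ndarray | None = None,
) -> tuple[float, float]:
    """(err^2, sum a^2) as functions of the base PDs, noise held fixed.

    ``dec_fixed`` (degrees) pins the decoding PDs, matching the
    encoding-only gradient path where decoding unit vectors are constants
    within a step.
    """
    p = pop.with_(base_pd=wrap_deg(base_pd))
    mean = mean_activity(p, condition, target)
    a = np.maximum(0.0, mean + eps)
    a[~p.alive] = 0.0
    if dec_fixed is None:
        pv = population_vector(p, a, condition)
    else:
        dec = np.deg2rad(dec_fixed)
        w = a * p.alive
        pv_x = float(np.sum(w * np.cos(dec)) / p.n)
        pv_y = float(np.sum(w * np.sin(dec)) / p.n)
        from .population import PV

        pv = PV(pv_x, pv_y)
    err = angular_error(pv.angle, target)
    return float(err**2), float(np.sum(a**2))


def cost_gradient(
    pop: Population,
    condition: Condition,
    target: float,
    activities: np.ndarray,
    cfg: LearningConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron gradients of the two cost terms w.r.t. the base PDs.

    Returns ``(g_sup, g_unsup)`` in degrees^2-per-degree units:
    ``g_sup = d(err^2)/d(phi)`` and ``g_unsup = d(sum a^2)/d(phi)``,
    evaluated at the trial's sampled activities with the additive noise
    realization treated as a fixed constant.  Inactive neurons (activity
    rectified to 0) receive zero gradient; dead neurons always do.
    """
    a = np.asarray(activities, float)
    enc = np.deg2rad(encoding_pd(pop, condition))
    dec = np.deg2rad(decoding_pd(pop, condition))
    th = np.deg2rad(target)
    d_eff = condition.effective_depth(pop)
    drive = d_eff * np.cos(th - enc)

    # da/dphi in radians: active through both rectifiers, else subgradient 0
    active = (a > 0) & (drive > 0) & pop.alive
    dadphi = np.where(active, d_eff * np.sin(th - enc), 0.0)

    pv = population_vector(pop, a, condition)
    if not pv.defined:
        g_sup = np.zeros(pop.n)
    else:
        err = angular_error(pv.angle, target)
        n2 = pv.norm**2
        # d(alpha)/d(phi), dimensionless (rad/rad == deg/deg)
        dalpha = dadphi * (pv.x * np.sin(dec) - pv.y * np.cos(dec)) / (pop.n * n2)
        if cfg.update_targets == "encoding_and_decoding":
            # decoding PDs are yoked to base_pd (plus a constant offset in the
            # enc+dec regime), so d(psi)/d(phi) = 1 for alive neurons
            dalpha = dalpha + np.where(
                pop.alive, a * (pv.x * np.cos(dec) + pv.y * np.sin(dec)), 0.0
            ) / (pop.n * n2)
        g_sup = 2.0 * err * dalpha
    g_unsup = 2.0 * a * dadphi * (np.pi / 180.0)
    g_sup[~pop.alive] = 0.0
    g_unsup[~pop.alive] = 0.0
    return g_sup, g_unsup


def fd_cost_gradient(
    pop: Population,
    condition: Condition,
    target: float,
    activities: np.ndarray,
    update_targets: str = "encoding_only",
    h: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Central finite differences of (err^2, sum a^2) w.r.t. each base PD.

    Differentiates the same function as :func:`cost_gradient`: in the
    default encoding-only mode the decoding PDs are pinned at their
    unperturbed values, whereas ``encoding_and_decoding`` lets the
    perturbation flow through the readout as well.
    """
    mean = mean_activity(pop, condition, target)
    eps = np.asarray(activities, float) - mean
    dec_fixed = decoding_pd(pop, condition) if update_targets == "encoding_only" else None
    g_sup = np.zeros(pop.n)
    g_unsup = np.zeros(pop.n)
    for i in range(pop.n):
        if not pop.alive[i]:
            continue
        up = pop.base_pd.copy()
        dn = pop.base_pd.copy()
        up[i] += h
        dn[i] -= h
        su, mu = _cost_terms_of_pds(pop, condition, target, eps, up, dec_fixed)
        sd, md = _cost_terms_of_pds(pop, condition, target, eps, dn, dec_fixed)
        g_sup[i] = (su - sd) / (2 * h)
        g_unsup[i] = (mu - md) / (2 * h)
    return g_sup, g_unsup


def learning_step(
    pop: Population,
    condition: Condition,
    target: float,
    activities: np.ndarray,
    cfg: LearningConfig,
    rng: np.random.Generator,
) -> Population:
    """One gradient update of the surviving neurons' base encoding PDs.

    phi_i <- phi_i - eta_sup * d(err^2)/d(phi_i)
                   - eta_unsup * lam * d(sum a^2)/d(phi_i)  [+ drift]

    Dead neurons, depths and quenched offsets are untouched; PDs are
    re-wrapped to [0, 360).  A nonfinite gradient rejects the step (the
    population is returned unchanged except for drift, which is skipped
    too).
    """
    if cfg.gradient_mode == "finite_difference":
        g_sup, g_unsup = fd_cost_gradient(
            pop, condition, target, activities, cfg.update_targets
        )
    else:
        g_sup, g_unsup = cost_gradient(pop, condition, target, activities, cfg)
    delta = -cfg.eta_sup * g_sup - cfg.eta_unsup * cfg.lam * g_unsup
    if not np.all(np.isfinite(delta)):
        return pop
    if cfg.drift_sigma > 0:
        delta = delta + np.where(
            pop.alive, rng.normal(0.0, cfg.drift_sigma, size=pop.n), 0.0
        )
    new_pd = np.where(pop.alive, wrap_deg(pop.base_pd + delta), pop.base_pd)
    return pop.with_(base_pd=new_pd)


@dataclass(frozen=True)
class Protocol:
    """Target schedule and trial budget for one rehabilitation run."""

    targets: tuple[float, ...] = STANDARD_TARGETS
    target_probs: tuple[float, ...] | None = None
    n_trials: int = 3000
    snapshot_trials: tuple[int, ...] = (1000, 2000, 3000)

    def __post_init__(self) -> None:
        probs = self.target_probs
        if probs is None:
            probs = tuple(1.0 / len(self.targets) for _ in self.targets)
            object.__setattr__(self, "target_probs", probs)
        probs = np.asarray(probs, float)
        if len(probs) != len(self.targets):
            raise ConfigurationError("target_probs must align with targets")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("target_probs must be nonnegative and sum to 1")


def named_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named RNG streams derived from one master seed.

    Streams: ``targets`` (schedule draws), ``noise`` (activity noise),
    ``drift`` (synaptic drift), ``annealed`` (per-trial rotation redraws),
    ``eval`` (Monte-Carlo evaluation reaches).
    """
    names = ("targets", "noise", "drift", "annealed", "eval")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


@dataclass
class Trajectory:
    """Per-trial records plus population snapshots from one run."""

    trials: pd.DataFrame
    snapshots: dict[int, Population]
    final: Population
    meta: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write trials.csv, per-snapshot population CSVs and metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        for t, pop in self.snapshots.items():
            pop.to_csv(outdir / f"population_trial{t:05d}.csv")
        self.final.to_csv(outdir / "population_final.csv")
        (outdir / "run_meta.json").write_text(json.dumps(self.meta, indent=2, default=str))


def run_rehabilitation(
    pop: Population,
    condition: Condition,
    protocol: Protocol,
    cfg: LearningConfig,
    noise: NoiseModel,
    streams: dict[str, np.random.Generator] | int = 0,
) -> Trajectory:
    """Run the full trial loop: reach, evaluate, learn, repeat.

    Each trial draws a target from the protocol distribution, computes the
    condition's encoding PDs (redrawing annealed rotations if the regime
    asks for them), samples noisy activities, decodes the PV, records
    error and cost, then applies one learning step.  Snapshots of the
    population are recorded after the trials listed in the protocol
    (1-based: a snapshot at 1000 is the state after 1000 trials).

    ``streams`` may be a master seed (int) or the dict from
    :func:`named_streams`; identical seeds and configs give bit-identical
    trajectories.
    """
    if isinstance(streams, (int, np.integer)):
        streams = named_streams(int(streams))
    targets = np.asarray(protocol.targets, float)
    probs = np.asarray(protocol.target_probs, float)
    snapshots: dict[int, Population] = {}
    rec: list[tuple] = []
    cur = pop
    for t in range(1, protocol.n_trials + 1):
        if condition.annealed:
            cur = cur.with_(
                rotation_offset=resample_annealed_rotations(
                    cur.n, condition.sigma, streams["annealed"]
                )
            )
        target = float(targets[streams["targets"].choice(len(targets), p=probs)])
        mean = mean_activity(cur, condition, target)
        acts = sample_activity(mean, noise, streams["noise"])
        pv = population_vector(cur, acts, condition)
        err = angular_error(pv.angle, target)
        cost = trial_cost(pv.angle, target, acts, cfg.lam)
        rec.append((t, target, pv.angle, pv.norm, err, cost))
        cur = learning_step(cur, condition, target, acts, cfg, streams["drift"])
        if t in protocol.snapshot_trials:
            snapshots[t] = cur
    trials = pd.DataFrame(
        rec, columns=["trial", "target_deg", "pv_angle_deg", "pv_norm", "err_deg", "cost"]
    )
    from . import __version__

    meta = {
        "version": __version__,
        "condition": {k: v for k, v in asdict(condition).items() if k != "depth_factor"},
        "learning": asdict(cfg),
        "protocol": asdict(protocol),
        "noise": asdict(noise),
        "n_neurons": pop.n,
    }
    return Trajectory(trials=trials, snapshots=snapshots, final=cur, meta=meta)
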