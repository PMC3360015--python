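"""Reorganization and movement-quality metrics, and the named experiment scenarios.

Reorganization of the damaged cortex is read off the distribution of the
surviving neurons' base encoding PDs: a circular histogram, a normalized
circular-entropy uniformity score, and the fraction of alive neurons whose
PD has migrated back into the original lesion wedge (``wedge_fill``).
Movement quality is probed by Monte-Carlo unimanual reaches to the eight
standard targets: mean absolute angular error (precision) and mean PV norm
(speed) per target.

`run_scenario` wires these together for the named experiment protocols —
each one is the base configuration plus the single manipulated factor, so
paired-seed contrasts isolate that factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import Condition, ConfigurationError, build_condition
from .population import (
    STANDARD_TARGETS,
    NoiseModel,
    Population,
    mean_activity,
    wrap_signed_deg,
)
from .rehab import (
    LearningConfig,
    LesionSpec,
    Protocol,
    Trajectory,
    angular_error,
    apply_lesion,
    named_streams,
    run_rehabilitation,
)

SCENARIOS = (
    "unimanual",
    "bimanual_quenched",
    "bimanual_annealed",
    "depth_only",
    "enc_dec_rotation",
    "nonuniform_targets",
    "supervised_only",
    "unsupervised_only",
    "annealed_drift",
)


@dataclass(frozen=True)
class ReorgSummary:
    """Circular histogram of alive base PDs plus scalar reorganization measures."""

    counts: np.ndarray
    bin_edges: np.ndarray
    uniformity: float
    wedge_fill: float
    n_alive: int

    @property
    def empty(self) -> bool:
        return self.n_alive == 0


def pd_histogram(
    pop: Population, n_bins: int = 36, lesion: LesionSpec | None = None
) -> ReorgSummary:
    """Bin the alive base PDs into equal circular bins.

    ``uniformity`` is the Shannon entropy of the bin distribution divided
    by log(n_bins), i.e. 1 for a perfectly equalized population and lower
    the more the PDs clump.  ``wedge_fill`` is the fraction of alive
    neurons whose base PD lies inside ``lesion``'s wedge (0 when no lesion
    is given); immediately after the lesion it is exactly 0, and it grows
    as reorganization repopulates the depleted directions.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be at least 2")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    alive_pds = pop.base_pd[pop.alive]
    counts, _ = np.histogram(alive_pds, bins=edges)
    n_alive = int(counts.sum())
    if n_alive == 0:
        return ReorgSummary(counts, edges, float("nan"), float("nan"), 0)
    p = counts / n_alive
    nz = p[p > 0]
    uniformity = float(-(nz * np.log(nz)).sum() / np.log(n_bins))
    if lesion is None:
        wedge_fill = 0.0
    else:
        wedge_fill = float(np.count_nonzero(lesion.in_wedge(alive_pds)) / n_alive)
    return ReorgSummary(counts, edges, uniformity, wedge_fill, n_alive)


@dataclass(frozen=True)
class DirectionProfile:
    """Per-target Monte-Carlo movement quality in unimanual reaching."""

    table: pd.DataFrame  # target_deg, mean_abs_err, sem_err, mean_norm, sem_norm
    n_reps: int

    def at(self, target: float) -> pd.Series:
        row = self.table[self.table["target_deg"] == target]
        if row.empty:
            raise KeyError(f"no profile entry for target {target}")
        return row.iloc[0]

    @property
    def worst_error_target(self) -> float:
        return float(self.table.loc[self.table["mean_abs_err"].idxmax(), "target_deg"])

    @property
    def slowest_target(self) -> float:
        return float(self.table.loc[self.table["mean_norm"].idxmin(), "target_deg"])


def evaluate_unimanual(
    pop: Population,
    targets: Sequence[float] = STANDARD_TARGETS,
    n_reps: int = 200,
    noise: NoiseModel = NoiseModel(k=0.1),
    rng: np.random.Generator | int = 0,
) -> DirectionProfile:
    """Probe unimanual reaching quality with ``n_reps`` noisy reaches per target."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be at least 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cond = Condition(regime="unimanual")
    dec = np.deg2rad(pop.base_pd)
    cw, sw = np.cos(dec) * pop.alive, np.sin(dec) * pop.alive
    rows = []
    for t in targets:
        mean = mean_activity(pop, cond, float(t))
        if noise.k == 0:
            acts = np.tile(mean, (n_reps, 1))
        else:
            sd = np.sqrt(noise.k * mean)
            acts = np.maximum(0.0, mean + rng.normal(size=(n_reps, pop.n)) * sd)
        x = acts @ cw / pop.n
        y = acts @ sw / pop.n
        norms = np.hypot(x, y)
        ang = np.rad2deg(np.arctan2(y, x)) % 360.0
        errs = np.abs(wrap_signed_deg(ang - float(t)))
        errs[norms == 0] = 180.0
        rows.append(
            (
                float(t),
                errs.mean(),
                errs.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0,
                norms.mean(),
                norms.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0,
            )
        )
    table = pd.DataFrame(
        rows, columns=["target_deg", "mean_abs_err", "sem_err", "mean_norm", "sem_norm"]
    )
    return DirectionProfile(table=table, n_reps=n_reps)


# --------------------------------------------------------------------------
# Named experiment scenarios
# --------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    name: str
    trajectory: Trajectory
    lesion: LesionSpec
    reorg: dict[int, ReorgSummary]        # snapshot trial -> summary
    profiles: dict[int, DirectionProfile]  # snapshot trial -> profile
    post_lesion_reorg: ReorgSummary
    post_lesion_profile: DirectionProfile

    @property
    def final_reorg(self) -> ReorgSummary:
        return self.reorg[max(self.reorg)] if self.reorg else self.post_lesion_reorg


def nearest_targets(center: float, targets: Sequence[float], k: int = 3) -> tuple[float, ...]:
    """The k targets closest (circularly) to the lesion center."""
    t = np.asarray(targets, float)
    dist = np.abs(wrap_signed_deg(t - center))
    return tuple(float(x) for x in t[np.argsort(dist, kind="stable")[:k]])


def _scenario_deltas(name: str, base: dict) -> dict:
    """Per-scenario overrides of the base configuration dictionary."""
    d = dict(base)
    if name == "unimanual":
        d.update(regime="unimanual", sigma=0.0)
    elif name == "bimanual_quenched":
        d.update(regime="bimanual_quenched")
    elif name == "bimanual_annealed":
        d.update(regime="bimanual_annealed")
    elif name == "depth_only":
        d.update(regime="bimanual_depth_only", sigma=0.0)
    elif name == "enc_dec_rotation":
        d.update(regime="bimanual_enc_dec")
    elif name == "nonuniform_targets":
        pass  # regime from config; only the target schedule is restricted
    elif name == "supervised_only":
        d.update(eta_unsup=0.0)
    elif name == "unsupervised_only":
        d.update(eta_sup=0.0)
    elif name == "annealed_drift":
        d.update(regime="unimanual", sigma=0.0)
        if d.get("drift_sigma", 0.0) == 0.0:
            d["drift_sigma"] = d.get("default_drift_sigma", 2.0)
    else:
        raise ConfigurationError(
            f"unknown scenario {name!r}; expected one of {SCENARIOS}"
        )
    return d


def run_scenario(
    name: str,
    n_neurons: int = 500,
    seed: int = 0,
    regime: str = "bimanual_quenched",
    sigma: float = 60.0,
    depth_sigma: float = 0.5,
    lesion: LesionSpec = LesionSpec(),
    learning: LearningConfig = LearningConfig(),
    noise: NoiseModel = NoiseModel(k=0.1),
    n_trials: int = 3000,
    snapshot_trials: tuple[int, ...] = (1000, 2000, 3000),
    layout: str = "grid",
    depth: float = 1.0,
    eval_reps: int = 200,
    drift_sigma_default: float = 2.0,
) -> ScenarioResult:
    """Run one named experiment protocol end to end.

    Builds the population, applies the lesion, constructs the scenario's
    condition/protocol/learning deltas on top of the base settings, runs
    the rehabilitation loop, and summarizes reorganization and unimanual
    movement quality at each snapshot.  All randomness (quenched draws,
    target schedule, noise, drift, evaluation) derives from ``seed``, so
    two scenarios run with the same seed share their base population,
    lesion and noise stream and differ only in the manipulated factor.
    """
    base = dict(
        regime=regime,
        sigma=sigma,
        depth_sigma=depth_sigma,
        eta_sup=learning.eta_sup,
        eta_unsup=learning.eta_unsup,
        lam=learning.lam,
        drift_sigma=learning.drift_sigma,
        gradient_mode=learning.gradient_mode,
        update_targets=learning.update_targets,
        default_drift_sigma=drift_sigma_default,
    )
    d = _scenario_deltas(name, base)

    ss = np.random.SeedSequence(seed)
    quench_seed, layout_seed, run_seed, eval_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    layout_rng = np.random.default_rng(layout_seed)
    pop = Population.uniform(n_neurons, layout=layout, depth=depth, rng=layout_rng)
    cond, offsets = build_condition(
        d["regime"], n_neurons, sigma=d["sigma"], depth_sigma=d["depth_sigma"], seed=quench_seed
    )
    pop = pop.with_(rotation_offset=offsets)
    lesioned = apply_lesion(pop, lesion)

    targets: tuple[float, ...] = STANDARD_TARGETS
    if name == "nonuniform_targets":
        targets = nearest_targets(lesion.center, STANDARD_TARGETS, k=3)
    protocol = Protocol(targets=targets, n_trials=n_trials, snapshot_trials=snapshot_trials)
    cfg = LearningConfig(
        eta_sup=d["eta_sup"],
        eta_unsup=d["eta_unsup"],
        lam=d["lam"],
        drift_sigma=d["drift_sigma"],
        gradient_mode=d["gradient_mode"],
        update_targets=d["update_targets"],
    )
    traj = run_rehabilitation(lesioned, cond, protocol, cfg, noise, streams=run_seed)
    traj.meta.update(scenario=name, seed=seed, lesion={"center": lesion.center, "fraction": lesion.fraction})

    post_reorg = pd_histogram(lesioned, lesion=lesion)
    post_profile = evaluate_unimanual(
        lesioned, STANDARD_TARGETS, eval_reps, noise, np.random.default_rng(eval_seed)
    )
    reorg: dict[int, ReorgSummary] = {}
    profiles: dict[int, DirectionProfile] = {}
    for t, snap in traj.snapshots.items():
        reorg[t] = pd_histogram(snap, lesion=lesion)
        profiles[t] = evaluate_unimanual(
            snap, STANDARD_TARGETS, eval_reps, noise, np.random.default_rng(eval_seed)
        )
    return ScenarioResult(
        name=name,
        trajectory=traj,
        lesion=lesion,
        reorg=reorg,
        profiles=profiles,
        post_lesion_reorg=post_reorg,
        post_lesion_profile=post_profile,
    )
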