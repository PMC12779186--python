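"""Closed-loop orchestration: daily sample -> retrain -> optimize -> actuate.

The agent reproduces the autonomous-operation use cases on the synthetic
plant: each reactor follows the reference protocol (perfusion-rate ramp to
the state-of-control VCV target) until the control start day; from then on,
every day after sampling the shared ensemble is retrained on the base
campaign plus all live data, each reactor's objective is optimized over its
bounded controls, and the chosen setpoints are written for the next day
interval.  A benchmark mode runs the identical protocol with setpoints
frozen at reference levels, so controlled-vs-benchmark differences are
attributable to the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONTROL_BOUNDS
from .datamodel import compute_vcv
from .optimizer import (ObjectiveSpec, OptimizerError, SearchSpace,
                        optimize_setpoints, predict_violations)
from .plant import (CLONE_A, CLONE_B, DisturbanceEvent, PerfusionPlant,
                    apply_disturbance)
from .swgp import forecast, retrain_online, train_ensemble

__all__ = ["AgentConfig", "LoopLog", "run_closed_loop", "run_benchmark",
           "use_case"]


@dataclass
class AgentConfig:
    """Closed-loop configuration for one campaign of reactors."""

    control_start_day: int = 9
    duration: int = 27
    horizon: int = 3
    retrain: bool = True
    objectives: dict = field(default_factory=dict)   # reactor id -> ObjectiveSpec
    search_spaces: dict = field(default_factory=dict)  # reactor id -> SearchSpace
    disturbances: list = field(default_factory=list)   # DisturbanceEvent with run_id
    limits: dict = field(default_factory=dict)         # variable -> (low, high)
    seed: int | None = None
    n_submodels: int = 20
    gp_options: dict = field(default_factory=dict)
    n_candidates: int = 64
    n_refine: int = 32

    def __post_init__(self):
        if self.control_start_day < 1:
            raise ValueError("control_start_day must be >= 1")
        if self.duration <= self.control_start_day:
            raise ValueError("duration must exceed control_start_day")


@dataclass
class LoopLog:
    """Append-only record of everything the agent observed and did."""

    entries: list = field(default_factory=list)

    def append(self, day, reactor, kind, **data):
        self.entries.append({"day": day, "reactor": reactor, "kind": kind,
                             **data})

    def to_frame(self):
        return pd.DataFrame(self.entries)

    def of_kind(self, kind):
        return [e for e in self.entries if e["kind"] == kind]


def _observed_state(obs, clone):
    state = dict(obs)
    state["clone"] = clone
    return state


def run_closed_loop(plants, base_campaign, cfg, base_ensemble=None):
    """Operate reactors in closed loop; returns (RunRecords, LoopLog).

    ``plants`` maps reactor id -> PerfusionPlant.  One shared ensemble is
    retrained each day on the base campaign plus the live data of all
    reactors; objectives differ per reactor only in the optimizer call.  If
    the optimizer fails, the previous setpoints are held (fail-safe) and an
    alarm is logged.
    """
    log = LoopLog()
    ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else 0)
    ens_seed, opt_seed0 = [int(s.generate_state(1)[0] % (2**31))
                           for s in ss.spawn(2)]
    ensemble = base_ensemble
    if ensemble is None:
        ensemble = train_ensemble(base_campaign, seed=ens_seed,
                                  n_submodels=cfg.n_submodels,
                                  **cfg.gp_options)
    base_for_retrain = base_campaign
    media = plants[next(iter(plants))].media
    current_sp = {rid: None for rid in plants}

    for day in range(cfg.duration):
        observations = {}
        for rid, plant in plants.items():
            obs = plant.sample()
            observations[rid] = obs
            log.append(day, rid, "sample",
                       vcv=compute_vcv(obs["Diam"], obs["VCD"]),
                       **{k: obs[k] for k in ("VCD", "Via", "Glc", "Amm")})
        for ev in cfg.disturbances:
            if ev.day == day and ev.run_id in plants:
                apply_disturbance(plants[ev.run_id], ev)
                log.append(day, ev.run_id, "disturbance", species=ev.species,
                           amount=ev.amount)

        controlled = day >= cfg.control_start_day
        if controlled and cfg.retrain:
            live = [plants[rid].to_run_record(f"live-{rid}")
                    for rid in plants]
            ensemble = retrain_online(base_for_retrain, live, seed=ens_seed,
                                      base_ensemble=ensemble,
                                      n_submodels=cfg.n_submodels,
                                      **cfg.gp_options)
            log.append(day, None, "retrain",
                       n_samples=ensemble.n_samples_)

        for rid, plant in plants.items():
            if controlled and rid in cfg.objectives:
                obj = cfg.objectives[rid]
                space = cfg.search_spaces.get(
                    rid, SearchSpace(bounds=dict(CONTROL_BOUNDS)))
                prev = current_sp[rid] or plant.protocol_setpoints()
                state = _observed_state(observations[rid], plant.params.name)
                try:
                    sp, ofv, diag = optimize_setpoints(
                        ensemble, state, space, obj, prev,
                        seed=(opt_seed0 + 1000 * day + hash(rid) % 997)
                        % (2**31),
                        n_candidates=cfg.n_candidates, n_refine=cfg.n_refine,
                        media=media,
                        bleed_ceiling=plant.config.bleed_ceiling)
                    log.append(day, rid, "optimize", ofv=ofv, **diag)
                except OptimizerError as exc:
                    sp = dict(prev)
                    log.append(day, rid, "alarm", message=str(exc))
                if cfg.limits:
                    fc = forecast(ensemble, state, sp, h=cfg.horizon,
                                  media=media, origin_day=day,
                                  bleed_ceiling=plant.config.bleed_ceiling)
                    for note in predict_violations(fc, cfg.limits):
                        log.append(day, rid, "notification",
                                   variable=note.variable,
                                   horizon_day=note.day,
                                   severity=note.severity, limit=note.limit,
                                   predicted_median=note.median,
                                   p10=note.p10, p90=note.p90)
            else:
                sp = plant.protocol_setpoints()
            current_sp[rid] = dict(sp)
            plant.advance_day(sp)
            log.append(day, rid, "setpoints", **sp)

    records = {}
    for rid, plant in plants.items():
        plant.sample()
        records[rid] = plant.to_run_record(rid)
    return records, log


def run_benchmark(plants, cfg):
    """Reference-protocol runs (no retraining, no optimization)."""
    bench_cfg = AgentConfig(control_start_day=cfg.control_start_day,
                            duration=cfg.duration, retrain=False,
                            objectives={}, seed=cfg.seed)
    records, log = run_closed_loop(plants, base_campaign=None,
                                   cfg=bench_cfg, base_ensemble=_NoEnsemble())
    return records, log


class _NoEnsemble:
    """Placeholder so benchmark runs never touch model code."""

    n_samples_ = 0


def use_case(number, seed=None, plant_config=None):
    """Plant + objective setup of the three standard control use cases.

    1: clone A, track 30 % VCV, all four controls active.
    2: clone B (absent from the base campaign), track 98 % viability,
       all four controls active.
    3: clone B, track 1.0 mM ammonium, pyruvate feed as the only control,
       with a manual ammonium spike on day 13.

    Returns ``(plants, cfg_kwargs)`` ready for :func:`run_closed_loop`.
    """
    bounds = dict(CONTROL_BOUNDS)
    if number == 1:
        params, obj = CLONE_A, ObjectiveSpec("VCV", "track", 30.0)
        active = ("VVD", "Temp", "Stir", "Pyr")
        disturbances = []
    elif number == 2:
        params, obj = CLONE_B, ObjectiveSpec("Via", "track", 98.0)
        active = ("VVD", "Temp", "Stir", "Pyr")
        disturbances = []
    elif number == 3:
        params, obj = CLONE_B, ObjectiveSpec("Amm", "track", 1.0)
        active = ("Pyr",)
        disturbances = [DisturbanceEvent(day=13, species="Amm", amount=2.5,
                                         run_id="uc3")]
    else:
        raise ValueError("use cases are numbered 1..3")
    rid = f"uc{number}"
    plant = PerfusionPlant(params=params, config=plant_config, seed=seed)
    cfg_kwargs = dict(
        objectives={rid: obj},
        search_spaces={rid: SearchSpace(bounds=bounds, active=active)},
        disturbances=disturbances,
    )
    return {rid: plant}, cfg_kwargs
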