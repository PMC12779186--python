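"""Daily setpoint optimization against the SW-GP forecast.

The objective tracks a target value of one (possibly derived) state variable
over the next three daily timesteps,

    OFV = (yhat_{t+1} - y_tar)^2 + (yhat_{t+2} - y_tar)^2 + (yhat_{t+3} - y_tar)^2

with yhat the ensemble-median forecast under candidate setpoints held
constant over the horizon.  Because the surrogate is cheap to evaluate, the
search is a seeded space-filling candidate sweep (Latin hypercube over the
active controls, the incumbent always included) followed by local refinement
around the best point; ties break toward the smallest change from the
current setpoints.  The returned setpoints are always within bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .swgp import forecast_batch, _protocol_step_fn

__all__ = ["ObjectiveSpec", "SearchSpace", "objective_value",
           "optimize_setpoints", "OptimizerError", "Notification",
           "predict_violations"]


@dataclass(frozen=True)
class ObjectiveSpec:
    """What a reactor's daily optimization aims for."""

    variable: str                 # modeled species or derived VCV
    mode: str = "track"           # track | maximize | minimize
    target: float | None = None   # y_tar, required for track mode
    horizon: int = 3

    def __post_init__(self):
        if self.mode not in ("track", "maximize", "minimize"):
            raise ValueError(f"unknown objective mode {self.mode!r}")
        if self.mode == "track" and self.target is None:
            raise ValueError("track mode requires a target value")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass(frozen=True)
class SearchSpace:
    """Per-control bounds and the subset of controls the optimizer may move."""

    bounds: dict                  # control -> (low, high)
    active: tuple = ()            # empty -> all bounded controls active

    def __post_init__(self):
        for ctrl, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bounds for {ctrl} inverted")
        object.__setattr__(self, "active",
                           tuple(self.active) or tuple(self.bounds))
        for ctrl in self.active:
            if ctrl not in self.bounds:
                raise ValueError(f"active control {ctrl} has no bounds")


class OptimizerError(RuntimeError):
    pass


def _median_trajectory(forecast_like, variable, h):
    med = forecast_like.median_of(variable)
    if len(med) < h:
        raise ValueError(f"forecast horizon {len(med)} < objective horizon {h}")
    return med[:h]


def objective_value(forecast, spec):
    """Objective function value of a forecast (lower is better)."""
    if spec.variable not in forecast.variables and spec.variable != "VCV":
        raise ValueError(f"variable {spec.variable!r} absent from forecast")
    y = _median_trajectory(forecast, spec.variable, spec.horizon)
    if spec.mode == "track":
        return float(np.sum((y - spec.target) ** 2))
    if spec.mode == "maximize":
        return float(np.sum(-y))
    return float(np.sum(y))


def _ofv_from_medians(y, spec):
    if spec.mode == "track":
        return np.sum((y - spec.target) ** 2, axis=-1)
    if spec.mode == "maximize":
        return np.sum(-y, axis=-1)
    return np.sum(y, axis=-1)


def _score_candidates(ensemble, state, cand, obj, media, bleed_ceiling):
    """OFV of each candidate setpoint vector (rows of ``cand``)."""
    mspec = ensemble.model_spec
    h = obj.horizon
    m = cand.shape[0]
    plans = np.repeat(cand[:, None, :], h, axis=1)
    fn = _protocol_step_fn(mspec, plans, state.get("V", 0.213), media,
                           bleed_ceiling=bleed_ceiling)
    trajs = forecast_batch(ensemble, [dict(state)] * m, plans, h, fn,
                           clone=state.get("clone"))
    if obj.variable == "VCV" and "VCV" not in mspec.modeled:
        from .datamodel import compute_vcv
        di = list(mspec.modeled).index("Diam")
        vi = list(mspec.modeled).index("VCD")
        var_traj = compute_vcv(trajs[:, :, :, di], trajs[:, :, :, vi])
    else:
        ki = list(mspec.modeled).index(obj.variable)
        var_traj = trajs[:, :, :, ki]
    med = np.percentile(var_traj, 50, axis=0)     # (m, h)
    return _ofv_from_medians(med, obj)


def optimize_setpoints(ensemble, state, space, objective, current_setpoints,
                       seed=None, n_candidates=64, n_refine=32,
                       refine_frac=0.25, media=None, bleed_ceiling=38.0):
    """Search the bounded control space for the setpoints minimizing the OFV.

    Inactive controls are held at their current values; the incumbent
    (current setpoints, clipped into bounds) is always a candidate, so the
    chosen point is never worse than the status quo under the model.

    Returns ``(setpoints, ofv, diagnostics)``.
    """
    mspec = ensemble.model_spec
    controls = list(mspec.setpoints)
    active = [c for c in space.active if c in controls]
    if not active:
        raise ValueError("search space has no active controls")
    rng = np.random.default_rng(seed)
    lo = np.array([space.bounds[c][0] for c in active])
    hi = np.array([space.bounds[c][1] for c in active])

    base = np.array([float(current_setpoints[c]) for c in controls])
    incumbent = base.copy()
    for ai, c in enumerate(active):
        ci = controls.index(c)
        incumbent[ci] = min(max(incumbent[ci], lo[ai]), hi[ai])

    def expand(active_mat):
        full = np.repeat(base[None, :], active_mat.shape[0], axis=0)
        for ai, c in enumerate(active):
            full[:, controls.index(c)] = active_mat[:, ai]
        return full

    n_lhs = max(n_candidates, 8)
    sampler = qmc.LatinHypercube(d=len(active), seed=rng)
    u = sampler.random(n_lhs)
    cand_active = lo + u * (hi - lo)
    inc_active = np.array([incumbent[controls.index(c)] for c in active])
    cand_active = np.vstack([inc_active, cand_active])
    media = media or {}

    cand = expand(cand_active)
    ofv = _score_candidates(ensemble, state, cand, objective, media,
                            bleed_ceiling)
    if not np.isfinite(ofv).any():
        raise OptimizerError(
            f"all {len(ofv)} candidates yielded non-finite objective values")

    # local refinement: successively shrunk boxes around the running optimum
    for frac in (refine_frac, refine_frac / 2.5):
        if n_refine <= 0:
            break
        best = int(np.nanargmin(ofv))
        width = (hi - lo) * frac / 2.0
        c0 = cand_active[best]
        r_lo = np.maximum(lo, c0 - width)
        r_hi = np.minimum(hi, c0 + width)
        u2 = qmc.LatinHypercube(d=len(active), seed=rng).random(n_refine)
        ref_active = r_lo + u2 * (r_hi - r_lo)
        ref = expand(ref_active)
        ofv2 = _score_candidates(ensemble, state, ref, objective, media,
                                 bleed_ceiling)
        cand_active = np.vstack([cand_active, ref_active])
        cand = np.vstack([cand, ref])
        ofv = np.concatenate([ofv, ofv2])

    finite = np.isfinite(ofv)
    ofv_min = np.nanmin(ofv[finite])
    scale = np.where(hi > lo, hi - lo, 1.0)
    dist = np.linalg.norm((cand_active - inc_active) / scale, axis=1)
    # near-ties (within 5% of the optimum) resolve toward the smallest
    # setpoint change, damping day-to-day actuation jitter
    span = np.nanmax(ofv[finite]) - ofv_min
    near = finite & (ofv <= ofv_min + 0.05 * abs(ofv_min) + 1e-4 * span + 1e-12)
    winner = int(np.flatnonzero(near)[np.argmin(dist[near])])

    chosen = {c: float(np.clip(cand[winner, controls.index(c)],
                               space.bounds[c][0], space.bounds[c][1]))
              if c in active else float(base[controls.index(c)])
              for c in controls}
    diagnostics = {"n_evaluated": int(len(ofv)),
                   "ofv_incumbent": float(ofv[0]),
                   "ofv_best": float(ofv[winner])}
    return chosen, float(ofv[winner]), diagnostics


# ---------------------------------------------------------------------------
# predictive notifications

@dataclass(frozen=True)
class Notification:
    """A predicted constraint violation at one horizon day."""

    variable: str
    day: int                      # absolute process day of the violation
    severity: str                 # "warning" (band edge) or "alarm" (median)
    bound: str                    # "low" or "high"
    limit: float
    median: float
    p10: float
    p90: float


def predict_violations(forecast, limits):
    """Notifications for every (variable, horizon day) whose 10-90 band
    crosses a limit; an alarm when the median itself crosses."""
    notes = []
    med, lo, hi = forecast.median, forecast.lower, forecast.upper
    for var, (low, high) in limits.items():
        if var not in forecast.variables:
            continue
        for day in forecast.days:
            m, l, u = med.loc[day, var], lo.loc[day, var], hi.loc[day, var]
            for bound, limit in (("low", low), ("high", high)):
                if limit is None:
                    continue
                crossed_band = l < limit if bound == "low" else u > limit
                crossed_med = m < limit if bound == "low" else m > limit
                if crossed_med:
                    sev = "alarm"
                elif crossed_band:
                    sev = "warning"
                else:
                    continue
                notes.append(Notification(var, int(day), sev, bound,
                                          float(limit), float(m), float(l),
                                          float(u)))
    return notes
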