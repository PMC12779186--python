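"""Forecast-quality metrics for the SW-GP ensemble.

The headline metric is the relative root-mean-squared error (rRMSE) of
h-day-ahead forecasts over a whole run,

    rRMSE_x = (1/sigma_x) * sqrt( sum_t sum_j (xhat_{t+j,t} - x_{t+j})^2 / n_p )

where the outer sum runs over forecast origin days t = 0..t_f-1, the inner
over horizon steps j = 1..min(h, t_f - t), xhat is the ensemble-median
prediction, sigma_x the pooled standard deviation of the variable over the
evaluation campaign, and n_p the number of (t, j) pairs.  For h <= t_f that
count has the closed form h*t_f - h(h-1)/2; the enumeration definition is
authoritative in the degenerate corner h > t_f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Campaign
from .swgp import (_recorded_step_fn, forecast_batch, retrain_online,
                   spec_for_campaign, train_ensemble)

__all__ = ["n_points", "rrmse", "campaign_sigmas", "run_forecast_medians",
           "ErrorReport", "loo_validate", "retraining_comparison"]


def n_points(h, t_f):
    """Number of (origin, horizon-step) prediction pairs in a run.

    Equals the brute-force count of pairs (t, j) with t in 0..t_f-1 and
    1 <= j <= min(h, t_f - t).
    """
    if h < 1 or t_f < 1:
        raise ValueError("h and t_f must be >= 1")
    if h <= t_f:
        return h * t_f - h * (h - 1) // 2
    return t_f * (t_f + 1) // 2


def campaign_sigmas(campaign, variables):
    """Pooled per-variable standard deviation over all campaign observations."""
    obs = pd.concat([run.states[list(variables)] for run in campaign])
    return obs.std(ddof=0)


def run_forecast_medians(ensemble, run, h=3):
    """Ensemble-median forecasts from every origin day of one run.

    Uses the run's recorded setpoints and flows (hindsight evaluation mode).
    Returns an array (t_f, h, n_variables) with NaN beyond the run end.
    """
    spec = ensemble.model_spec
    t_f = run.duration
    s = run.states
    origins = list(range(t_f))
    states = s.iloc[:-1].copy()
    states["clone"] = run.clone
    zero_flow = pd.DataFrame(0.0, index=range(h), columns=run.flows.columns)
    frames, vols = [], []
    for t in origins:
        rows = [run.flows.loc[t + j] if t + j < t_f else zero_flow.iloc[0]
                for j in range(h)]
        fr = pd.DataFrame(rows).reset_index(drop=True)
        frames.append(fr)
        v = np.empty(h)
        v[0] = s["V"].loc[t]
        for j in range(1, h):
            v[j] = v[j - 1] + fr["dVdt"].iloc[j - 1] if "dVdt" in fr else v[j - 1]
        vols.append(v)
    plans = np.stack([
        s[list(spec.setpoints)].to_numpy(dtype=float)[
            np.minimum(np.arange(t, t + h), t_f - 1)]
        for t in origins])
    fn = _recorded_step_fn(spec, frames, vols)
    trajs = forecast_batch(ensemble, states, plans, h, fn)
    med = np.percentile(trajs, 50, axis=0)          # (m, h, k)
    for ti, t in enumerate(origins):
        for j in range(h):
            if t + j + 1 > t_f:
                med[ti, j, :] = np.nan
    return med


def rrmse(run, medians, sigmas, h=3, variables=None):
    """Per-variable rRMSE of a run given median forecasts from every origin.

    ``medians`` is the (t_f, h, k) array of :func:`run_forecast_medians` (or a
    mapping origin_day -> Forecast, from which medians are taken).  Variables
    with zero sigma are reported as NaN with a warning.
    """
    spec_vars = variables
    if isinstance(medians, dict):
        any_fc = next(iter(medians.values()))
        spec_vars = spec_vars or list(any_fc.variables)
        t_f = run.duration
        arr = np.full((t_f, h, len(spec_vars)), np.nan)
        for t, fc in medians.items():
            med = fc.median
            for j in range(min(h, fc.horizon)):
                day = t + j + 1
                if day <= t_f:
                    arr[t, j, :] = med.loc[day, spec_vars].to_numpy()
        medians = arr
    t_f, hh, k = medians.shape
    spec_vars = spec_vars or list(sigmas.index[:k])
    obs = run.states[spec_vars]
    sq = np.zeros(k)
    n_used = 0
    for t in range(t_f):
        for j in range(hh):
            day = t + j + 1
            if day <= t_f and np.isfinite(medians[t, j, :]).all():
                resid = medians[t, j, :] - obs.loc[day].to_numpy()
                sq += resid ** 2
                n_used += 1
    np_count = n_points(hh, t_f)
    out = {}
    for ki, var in enumerate(spec_vars):
        sigma = float(sigmas[var])
        if sigma <= 0:
            warnings.warn(f"sigma of {var} is zero; rRMSE undefined")
            out[var] = np.nan
        else:
            out[var] = float(np.sqrt(sq[ki] / np_count) / sigma)
    return pd.Series(out)


@dataclass
class ErrorReport:
    """Leave-one-run-out validation summary."""

    per_run: pd.DataFrame          # rows: run_id, cols: variable
    average: pd.Series             # run-averaged rRMSE per variable
    sigmas: pd.Series

    def to_frame(self):
        tidy = self.per_run.reset_index().melt(
            id_vars="run_id", var_name="variable", value_name="rRMSE")
        return tidy


def loo_validate(campaign, h=3, seed=None, n_submodels=20, **gp_kw):
    """Leave-one-run-out validation of the SW-GP ensemble.

    For each run, an ensemble is trained on the remaining runs and forecasts
    are issued from every day with the held-out run's recorded setpoints and
    flows; rRMSE is computed per variable.
    """
    if len(campaign) < 3:
        raise ValueError("leave-one-out validation needs >= 3 runs")
    spec = spec_for_campaign(campaign)
    sigmas = campaign_sigmas(campaign, spec.modeled)
    rows = {}
    for held in campaign.runs:
        rest = Campaign([r for r in campaign.runs if r.run_id != held.run_id],
                        bounds=campaign.bounds)
        ens = train_ensemble(rest, model_spec=spec, n_submodels=n_submodels,
                             seed=seed, **gp_kw)
        med = run_forecast_medians(ens, held, h=h)
        rows[held.run_id] = rrmse(held, med, sigmas, h=h,
                                  variables=list(spec.modeled))
    per_run = pd.DataFrame(rows).T
    per_run.index.name = "run_id"
    return ErrorReport(per_run=per_run, average=per_run.mean(axis=0),
                       sigmas=sigmas)


def _per_day_rrmse(runs, medians_map, sigmas, h, variables, t_max):
    """Per-origin-day rRMSE averaged over runs (full-horizon origins only)."""
    rows = []
    for t in range(t_max + 1):
        sq = np.zeros(len(variables))
        n = 0
        for run in runs:
            med = medians_map[run.run_id]
            obs = run.states[variables]
            for j in range(h):
                day = t + j + 1
                if day <= run.duration and np.isfinite(med[t, j]).all():
                    sq += (med[t, j, :] - obs.loc[day].to_numpy()) ** 2
                    n += 1
        vals = np.sqrt(sq / max(n, 1)) / sigmas[variables].to_numpy()
        rows.append(pd.Series(vals, index=variables, name=t))
    out = pd.DataFrame(rows)
    out.index.name = "day"
    return out


def retraining_comparison(base_campaign, eval_campaign, h=3, seed=None,
                          n_submodels=20, **gp_kw):
    """Daily forecast error on new-clone runs, with and without retraining.

    The "without" model is trained once on the base campaign (the known
    clone).  The "with" model is retrained each day on the base campaign plus
    all evaluation-run data observed up to that day.  For each origin day t
    (up to t_f - h, so every origin contributes a full horizon) the h-day
    prediction error is averaged over all evaluation runs.

    Returns a DataFrame indexed by day with MultiIndex columns
    (variable, 'with'|'without').
    """
    spec = spec_for_campaign(
        Campaign(list(base_campaign.runs) + list(eval_campaign.runs)))
    variables = list(spec.modeled)
    sigmas = campaign_sigmas(eval_campaign, variables)
    t_f = min(r.duration for r in eval_campaign)
    t_max = t_f - h

    ens_without = train_ensemble(base_campaign, model_spec=spec,
                                 n_submodels=n_submodels, seed=seed, **gp_kw)
    med_without = {r.run_id: run_forecast_medians(ens_without, r, h=h)
                   for r in eval_campaign}

    med_with = {r.run_id: np.full_like(med_without[r.run_id], np.nan)
                for r in eval_campaign}
    prev = ens_without
    for t in range(t_max + 1):
        if t == 0:
            ens_t = ens_without          # no live data yet: identical models
        else:
            live = [r.truncated(t) for r in eval_campaign]
            ens_t = retrain_online(base_campaign, live, seed=seed,
                                   base_ensemble=prev, model_spec=spec,
                                   n_submodels=n_submodels, **gp_kw)
            prev = ens_t
        for r in eval_campaign:
            med_t = _origin_medians(ens_t, r, t, h)
            med_with[r.run_id][t, :, :] = med_t

    w = _per_day_rrmse(list(eval_campaign), med_with, sigmas, h, variables, t_max)
    wo = _per_day_rrmse(list(eval_campaign), med_without, sigmas, h, variables,
                        t_max)
    out = pd.concat({"with": w, "without": wo}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1)


def _origin_medians(ensemble, run, t, h):
    """Median h-day forecast of one run from a single origin day."""
    spec = ensemble.model_spec
    s = run.states
    state = s.loc[t].to_dict()
    state["clone"] = run.clone
    rows = [run.flows.loc[t + j] for j in range(h)]
    fr = pd.DataFrame(rows).reset_index(drop=True)
    v = np.empty(h)
    v[0] = s["V"].loc[t]
    for j in range(1, h):
        v[j] = v[j - 1] + (fr["dVdt"].iloc[j - 1] if "dVdt" in fr else 0.0)
    plans = s[list(spec.setpoints)].to_numpy(dtype=float)[
        np.minimum(np.arange(t, t + h), run.duration - 1)][None]
    fn = _recorded_step_fn(spec, [fr], [v])
    trajs = forecast_batch(ensemble, [state], plans, h, fn)
    return np.percentile(trajs[:, 0], 50, axis=0)
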