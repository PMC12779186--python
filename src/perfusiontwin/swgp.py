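"""Step-wise Gaussian-process (SW-GP) hybrid model.

The hybrid model couples discretized reactor mass balances with GP regression:
for each daily interval the *discrete production rate* of every species is
recovered from the data by rearranging the balance

    R(s(t_i)) = (c(t_{i+1}) - c(t_i)) / dt  -  (u_f - u_b - u_p - c dV/dt) / V

(all right-hand quantities evaluated at t_i; permeate u_p is zero for
membrane-retained species, and viability/diameter are carried as plain daily
increments with no flow terms).  A GP learns R as a function of the process
state s (concentrations, viability, diameter, setpoints, clone encoding), and
forecasts are produced by rolling the balance forward one day at a time with
GP-predicted rates.

Robustness against batch-to-batch variation and outliers comes from an
ensemble of ``n_submodels`` (default 20) GPs: the training data is split into
20 subsets and each submodel is trained on 19 of them.  Each submodel is
rolled forward independently so the ensemble yields coherent trajectory
bundles; the 10th/50th/90th percentiles across submodels give the median
forecast and an 80 % interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.utils.validation import check_is_fitted

from .datamodel import (Campaign, compute_vcv, FEDBATCH_SPEC,
                        PERFUSION_SPEC, GLC_BOLUS_TARGET, GLC_BOLUS_TRIGGER)

__all__ = [
    "extract_rates", "build_training_data", "StepwiseGPEnsemble", "Forecast",
    "train_ensemble", "retrain_online", "forecast", "forecast_batch",
    "spec_for_campaign", "save_ensemble", "load_ensemble",
]


# ---------------------------------------------------------------------------
# rate extraction (the mechanistic half of the hybrid)

def _flow_terms(flow_row, c_now, V, spec):
    """Per-species flow correction (u_f - u_b - u_p - c dV/dt)/V at one step."""
    out = {}
    dvdt = flow_row.get("dVdt", 0.0)
    for sp in spec.species:
        uf = flow_row.get(f"feed_{sp}", 0.0)
        ub = flow_row.get(f"bleed_{sp}", 0.0)
        up = 0.0 if sp in spec.retained else flow_row.get(f"perm_{sp}", 0.0)
        out[sp] = (uf - ub - up - c_now[sp] * dvdt) / V
    return out


def extract_rates(run, spec=None):
    """Discrete production rates for every day interval of a run.

    Returns ``(X, Y)`` DataFrames indexed by ``(run_id, day)``: ``X`` holds the
    GP inputs (modeled states at t_i, the interval's setpoints, clone one-hot)
    and ``Y`` the rates per modeled variable (species-unit/L/d, or per-day
    increments for the intensive variables).
    """
    spec = spec or (FEDBATCH_SPEC if run.mode == "fed-batch" else PERFUSION_SPEC)
    cache = run.__dict__.setdefault("_rate_cache", {})
    if spec in cache:                # runs are immutable once recorded
        return cache[spec]
    s = run.states
    if len(s) < 2:
        raise ValueError(f"run {run.run_id}: need >= 2 daily states")
    days = s.index[:-1]
    missing = set(days) - set(run.flows.index)
    if missing:
        raise ValueError(
            f"run {run.run_id}: missing flow row for interval starting day "
            f"{sorted(missing)[0]}")
    x_rows, y_rows = [], []
    for d in days:
        now, nxt = s.loc[d], s.loc[d + 1]
        ft = _flow_terms(run.flows.loc[d], now, now["V"], spec)
        x = {v: now[v] for v in spec.modeled}
        x.update({sp: now[sp] for sp in spec.setpoints})
        for c in spec.clones:
            x[f"clone_{c}"] = 1.0 if run.clone == c else 0.0
        y = {sp: (nxt[sp] - now[sp]) - ft[sp] for sp in spec.species}
        y.update({v: nxt[v] - now[v] for v in spec.intensive})
        x_rows.append(x)
        y_rows.append(y)
    idx = pd.MultiIndex.from_product([[run.run_id], days], names=["run_id", "day"])
    X = pd.DataFrame(x_rows, index=idx)[spec.feature_names()]
    Y = pd.DataFrame(y_rows, index=idx)[list(spec.modeled)]
    if not np.isfinite(X.to_numpy()).all() or not np.isfinite(Y.to_numpy()).all():
        raise ValueError(f"run {run.run_id}: non-finite rate sample")
    cache[spec] = (X, Y)
    return X, Y


def step_state(state, rates, flow_row, spec, via_cap=True):
    """One forward step of the discretized balance (inverse of extract_rates)."""
    nxt = dict(state)
    ft = _flow_terms(flow_row, state, state["V"], spec)
    for sp in spec.species:
        nxt[sp] = state[sp] + rates[sp] + ft[sp]
    for v in spec.intensive:
        nxt[v] = state[v] + rates[v]
    nxt["V"] = state["V"] + flow_row.get("dVdt", 0.0)
    for k in spec.modeled:
        nxt[k] = max(0.0, nxt[k])
    if via_cap and "Via" in nxt:
        nxt["Via"] = min(100.0, nxt["Via"])
    return nxt


def spec_for_campaign(campaign, base_spec=None):
    """Model spec for a campaign, extending the clone set if needed."""
    spec = base_spec or (FEDBATCH_SPEC if campaign.runs[0].mode == "fed-batch"
                         else PERFUSION_SPEC)
    clones = tuple(spec.clones) + tuple(
        c for c in campaign.clones if c not in spec.clones)
    if clones != spec.clones:
        from dataclasses import replace
        spec = replace(spec, clones=clones)
    return spec


def build_training_data(campaign, spec=None):
    """Stack rate samples of all runs; returns (X, Y, groups=run_ids)."""
    spec = spec or spec_for_campaign(campaign)
    xs, ys = zip(*(extract_rates(run, spec) for run in campaign))
    X = pd.concat(xs)
    Y = pd.concat(ys)
    groups = X.index.get_level_values("run_id").to_numpy()
    return X, Y, groups


# ---------------------------------------------------------------------------
# ensemble estimator

def _capped_lbfgs(maxiter):
    def _opt(obj_func, initial_theta, bounds):
        res = minimize(obj_func, initial_theta, method="L-BFGS-B", jac=True,
                       bounds=bounds, options={"maxiter": maxiter})
        return res.x, res.fun
    return _opt


class StepwiseGPEnsemble(BaseEstimator, RegressorMixin):
    """Ensemble of GP regressors mapping process state to production rates.

    The training data is partitioned into ``n_submodels`` subsets — at run
    level when at least ``n_submodels`` runs are available (preserving
    within-run correlation), else at sample level — and submodel *i* is
    trained on all subsets but the *i*-th.  Each output gets an independent
    GP with an anisotropic squared-exponential kernel plus an additive
    observation-noise term; hyperparameters are set by marginal-likelihood
    maximization (multi-start L-BFGS on a seeded subsample of at most
    ``hyper_subsample`` points).

    With ``share_hyperparameters=True`` (default) the kernel hyperparameters
    are fitted once per output and shared by all submodels, which then differ
    only in their training subsets; this keeps daily retraining and
    leave-one-out studies tractable while retaining the subset-resampling
    variability the ensemble is built to express.  Set it to False for fully
    independent per-submodel marginal-likelihood fits.

    Constant input columns (for instance the one-hot indicator of a clone not
    present in the training data) are dropped from the kernel's active
    dimensions with a warning.
    """

    def __init__(self, model_spec=PERFUSION_SPEC, n_submodels=20,
                 n_restarts=1, hyper_subsample=192, hyper_maxiter=35,
                 share_hyperparameters=True, noise_floor=1e-8,
                 length_scale_floor=1.0, random_state=None):
        self.model_spec = model_spec
        self.n_submodels = n_submodels
        self.n_restarts = n_restarts
        self.hyper_subsample = hyper_subsample
        self.hyper_maxiter = hyper_maxiter
        self.share_hyperparameters = share_hyperparameters
        self.noise_floor = noise_floor
        self.length_scale_floor = length_scale_floor
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _partition(self, n, groups, rng):
        assign = np.empty(n, dtype=int)
        if groups is not None:
            uniq = pd.unique(groups)
            if len(uniq) >= self.n_submodels:
                order = rng.permutation(len(uniq))
                sub_of_group = {uniq[g]: i % self.n_submodels
                                for i, g in enumerate(order)}
                for i, g in enumerate(groups):
                    assign[i] = sub_of_group[g]
                return assign
        perm = rng.permutation(n)
        for rank, idx in enumerate(perm):
            assign[idx] = rank % self.n_submodels
        return assign

    def _base_kernel(self, active_features):
        # the length-scale floor (standardized units) keeps the fit smooth
        # between the discrete levels of designed factors, where a collapsed
        # length-scale would otherwise revert interpolated setpoints to the
        # prior mean; clone indicator dimensions stay on their raw 0/1 scale
        # and may take shorter length-scales to express clone differences
        bounds = np.array([(0.3, 1e2) if f.startswith("clone_")
                           else (self.length_scale_floor, 1e2)
                           for f in active_features])
        return (ConstantKernel(1.0, (1e-3, 1e3))
                * RBF(np.ones(len(active_features)), bounds)
                + WhiteKernel(1e-2, (self.noise_floor, 1e1)))

    def fit(self, X, y, groups=None, hyper_kernels=None):
        """Fit the ensemble.

        ``X``/``y`` are DataFrames as produced by :func:`build_training_data`
        (plain arrays are accepted; columns are then taken from the model
        spec).  ``groups`` (run ids) controls run-level subset assignment.
        ``hyper_kernels`` may carry the fitted kernels of a previous ensemble
        with the same active feature set to skip hyperparameter optimization
        (online-retraining fast path).
        """
        spec = self.model_spec
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            self.feature_names_in_ = spec.feature_names()
            Xa = np.asarray(X, dtype=float)
        if isinstance(y, pd.DataFrame):
            self.output_names_ = list(y.columns)
            Ya = y.to_numpy(dtype=float)
        else:
            self.output_names_ = list(spec.modeled)
            Ya = np.asarray(y, dtype=float)
        if Ya.ndim == 1:
            Ya = Ya[:, None]
            self.output_names_ = self.output_names_[:1]
        n, d = Xa.shape
        if self.n_submodels < 2:
            raise ValueError("n_submodels must be >= 2")
        if n < self.n_submodels:
            raise ValueError(
                f"need at least n_submodels={self.n_submodels} samples, got {n}")
        if not np.isfinite(Xa).all() or not np.isfinite(Ya).all():
            raise ValueError("non-finite training data")

        std = Xa.std(axis=0)
        active = std > 1e-10
        if not active.all():
            dropped = [f for f, a in zip(self.feature_names_in_, active) if not a]
            warnings.warn(
                f"constant input columns dropped from kernel: {dropped}",
                UserWarning, stacklevel=2)
        self.active_mask_ = active
        self.active_features_ = [f for f, a in
                                 zip(self.feature_names_in_, active) if a]
        self.x_mean_ = Xa[:, active].mean(axis=0)
        self.x_scale_ = np.where(std[active] > 0, std[active], 1.0)
        # clone one-hot columns keep their raw 0/1 coding: standardizing a
        # rare indicator would push the minority clone several sigma away
        # from all other data and sever cross-clone transfer
        for i, f in enumerate(self.active_features_):
            if f.startswith("clone_"):
                self.x_mean_[i], self.x_scale_[i] = 0.0, 1.0
        Xs = (Xa[:, active] - self.x_mean_) / self.x_scale_

        rng = np.random.default_rng(self.random_state)
        self.subset_of_ = self._partition(n, groups, rng)

        reuse = None
        if (hyper_kernels is not None
                and hyper_kernels.get("features") == self.active_features_):
            reuse = hyper_kernels["kernels"]
        self.hyper_kernels_ = {"features": list(self.active_features_),
                               "kernels": []}
        opt = _capped_lbfgs(self.hyper_maxiter)

        if self.share_hyperparameters:
            kernels = []
            for k_out in range(Ya.shape[1]):
                if reuse is not None:
                    kernels.append(reuse[k_out])
                    continue
                sub = rng.permutation(n)[:self.hyper_subsample]
                gp = GaussianProcessRegressor(
                    kernel=self._base_kernel(self.active_features_),
                    normalize_y=True, optimizer=opt,
                    n_restarts_optimizer=self.n_restarts,
                    random_state=int(rng.integers(2**31)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gp.fit(Xs[sub], Ya[sub, k_out])
                kernels.append(gp.kernel_)
            self.hyper_kernels_["kernels"] = kernels

        self.submodels_ = []
        for i in range(self.n_submodels):
            mask = self.subset_of_ != i
            gps = []
            for k_out in range(Ya.shape[1]):
                if self.share_hyperparameters:
                    gp = GaussianProcessRegressor(
                        kernel=self.hyper_kernels_["kernels"][k_out],
                        optimizer=None, normalize_y=True)
                else:
                    gp = GaussianProcessRegressor(
                        kernel=self._base_kernel(self.active_features_),
                        normalize_y=True, optimizer=opt,
                        n_restarts_optimizer=self.n_restarts,
                        random_state=int(rng.integers(2**31)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gp.fit(Xs[mask], Ya[mask, k_out])
                gps.append(gp)
            self.submodels_.append(gps)
        if not self.share_hyperparameters:
            self.hyper_kernels_["kernels"] = [gp.kernel_
                                              for gp in self.submodels_[0]]
        # out-of-subset residual scale per output: each submodel scored on
        # its held-out subset.  Marginal likelihood underestimates the noise
        # of smooth high-dimensional fits, so this empirical scale floors the
        # predictive std used for interval construction.
        sq = np.zeros(Ya.shape[1])
        cnt = 0
        for i in range(self.n_submodels):
            mask = self.subset_of_ == i
            if not mask.any():
                continue
            pred = self._predict_submodel(i, Xs[mask])
            sq += ((pred - Ya[mask]) ** 2).sum(axis=0)
            cnt += int(mask.sum())
        self.oos_residual_std_ = np.sqrt(sq / max(cnt, 1))
        self.n_features_in_ = d
        self.n_samples_ = n
        return self

    # -- prediction --------------------------------------------------------

    def _to_matrix(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_in_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return (X[:, self.active_mask_] - self.x_mean_) / self.x_scale_

    def _predict_submodel(self, i, Xs, return_std=False):
        """Rates from submodel i for pre-standardized inputs (m, d_active)."""
        if not return_std:
            return np.column_stack([gp.predict(Xs)
                                    for gp in self.submodels_[i]])
        out = [gp.predict(Xs, return_std=True) for gp in self.submodels_[i]]
        return (np.column_stack([m for m, _ in out]),
                np.column_stack([sd for _, sd in out]))

    def predict_ensemble(self, X):
        """All submodel predictions, shape (n_submodels, m, n_outputs)."""
        check_is_fitted(self, "submodels_")
        Xs = self._to_matrix(X)
        return np.stack([self._predict_submodel(i, Xs)
                         for i in range(self.n_submodels)])

    def predict(self, X):
        """Ensemble median rate prediction, shape (m, n_outputs)."""
        return np.percentile(self.predict_ensemble(X), 50, axis=0)

    def predict_quantiles(self, X, q=(10, 50, 90)):
        return np.percentile(self.predict_ensemble(X), q, axis=0)


# ---------------------------------------------------------------------------
# forecasting

@dataclass
class Forecast:
    """Multi-day stepwise forecast with ensemble percentile bands.

    ``trajectories`` has shape (n_submodels, horizon, n_variables); day j of
    the horizon corresponds to process day ``origin_day + j + 1``.
    """

    origin_day: int
    horizon: int
    variables: tuple
    trajectories: np.ndarray
    setpoint_plan: pd.DataFrame | None = None
    clone: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trajectories = np.asarray(self.trajectories, dtype=float)
        if self.trajectories.ndim != 3:
            raise ValueError("trajectories must be (n_submodels, h, k)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    @property
    def days(self):
        return np.arange(self.origin_day + 1, self.origin_day + self.horizon + 1)

    def quantile(self, q):
        vals = np.percentile(self.trajectories, q, axis=0)
        return pd.DataFrame(vals, index=self.days, columns=list(self.variables))

    @property
    def median(self):
        return self.quantile(50)

    @property
    def lower(self):
        return self.quantile(10)

    @property
    def upper(self):
        return self.quantile(90)

    def variable(self, name):
        """Per-submodel trajectories of one (possibly derived) variable."""
        if name == "VCV" and "VCV" not in self.variables:
            d = self.trajectories[:, :, self.variables.index("Diam")]
            v = self.trajectories[:, :, self.variables.index("VCD")]
            return compute_vcv(d, v)
        return self.trajectories[:, :, self.variables.index(name)]

    def median_of(self, name):
        return np.percentile(self.variable(name), 50, axis=0)

    def band_of(self, name, q=(10, 90)):
        return np.percentile(self.variable(name), q, axis=0)

    def to_frame(self, run_id=None):
        """Tidy export: one row per (horizon day, variable)."""
        rows = []
        med, lo, hi = self.median, self.lower, self.upper
        for day in self.days:
            for var in self.variables:
                rows.append({"run_id": run_id, "origin_day": self.origin_day,
                             "horizon_day": int(day), "species": var,
                             "median": med.loc[day, var],
                             "p10": lo.loc[day, var], "p90": hi.loc[day, var]})
        return pd.DataFrame(rows)


def _protocol_step_fn(spec, plans, volume, media, bleed_ceiling=38.0):
    """One-day state update under perfusion-protocol flows.

    Solubles are exchanged against fresh media at the planned rate D = VVD
    with the exact one-day integrator of the linear exchange dynamics,

        c(t+1) = c(t) + R (1 - e^-D)/D + (media - c(t)) (1 - e^-D),

    which is consistent with rates extracted from integrated (recorded)
    flows: when R equals the true mean production rate the step is exact.
    Membrane-retained species see no exchange.  The glucose bolus rule tops
    the predicted glucose up to its target when it falls below the trigger,
    and a bleed correction caps predicted VCV at the ceiling.
    """
    i_vvd = list(spec.setpoints).index("VVD")
    sol = [sp for sp in spec.species if sp not in spec.retained]
    idx = {v: k for k, v in enumerate(spec.modeled)}

    def fn(j, state, rates):
        state = state.copy()
        glc = state[:, idx["Glc"]]
        low = glc < GLC_BOLUS_TRIGGER
        state[low, idx["Glc"]] = GLC_BOLUS_TARGET
        d = np.maximum(plans[:, j, i_vvd], 0.0)
        decay = -np.expm1(-d)                       # 1 - e^-D
        phi1 = np.where(d > 1e-12, decay / np.where(d > 1e-12, d, 1.0), 1.0)
        nxt = state + rates                         # retained & intensive
        for sp in sol:
            k = idx[sp]
            nxt[:, k] = (state[:, k] + rates[:, k] * phi1
                         + (media.get(sp, 0.0) - state[:, k]) * decay)
        if "Diam" in idx and bleed_ceiling is not None:
            vcv = compute_vcv(np.maximum(nxt[:, idx["Diam"]], 0.0),
                              np.maximum(nxt[:, idx["VCD"]], 0.0))
            over = vcv > bleed_ceiling
            if over.any():
                f = bleed_ceiling / vcv[over]
                for sp in spec.retained:
                    nxt[over, idx[sp]] *= f
        return nxt

    return fn


def _recorded_step_fn(spec, flow_frames, volumes):
    """One-day update using recorded flow rows (hindsight evaluation mode)."""
    idx = {v: k for k, v in enumerate(spec.modeled)}

    def fn(j, state, rates):
        m = state.shape[0]
        nxt = state + rates
        for r in range(m):
            row = flow_frames[r].iloc[j]
            terms = _flow_terms(
                row, {sp: state[r, idx[sp]] for sp in spec.species},
                volumes[r][j], spec)
            for sp in spec.species:
                nxt[r, idx[sp]] += terms[sp]
        return nxt

    return fn


def forecast_batch(ensemble, states, plans, h, step_fn, origin_days=None,
                   clone=None, sample_rates=False, rng=None):
    """Roll every submodel forward ``h`` daily steps for a batch of scenarios.

    ``states``: list/frame of m initial states (modeled variables + clone);
    ``plans``: array (m, h, n_setpoints); ``step_fn(j, state_matrix, rates)``
    applies the discretized balance with the planned or recorded flows for
    horizon step j.  Returns an array of shape (n_submodels, m, h, k);
    concentrations are clipped at zero and viability at 100 after every step.

    With ``sample_rates=True`` each submodel's rates are drawn (seeded via
    ``rng``) from its GP predictive distribution instead of using the mean,
    so the trajectory bundle expresses predictive uncertainty on top of the
    subset-resampling variability; use this for interval construction.  The
    mean-rate rollout is cheaper and is what median-based consumers (the
    optimizer, rRMSE evaluation) use.
    """
    rng = np.random.default_rng(rng)
    spec = ensemble.model_spec
    modeled = list(spec.modeled)
    k = len(modeled)
    if isinstance(states, pd.DataFrame):
        base = states[modeled].to_numpy(dtype=float)
        clones = states["clone"] if "clone" in states else None
    else:
        base = np.array([[s[v] for v in modeled] for s in states], dtype=float)
        clones = [s.get("clone", clone) for s in states]
    m = base.shape[0]
    if plans.shape[:2] != (m, h):
        raise ValueError(f"setpoint plan must cover {h} days for {m} scenarios")
    onehot = np.zeros((m, len(spec.clones)))
    for r in range(m):
        c = (clones[r] if clones is not None else clone)
        if c in spec.clones:
            onehot[r, spec.clones.index(c)] = 1.0
    i_via = modeled.index("Via") if "Via" in modeled else None

    out = np.empty((ensemble.n_submodels, m, h, k))
    feat_template = np.empty((m, len(ensemble.feature_names_in_)))
    for i in range(ensemble.n_submodels):
        state = base.copy()
        for j in range(h):
            feat_template[:, :k] = state
            feat_template[:, k:k + plans.shape[2]] = plans[:, j, :]
            feat_template[:, k + plans.shape[2]:] = onehot
            Xs = ((feat_template[:, ensemble.active_mask_] - ensemble.x_mean_)
                  / ensemble.x_scale_)
            if sample_rates:
                mean, std = ensemble._predict_submodel(i, Xs, return_std=True)
                floor = getattr(ensemble, "oos_residual_std_", None)
                if floor is not None:
                    std = np.maximum(std, floor)
                rates = mean + std * rng.standard_normal(mean.shape)
            else:
                rates = ensemble._predict_submodel(i, Xs)
            state = np.maximum(step_fn(j, state, rates), 0.0)
            if i_via is not None:
                state[:, i_via] = np.minimum(state[:, i_via], 100.0)
            out[i, :, j, :] = state
    return out


def forecast(ensemble, state, setpoint_plan, h=3, flows=None, media=None,
             volume=None, bleed_ceiling=38.0, origin_day=None, clone=None,
             sample_rates=True, rng=0):
    """Stepwise h-day forecast from one state under a setpoint plan.

    ``setpoint_plan`` is a DataFrame with h rows (or a dict, held constant).
    If ``flows`` (recorded flow rows, h of them) is given they are used as the
    known flow corrections; otherwise perfusion-protocol flows (media exchange
    at the planned VVD, glucose bolus rule, bleed cap) are derived from the
    predicted state at each step.  By default rates are sampled from each
    submodel's predictive distribution (seeded, deterministic) so that the
    10-90 band is a usable prediction interval; pass ``sample_rates=False``
    for the mean-rate rollout.
    """
    spec = ensemble.model_spec
    if isinstance(setpoint_plan, dict):
        setpoint_plan = pd.DataFrame([setpoint_plan] * h)
    if len(setpoint_plan) < h:
        raise ValueError(f"setpoint plan covers {len(setpoint_plan)} < h={h} days")
    plans = setpoint_plan[list(spec.setpoints)].to_numpy(dtype=float)[None, :h, :]
    V = volume if volume is not None else state.get("V", 0.213)
    if flows is not None:
        if len(flows) < h:
            raise ValueError("recorded flows must cover the horizon")
        vols = [V + np.r_[0.0, np.cumsum(flows["dVdt"].to_numpy())[:h - 1]]
                if "dVdt" in flows else np.full(h, V)]
        fn = _recorded_step_fn(spec, [flows.iloc[:h]], vols)
    else:
        fn = _protocol_step_fn(spec, plans, V, media or {},
                               bleed_ceiling=bleed_ceiling)
    clone = clone or state.get("clone")
    trajs = forecast_batch(ensemble, [dict(state)], plans, h, fn, clone=clone,
                           sample_rates=sample_rates, rng=rng)
    day = origin_day if origin_day is not None else int(state.get("day", 0))
    return Forecast(day, h, tuple(spec.modeled), trajs[:, 0],
                    setpoint_plan=setpoint_plan.iloc[:h], clone=clone)


# ---------------------------------------------------------------------------
# training entry points

def train_ensemble(campaign, model_spec=None, n_submodels=20, seed=None, **kw):
    """Fit a :class:`StepwiseGPEnsemble` on a campaign's rate samples."""
    spec = spec_for_campaign(campaign, model_spec)
    X, Y, groups = build_training_data(campaign, spec)
    est = StepwiseGPEnsemble(model_spec=spec, n_submodels=n_submodels,
                             random_state=seed, **kw)
    est.fit(X, Y, groups=groups)
    return est


def retrain_online(base_campaign, live_runs=(), seed=None, base_ensemble=None,
                   model_spec=None, n_submodels=20, **kw):
    """Fresh ensemble trained on the base campaign plus all live data so far.

    ``live_runs`` are (possibly partial) RunRecords of ongoing reactors; runs
    shorter than two sampling days contribute nothing yet.  The previous
    ensemble is never mutated (audit trail); when given, its fitted kernel
    hyperparameters are reused if the active feature set is unchanged,
    otherwise hyperparameters are re-optimized.
    """
    live = [r for r in live_runs if len(r.states) >= 2]
    combined = Campaign(list(base_campaign.runs) + live,
                        design_table=base_campaign.design_table,
                        bounds=base_campaign.bounds)
    spec = spec_for_campaign(combined, model_spec)
    X, Y, groups = build_training_data(combined, spec)
    est = StepwiseGPEnsemble(model_spec=spec, n_submodels=n_submodels,
                             random_state=seed, **kw)
    hk = getattr(base_ensemble, "hyper_kernels_", None) if base_ensemble else None
    est.fit(X, Y, groups=groups, hyper_kernels=hk)
    return est


def save_ensemble(path, ensemble):
    joblib.dump(ensemble, path)
    return path


def load_ensemble(path):
    return joblib.load(path)
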