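"""Mechanistic synthetic plant for perfusion and fed-batch CHO cultivations.

The plant stands in for a parallel mini-bioreactor system: it generates the
training campaign, the in-silico fed-batch clone datasets, and serves as the
closed-loop "hardware" for the control use cases.  Kinetics are Monod-type:
growth on glucose/glutamine with ammonium/lactate inhibition, temperature- and
shear-modulated death, glutamine starvation death, spontaneous glutamine
degradation, pyruvate-dependent attenuation of ammonium release, and a
lactate-consumption switch for the fed-batch clones.  Parameter values are the
package's own calibration (no published values exist for the system emulated);
they were fixed once against the qualitative anchors documented in
``docs/methods.md`` (steady VCV < 20 % at reference setpoints, ammonium
drifting to ~4 mM by day 9 without pyruvate, viability responses to mild
hypothermia and excess agitation).

Daily protocol events are applied at day boundaries in the order
sample -> disturbance -> setpoint update -> integrate.  Within a day the
state is advanced with a fixed-step classical Runge-Kutta scheme; cumulative
feed/permeate mass integrals ride along in the same RK4 vector so that the
recorded interval flows are consistent with the state trajectory to machine
precision (discrete events - glucose boluses, bleeds, disturbances, fed-batch
feeds - are booked algebraically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (Campaign, RunRecord, bolus_volume, compute_vcv,
                        flow_columns, GLC_BOLUS_STOCK, FEDBATCH_STATE_COLS,
                        PERFUSION_STATE_COLS)
from .config import DESIGN_BOUNDS

__all__ = [
    "KineticParams", "FedBatchParams", "PlantConfig", "DisturbanceEvent",
    "CLONE_A", "CLONE_B", "CLONE_X", "CLONE_Y",
    "REFERENCE_SETPOINTS", "PerfusionPlant",
    "simulate_perfusion_day", "generate_training_campaign",
    "simulate_fedbatch_run", "generate_fedbatch_campaign",
    "apply_disturbance", "sample_with_noise", "DEFAULT_NOISE_CVS",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class KineticParams:
    """Clone-specific kinetic parameters of the perfusion plant.

    Rates are per day; cell-specific rates are per (1e6 cells/mL) of VCD.
    """

    name: str = "A"
    mu_max: float = 1.1            # d^-1, maximum specific growth rate
    K_glc: float = 0.4             # g/L, glucose Monod constant
    K_gln: float = 0.3             # mM, glutamine Monod constant
    K_i_amm: float = 25.0          # mM, ammonium growth inhibition
    K_i_lac: float = 30.0          # g/L, lactate growth inhibition
    T_opt: float = 36.5            # degC, growth temperature optimum
    sigma_T: float = 3.5           # degC, width of the growth-temp response
    k_d0: float = 0.02             # d^-1, base death rate at 35.25 degC
    theta_d: float = 0.7           # per degC, death temperature sensitivity
    K_d_amm: float = 10.0          # mM, ammonium death scale (quadratic)
    k_shear: float = 0.08          # d^-1 at 350 rpm above the shear threshold
    stir_crit: float = 1050.0      # rpm, shear-damage threshold
    k_starv: float = 0.05          # d^-1, max glutamine-starvation death
    K_starv: float = 0.05          # mM
    k_lys: float = 4.5             # d^-1, dead-cell clearance (lysis)
    Y_x_gln: float = 2.6           # VCD-units per mM glutamine
    m_gln: float = 0.085           # mM/d per VCD-unit, maintenance at 35.25
    theta_m: float = 0.10          # per degC, maintenance temp sensitivity
    K_m_gln: float = 0.005         # mM, uptake saturation floor
    Y_x_glc: float = 2.1           # VCD-units per g/L glucose
    m_glc: float = 0.07            # g/L/d per VCD-unit
    theta_m_glc: float = 0.20      # per degC
    K_m_glc: float = 0.1           # g/L
    Y_lac_glc: float = 0.30        # g lactate per g glucose consumed
    y_amm_gln: float = 0.86        # mM ammonium per mM glutamine consumed
    alpha_pyr: float = 2.8         # per g/(L d) pyruvate feed, NH4 attenuation
    k_dgln: float = 0.02           # d^-1, spontaneous glutamine degradation
    y_glu_gln: float = 0.7         # mM glutamate per mM glutamine degraded
    q_glu_mu: float = 0.04         # glutamate uptake, growth-associated
    q_glu_0: float = 0.002         # glutamate uptake, basal
    K_glu: float = 0.3             # mM
    q_titer: float = 1.8           # mg/L/d per VCD-unit
    theta_qp: float = 0.15         # per degC below 35.25 (hypothermia boost)
    k_diam: float = 0.6            # d^-1, diameter relaxation rate
    diam_base: float = 16.5        # um, resting diameter
    diam_mu: float = 5.5           # um at mu = mu_max
    diam_vvd: float = 1.0          # um per unit VVD above the reference rate
    diam_temp: float = 0.5         # um per degC of mild hypothermia

    def f_temp(self, temp):
        return math.exp(-((temp - self.T_opt) / self.sigma_T) ** 2)


CLONE_A = KineticParams()
#: Clone B: same host, different product; more death-prone at warm setpoints,
#: more ammonium-sensitive, slightly slower and more productive.
CLONE_B = replace(CLONE_A, name="B", mu_max=1.0, k_d0=0.05, theta_d=0.9,
                  K_d_amm=4.5, y_amm_gln=0.95, q_titer=2.2)


@dataclass(frozen=True)
class FedBatchParams:
    """Kinetics of the in-silico fed-batch clones (X consumes lactate, Y not)."""

    name: str = "X"
    lactate_consumption: bool = True
    mu_max: float = 0.85
    K_glc: float = 0.3
    K_gln: float = 0.3
    K_i_amm: float = 18.0
    K_i_lac: float = 25.0
    K_do: float = 10.0             # % sat, DO saturation constant
    k_d0: float = 0.02
    k_d_amm: float = 0.004         # d^-1 per mM
    k_starv: float = 0.06
    K_starv: float = 0.1
    k_shear: float = 0.03
    stir_crit: float = 1050.0
    k_lys: float = 0.08            # d^-1, dead -> lysed conversion
    Y_x_glc: float = 1.0
    m_glc: float = 0.09
    K_m_glc: float = 0.2
    Y_x_gln: float = 1.4
    m_gln: float = 0.02
    K_m_gln: float = 0.02
    Y_lac_glc: float = 0.35
    q_lac_max: float = 0.15        # g/L/d per VCD-unit, lactate consumption
    K_lac_c: float = 0.5           # g/L
    glc_switch: float = 1.0        # g/L, glycolysis saturation scale
    y_amm_gln: float = 0.75
    k_dgln: float = 0.04
    beta_lac_amm: float = 30.0     # NH4 attenuation per unit lactate uptake
    q_titer: float = 1.2


CLONE_X = FedBatchParams()
CLONE_Y = replace(CLONE_X, name="Y", lactate_consumption=False)


DEFAULT_NOISE_CVS = {
    "VCD": 0.05, "DCD": 0.05, "Diam": 0.02, "Glc": 0.03, "Gln": 0.03,
    "Glu": 0.03, "Lac": 0.03, "Amm": 0.03, "Titer": 0.03, "Lysed": 0.05,
}
VIA_NOISE_PP = 0.5

#: perfusion medium composition (species absent -> 0)
DEFAULT_MEDIA = {"Glc": 7.0, "Gln": 5.0, "Glu": 1.0}

REFERENCE_SETPOINTS = {"Temp": 35.25, "Stir": 1050.0, "VVD": 1.25, "Pyr": 0.0}
GROWTH_TEMP = 36.5


@dataclass
class PlantConfig:
    mode: str = "perfusion"
    v0: float = 0.213                       # L, perfusion working volume
    media: dict = field(default_factory=lambda: dict(DEFAULT_MEDIA))
    ramp_rate: float = 0.65                 # d^-2, growth-phase VVD ramp slope
    vvd_cap: float = 1.3                    # d^-1, growth-phase VVD ceiling
    soc_vcv_target: float = 14.0            # %, state-of-control trigger
    soc_max_day: int = 7                    # growth phase ends here regardless
    bleed_ceiling: float = 38.0             # %, VCV at which bleeding starts
    substep: float = 0.01                   # d, RK4 step
    noise_cvs: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_CVS))
    via_noise_pp: float = VIA_NOISE_PP
    inoc_cv: float = 0.05                   # run-to-run inoculum variability

    def __post_init__(self):
        if self.substep > 0.1:
            raise ValueError("integration substep must be <= 0.1 d")
        if any(cv < 0 for cv in self.noise_cvs.values()):
            raise ValueError("noise CVs must be >= 0")


@dataclass(frozen=True)
class DisturbanceEvent:
    """Instantaneous addition of `amount` (species-unit * L) after sampling."""

    day: int
    species: str
    amount: float
    run_id: str | None = None


def sample_with_noise(true_row, noise_cvs=None, rng=None, via_noise_pp=VIA_NOISE_PP):
    """At-line measurement emulation: multiplicative Gaussian noise per variable.

    Concentrations (including DCD) get ``x * (1 + cv*eps)`` truncated at 0;
    viability is then recomputed from the noisy counts via the identity
    Via = 100*VCD/(VCD+DCD), so the identity holds at every stored state
    (counting noise is the at-line analyzer's actual viability error source).
    If DCD is absent, viability instead gets an absolute ``via_noise_pp``
    perturbation truncated to (0, 100].  Volume and setpoints are exact.
    """
    rng = np.random.default_rng(rng)
    cvs = DEFAULT_NOISE_CVS if noise_cvs is None else noise_cvs
    obs = dict(true_row)
    for col, cv in cvs.items():
        if col in obs and cv > 0:
            obs[col] = max(0.0, obs[col] * (1.0 + cv * rng.standard_normal()))
    if "Via" in obs:
        if "DCD" in obs:
            obs["Via"] = min(
                100.0, 100.0 * obs["VCD"] / max(obs["VCD"] + obs["DCD"], 1e-12))
        elif via_noise_pp > 0:
            via = obs["Via"] + via_noise_pp * rng.standard_normal()
            obs["Via"] = min(100.0, max(1e-6, via))
    return obs


# ---------------------------------------------------------------------------
# perfusion plant

class PerfusionPlant:
    """Stateful single-reactor perfusion simulator on a daily protocol grid.

    The daily cycle is driven externally (by the campaign generator or the
    closed-loop agent)::

        obs = plant.sample(rng)            # noisy at-line measurement
        plant.inject("Amm", 1.5)           # optional disturbance
        plant.advance_day(setpoints)       # integrate [day, day+1)

    ``extra_solubles`` admits fictitious species with zero reaction rate
    (inert tracers) for conservation checks.
    """

    CELLS = ("VCD", "DCD")

    def __init__(self, params=CLONE_A, config=None, seed=None,
                 initial_state=None, extra_solubles=None):
        self.params = params
        self.config = config or PlantConfig()
        self.rng = np.random.default_rng(seed)
        self.solubles = ("Glc", "Gln", "Glu", "Lac", "Amm", "Titer")
        self.media = dict(self.config.media)
        if extra_solubles:
            self.solubles = self.solubles + tuple(extra_solubles)
            for sp, med in extra_solubles.items():
                self.media[sp] = med
        self.species = self.CELLS + self.solubles
        self.day = 0
        self.in_soc = False
        self.soc_day = None
        state = {
            "V": self.config.v0, "VCD": 10.0, "DCD": 0.1, "Diam": 18.0,
            "Glc": 5.0, "Gln": 5.0, "Glu": 0.8, "Lac": 0.1, "Amm": 0.3,
            "Titer": 0.0,
        }
        for sp in self.solubles:
            state.setdefault(sp, self.media.get(sp, 0.0))
        if initial_state:
            state.update(initial_state)
        elif self.config.inoc_cv > 0:
            state["VCD"] *= max(0.2, 1.0 + self.config.inoc_cv
                                * self.rng.standard_normal())
        self.state = state
        self._truth_rows = {0: self._snapshot()}
        self._obs_rows = {}
        self._flow_rows = {}
        self._applied_setpoints = {}
        self._pending_feed = {sp: 0.0 for sp in self.species}
        self._last_obs = None

    # -- bookkeeping -------------------------------------------------------

    def _snapshot(self):
        s = self.state
        via = 100.0 * s["VCD"] / max(s["VCD"] + s["DCD"], 1e-12)
        row = {"V": s["V"], "Via": via, "Diam": s["Diam"]}
        for sp in self.species:
            row[sp] = s[sp]
        return row

    @property
    def vcv(self):
        return compute_vcv(self.state["Diam"], self.state["VCD"])

    # -- daily protocol ----------------------------------------------------

    def protocol_setpoints(self):
        """Reference protocol: VVD ramp during growth, reference levels after."""
        if self.in_soc:
            return dict(REFERENCE_SETPOINTS)
        vvd = min(self.config.vvd_cap, self.config.ramp_rate * self.day)
        return {"Temp": GROWTH_TEMP, "Stir": REFERENCE_SETPOINTS["Stir"],
                "VVD": vvd, "Pyr": 0.0}

    def sample(self, rng=None):
        """Noisy observation of the current day's state; triggers SoC detection."""
        if self.day in self._obs_rows:
            return dict(self._obs_rows[self.day])
        true_row = self._truth_rows[self.day]
        obs = sample_with_noise(true_row, self.config.noise_cvs,
                                rng if rng is not None else self.rng,
                                self.config.via_noise_pp)
        obs["V"] = true_row["V"]
        self._obs_rows[self.day] = dict(obs)
        self._last_obs = obs
        if not self.in_soc and (
                compute_vcv(obs["Diam"], obs["VCD"]) >= self.config.soc_vcv_target
                or self.day >= self.config.soc_max_day):
            self.in_soc = True
            self.soc_day = self.day
        return dict(obs)

    def inject(self, species, amount):
        """Manual addition of ``amount`` (species-unit * L) after sampling.

        The addition is a known operator action, so its mass is booked as a
        feed of the upcoming interval (the model is not asked to explain it
        as a biological rate).
        """
        if species not in self.species:
            raise ValueError(f"unknown species {species!r}")
        if amount < 0:
            raise ValueError("disturbance amount must be >= 0")
        self.state[species] += amount / self.state["V"]
        self._pending_feed[species] += amount
        return self.state[species]

    # -- dynamics ----------------------------------------------------------

    def _rates(self, c, setpoints):
        """Reaction-rate vector (per L per day) and diameter derivative."""
        p = self.params
        temp, stir, pyr = setpoints["Temp"], setpoints["Stir"], setpoints["Pyr"]
        vcd, dcd = c["VCD"], c["DCD"]
        glc, gln, glu, lac, amm = c["Glc"], c["Gln"], c["Glu"], c["Lac"], c["Amm"]

        mu = (p.mu_max * p.f_temp(temp)
              * glc / (p.K_glc + glc) * gln / (p.K_gln + gln)
              * p.K_i_amm / (p.K_i_amm + amm) * p.K_i_lac / (p.K_i_lac + lac))
        shear = max(0.0, (stir - p.stir_crit) / 350.0)
        kd = (p.k_d0 * math.exp(p.theta_d * (temp - 35.25))
              * (1.0 + (amm / p.K_d_amm) ** 2)
              + p.k_shear * shear ** 2
              + p.k_starv * p.K_starv / (p.K_starv + gln))

        m_gln = p.m_gln * math.exp(p.theta_m * (temp - 35.25))
        q_gln = (mu / p.Y_x_gln + m_gln) * gln / (p.K_m_gln + gln)
        m_glc = p.m_glc * math.exp(p.theta_m_glc * (temp - 35.25))
        q_glc = (mu / p.Y_x_glc + m_glc) * glc / (p.K_m_glc + glc)
        phi_pyr = 1.0 / (1.0 + p.alpha_pyr * pyr)
        q_glu = (p.q_glu_mu * mu + p.q_glu_0) * glu / (p.K_glu + glu)

        r = dict.fromkeys(self.species, 0.0)
        r["VCD"] = (mu - kd) * vcd
        r["DCD"] = kd * vcd - p.k_lys * dcd
        r["Glc"] = -q_glc * vcd
        r["Gln"] = -q_gln * vcd - p.k_dgln * gln
        r["Glu"] = p.y_glu_gln * p.k_dgln * gln - q_glu * vcd
        r["Lac"] = p.Y_lac_glc * q_glc * vcd
        r["Amm"] = (p.y_amm_gln * q_gln * vcd + p.k_dgln * gln) * phi_pyr
        r["Titer"] = (p.q_titer * max(0.0, 1.0 + p.theta_qp * (35.25 - temp))
                      * vcd)
        diam_target = (p.diam_base + p.diam_mu * mu / p.mu_max
                       + p.diam_vvd * (setpoints["VVD"] - 1.25)
                       + p.diam_temp * (35.25 - temp))
        d_diam = p.k_diam * (diam_target - c["Diam"])
        return r, d_diam, mu

    def _apply_bolus(self, glc_obs):
        """Protocol glucose bolus sized from the observed glucose value."""
        triggered, v = bolus_volume(self.state["V"], glc_obs)
        if not triggered or v <= 0:
            return
        V = self.state["V"]
        g = V / (V + v)
        mixed = {sp: self.state[sp] * g for sp in self.solubles}
        mixed["Glc"] += GLC_BOLUS_STOCK * v / (V + v)
        for sp in self.solubles:                  # volume restored via permeate
            self._flow_rows[self.day][f"perm_{sp}"] += v * mixed[sp]
            self.state[sp] = mixed[sp]
        self._flow_rows[self.day]["feed_Glc"] += v * GLC_BOLUS_STOCK

    def _apply_bleed(self, flows):
        """Whole-broth removal (media-replaced) pinning VCV at the ceiling."""
        vcv = self.vcv
        ceil = self.config.bleed_ceiling
        if vcv <= ceil:
            return
        V = self.state["V"]
        f = ceil / vcv
        vb = V * (1.0 - f)
        for sp in self.CELLS:
            flows[f"bleed_{sp}"] += vb * self.state[sp]
            self.state[sp] *= f
        for sp in self.solubles:
            flows[f"bleed_{sp}"] += vb * self.state[sp]
            flows[f"feed_{sp}"] += vb * self.media.get(sp, 0.0)
            self.state[sp] += (vb / V) * (self.media.get(sp, 0.0) - self.state[sp])

    def advance_day(self, setpoints):
        """Integrate one day under constant setpoints; returns the flow row."""
        for k in ("Temp", "Stir", "VVD", "Pyr"):
            if k not in setpoints:
                raise ValueError(f"missing setpoint {k!r}")
        day = self.day
        flows = {c: 0.0 for c in flow_columns(self.species)}
        for sp, mass in self._pending_feed.items():
            flows[f"feed_{sp}"] += mass
        self._pending_feed = {sp: 0.0 for sp in self.species}
        self._flow_rows[day] = flows
        self._applied_setpoints[day] = {**setpoints, "DO": 50.0}

        obs = self._last_obs or self._truth_rows[day]
        self._apply_bolus(obs["Glc"])

        p_flow = setpoints["VVD"] * self.state["V"]  # L/d in = permeate out
        n_steps = max(1, round(1.0 / self.config.substep))
        dt = 1.0 / n_steps
        for _ in range(n_steps):
            self._rk4_substep(dt, setpoints, p_flow, flows)
            self._apply_bleed(flows)
        self.day += 1
        self._truth_rows[self.day] = self._snapshot()
        self._last_obs = None
        return dict(flows)

    def _rk4_substep(self, dt, setpoints, p_flow, flows):
        V = self.state["V"]
        d_in = p_flow / V       # dilution rate, d^-1

        def deriv(c):
            r, d_diam, _ = self._rates(c, setpoints)
            dc = {}
            for sp in self.CELLS:
                dc[sp] = r[sp]                       # retained by membrane
            for sp in self.solubles:
                dc[sp] = r[sp] + d_in * (self.media.get(sp, 0.0) - c[sp])
            dc["Diam"] = d_diam
            dflow = {sp: p_flow * c[sp] for sp in self.solubles}  # permeate
            return dc, dflow

        c0 = {k: self.state[k] for k in (*self.species, "Diam")}
        k1, f1 = deriv(c0)
        c1 = {k: c0[k] + 0.5 * dt * k1[k] for k in c0}
        k2, f2 = deriv(c1)
        c2 = {k: c0[k] + 0.5 * dt * k2[k] for k in c0}
        k3, f3 = deriv(c2)
        c3 = {k: c0[k] + dt * k3[k] for k in c0}
        k4, f4 = deriv(c3)
        for k in c0:
            val = c0[k] + dt / 6.0 * (k1[k] + 2 * k2[k] + 2 * k3[k] + k4[k])
            self.state[k] = max(0.0, val)
        for sp in self.solubles:
            flows[f"perm_{sp}"] += dt / 6.0 * (f1[sp] + 2 * f2[sp]
                                               + 2 * f3[sp] + f4[sp])
            flows[f"feed_{sp}"] += dt * p_flow * self.media.get(sp, 0.0)

    # -- export ------------------------------------------------------------

    def to_run_record(self, run_id, observed=True):
        rows = self._obs_rows if observed else self._truth_rows
        if observed and len(self._obs_rows) != len(self._truth_rows):
            raise RuntimeError("not every day was sampled; cannot export "
                               "an observed run record")
        days = sorted(self._truth_rows)
        data = []
        for d in days:
            row = dict(rows[d])
            sp = self._applied_setpoints.get(
                d, self._applied_setpoints.get(d - 1, {**REFERENCE_SETPOINTS,
                                                      "DO": 50.0}))
            row.update(sp)
            data.append(row)
        states = pd.DataFrame(data, index=days)
        cols = [c for c in PERFUSION_STATE_COLS if c in states.columns]
        extra = [c for c in states.columns if c not in cols]
        states = states[cols + extra]
        flows = pd.DataFrame([self._flow_rows[d] for d in days[:-1]],
                             index=days[:-1])
        flows["dVdt"] = 0.0
        return RunRecord(run_id, self.params.name, states, flows,
                         mode="perfusion",
                         metadata={"soc_day": self.soc_day})


def simulate_perfusion_day(plant, setpoints, bounds=None, rng=None):
    """Sample, then advance the plant one day under ``setpoints``.

    Out-of-bounds setpoints raise (a guard against bad optimizer output).
    Returns ``(observed_state_row, next_true_state_row, flow_row)``.
    """
    bounds = bounds or DESIGN_BOUNDS
    for key, (lo, hi) in bounds.items():
        if key in setpoints and not (lo - 1e-9 <= setpoints[key] <= hi + 1e-9):
            raise ValueError(
                f"setpoint {key}={setpoints[key]} outside [{lo}, {hi}]")
    obs = plant.sample(rng)
    flows = plant.advance_day(setpoints)
    return obs, plant._truth_rows[plant.day], flows


def apply_disturbance(plant, event):
    """Apply a :class:`DisturbanceEvent` scheduled for the current day."""
    if event.day != plant.day:
        raise ValueError(
            f"disturbance scheduled for day {event.day} applied on day {plant.day}")
    return plant.inject(event.species, event.amount)


# ---------------------------------------------------------------------------
# training campaign

def _factorial_design(rng, bounds):
    """16 two-level corners + 4 center replicates + 4 seeded axial picks."""
    factors = ("VVD", "Temp", "Stir", "Pyr")
    rows = []
    for code in range(16):
        rows.append([1 if code & (1 << i) else -1 for i in range(4)])
    rows += [[0, 0, 0, 0]] * 4
    axial = rng.choice(8, size=4, replace=False)
    for a in axial:
        row = [0, 0, 0, 0]
        row[a % 4] = 1 if a < 4 else -1
        rows.append(row)
    levels = pd.DataFrame(rows, columns=factors)
    design = levels.copy().astype(float)
    for f in factors:
        lo, hi = bounds[f]
        design[f] = lo + (levels[f] + 1) / 2.0 * (hi - lo)
    design.insert(0, "run_id", [f"R{i + 1:02d}" for i in range(len(design))])
    return design


def generate_training_campaign(seed, n_runs=24, t_f=20, params=CLONE_A,
                               config=None, bounds=None):
    """Seeded perfusion training campaign over the 4-factor design space.

    Each run follows the reference ramp until the state-of-control VCV target
    is reached, then applies its design setpoints; daily at-line sampling with
    measurement noise.  Deterministic for a given seed (per-run substreams).
    """
    bounds = dict(bounds or DESIGN_BOUNDS)
    if len(bounds) < 4:
        raise ValueError("training design needs at least 4 factors")
    master = np.random.SeedSequence(seed)
    design = _factorial_design(np.random.default_rng(master.spawn(1)[0]), bounds)
    if n_runs != len(design):
        raise ValueError(f"design has {len(design)} runs, requested {n_runs}")
    runs = []
    streams = master.spawn(n_runs + 1)[1:]
    for i, row in design.iterrows():
        plant = PerfusionPlant(params=params, config=config, seed=streams[i])
        for _ in range(t_f):
            plant.sample()
            sp = plant.protocol_setpoints()
            if plant.in_soc:
                sp = {f: row[f] for f in ("VVD", "Temp", "Stir", "Pyr")}
            plant.advance_day(sp)
        plant.sample()
        runs.append(plant.to_run_record(row["run_id"]))
    return Campaign(runs, design_table=design, bounds=bounds)


# ---------------------------------------------------------------------------
# fed-batch in-silico clones

def _fedbatch_rates(p, c, setpoints):
    stir, do = setpoints["Stir"], setpoints["DO"]
    vcd, glc, gln, lac, amm = c["VCD"], c["Glc"], c["Gln"], c["Lac"], c["Amm"]
    mu = (p.mu_max * do / (p.K_do + do)
          * glc / (p.K_glc + glc) * gln / (p.K_gln + gln)
          * p.K_i_amm / (p.K_i_amm + amm) * p.K_i_lac / (p.K_i_lac + lac))
    shear = max(0.0, (stir - p.stir_crit) / 350.0)
    kd = (p.k_d0 + p.k_d_amm * amm + p.k_shear * shear ** 2
          + p.k_starv * p.K_starv / (p.K_starv + gln))
    q_glc = (mu / p.Y_x_glc + p.m_glc) * glc / (p.K_m_glc + glc)
    q_gln = (mu / p.Y_x_gln + p.m_gln) * gln / (p.K_m_gln + gln)
    sat = glc ** 2 / (glc ** 2 + p.glc_switch ** 2)   # glycolysis saturation
    q_lac_c = 0.0
    if p.lactate_consumption:
        q_lac_c = p.q_lac_max * lac / (p.K_lac_c + lac) * (1.0 - sat)
    phi = 1.0 / (1.0 + p.beta_lac_amm * q_lac_c)      # TCA fed by lactate
    r = {
        "VCD": (mu - kd) * vcd,
        "DCD": kd * vcd - p.k_lys * c["DCD"],
        "Lysed": p.k_lys * c["DCD"],
        "Glc": -q_glc * vcd,
        "Gln": -q_gln * vcd - p.k_dgln * gln,
        "Lac": p.Y_lac_glc * q_glc * vcd - q_lac_c * vcd,
        "Amm": (p.y_amm_gln * q_gln * vcd + p.k_dgln * gln) * phi,
        "Titer": p.q_titer * vcd,
    }
    return r


FEEDS_MEDIUM = {"Glc": 40.0, "Gln": 60.0}   # fed-batch feed concentrate


def simulate_fedbatch_run(params, controls, seed=None, t_f=14, substep=0.01,
                          noise_cvs=None, run_id="F01"):
    """Simulate one 14-day fed-batch run of an in-silico clone.

    ``controls``: dict with Stir, DO, VCD0, Glc0, Gln0 and ``feed_volumes``
    (L/day, applied as an instantaneous feed at the start of each day from
    day 1; negative volumes rejected).  Returns an observed RunRecord.
    """
    feed_volumes = np.asarray(controls.get("feed_volumes",
                                           np.zeros(t_f)), dtype=float)
    if (feed_volumes < 0).any():
        raise ValueError("feed volumes must be >= 0")
    if len(feed_volumes) < t_f:
        raise ValueError(f"need {t_f} daily feed volumes")
    rng = np.random.default_rng(seed)
    species = ("VCD", "DCD", "Lysed", "Glc", "Gln", "Lac", "Amm", "Titer")
    state = {"VCD": controls.get("VCD0", 0.5), "DCD": 0.01, "Lysed": 0.0,
             "Glc": controls.get("Glc0", 6.0), "Gln": controls.get("Gln0", 4.5),
             "Lac": 0.1, "Amm": 0.2, "Titer": 0.0}
    V = controls.get("V0", 0.18)
    setpoints = {"Stir": controls.get("Stir", 900.0),
                 "DO": controls.get("DO", 50.0)}
    cvs = dict(DEFAULT_NOISE_CVS if noise_cvs is None else noise_cvs)

    truth, obs_rows, flow_rows = [], [], []

    def record(day):
        via = 100.0 * state["VCD"] / max(state["VCD"] + state["DCD"], 1e-12)
        row = {"V": V, "Via": via, "Diam": 18.0, "Glu": 0.5, **state}
        truth.append(row)
        obs = sample_with_noise(row, cvs, rng)
        obs["V"] = V
        obs_rows.append(obs)

    record(0)
    n_steps = max(1, round(1.0 / substep))
    dt = 1.0 / n_steps
    for day in range(t_f):
        flows = {c: 0.0 for c in flow_columns(species)}
        v_feed = feed_volumes[day]
        if v_feed > 0:                      # instantaneous feed after sampling
            g = V / (V + v_feed)
            for sp in species:
                if sp in ("VCD", "DCD", "Lysed"):
                    state[sp] *= g          # cells diluted, no cell feed
                else:
                    added = FEEDS_MEDIUM.get(sp, 0.0) * v_feed
                    state[sp] = state[sp] * g + added / (V + v_feed)
                    flows[f"feed_{sp}"] += added
            V += v_feed
        flows["dVdt"] = v_feed
        for _ in range(n_steps):
            c0 = dict(state)
            k1 = _fedbatch_rates(params, c0, setpoints)
            c1 = {k: c0[k] + 0.5 * dt * k1[k] for k in c0}
            k2 = _fedbatch_rates(params, c1, setpoints)
            c2 = {k: c0[k] + 0.5 * dt * k2[k] for k in c0}
            k3 = _fedbatch_rates(params, c2, setpoints)
            c3 = {k: c0[k] + dt * k3[k] for k in c0}
            k4 = _fedbatch_rates(params, c3, setpoints)
            for k in c0:
                state[k] = max(0.0, c0[k] + dt / 6.0
                               * (k1[k] + 2 * k2[k] + 2 * k3[k] + k4[k]))
        flow_rows.append(flows)
        record(day + 1)

    def build(rows):
        df = pd.DataFrame(rows, index=range(t_f + 1))
        df["Temp"], df["Stir"] = 36.5, setpoints["Stir"]
        df["VVD"], df["Pyr"], df["DO"] = 0.0, 0.0, setpoints["DO"]
        cols = [c for c in FEDBATCH_STATE_COLS if c in df.columns]
        return df[cols]

    flows_df = pd.DataFrame(flow_rows, index=range(t_f))
    return RunRecord(run_id, params.name, build(obs_rows), flows_df,
                     mode="fed-batch", metadata={"controls": dict(setpoints)})


def generate_fedbatch_campaign(params, n_runs=24, seed=0, t_f=14,
                               substep=0.01, noise_cvs=None):
    """Seeded Latin-hypercube campaign of in-silico fed-batch runs."""
    from scipy.stats import qmc

    master = np.random.SeedSequence(seed)
    sampler = qmc.LatinHypercube(d=6, seed=np.random.default_rng(master.spawn(1)[0]))
    u = sampler.random(n_runs)
    lo = np.array([700.0, 30.0, 0.3, 4.0, 3.0, 0.002])
    hi = np.array([1400.0, 60.0, 0.8, 8.0, 6.0, 0.006])
    ctrl = qmc.scale(u, lo, hi)
    runs = []
    streams = master.spawn(n_runs + 1)[1:]
    for i in range(n_runs):
        stir, do, vcd0, glc0, gln0, feed = ctrl[i]
        feeds = np.r_[np.zeros(3), np.full(t_f - 3, feed)]  # feeding from day 3
        controls = {"Stir": stir, "DO": do, "VCD0": vcd0, "Glc0": glc0,
                    "Gln0": gln0, "feed_volumes": feeds}
        runs.append(simulate_fedbatch_run(
            params, controls, seed=streams[i], t_f=t_f, substep=substep,
            noise_cvs=noise_cvs, run_id=f"{params.name}{i + 1:02d}"))
    design = pd.DataFrame(ctrl, columns=["Stir", "DO", "VCD0", "Glc0", "Gln0",
                                         "feed_vol"])
    design.insert(0, "run_id", [r.run_id for r in runs])
    return Campaign(runs, design_table=design)
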