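"""Core domain types and derived quantities for perfusion/fed-batch cultivation data.

A cultivation run is represented as two aligned tables on a daily integer time
grid (day 0 = inoculation): a *state* table (one row per sampling day) and a
*flow* table (one row per day interval ``[t, t+1)``) holding per-species mass
feed / bleed / permeate totals in species-unit·L/d plus the volume derivative.

Units are fixed package-wide:

====== ======================== =========================
column quantity                 unit
====== ======================== =========================
V      broth volume             L
VCD    viable cell density      1e6 cells/mL
DCD    dead cell density        1e6 cells/mL
Lysed  lysed cell density       1e6 cells/mL (fed-batch)
Via    viability                %
Diam   mean cell diameter       µm
Glc    glucose                  g/L
Gln    glutamine                mM
Glu    glutamate                mM
Lac    lactate                  g/L
Amm    ammonium                 mM
Titer  product titer            mg/L
Temp   temperature setpoint     °C
Stir   stirrer speed setpoint   rpm
VVD    perfusion rate setpoint  vessel volumes per day
Pyr    pyruvate feed setpoint   g/(L·d)
DO     dissolved O2 setpoint    % saturation
====== ======================== =========================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "PERFUSION_SPEC",
    "FEDBATCH_SPEC",
    "RunRecord",
    "Campaign",
    "compute_vcv",
    "bolus_volume",
    "GLC_BOLUS_TRIGGER",
    "GLC_BOLUS_TARGET",
    "GLC_BOLUS_STOCK",
]

#: Glucose bolus protocol constants (g/L): trigger threshold, replenish target,
#: and the concentration of the glucose stock used to size the bolus.
GLC_BOLUS_TRIGGER = 2.00
GLC_BOLUS_TARGET = 5.00
GLC_BOLUS_STOCK = 200.0

#: Per-litre sphere-volume factor: VCV% = VCD [1e6/mL] * (pi/6) d^3 [µm^3] * 1e-4
_VCV_FACTOR = 1e-4


def compute_vcv(diam, vcd):
    """Viable cell volume (%) from mean cell diameter (µm) and VCD (1e6 cells/mL).

    The viable cells are treated as spheres of diameter ``diam``; the returned
    value is the percentage of the broth volume they occupy:

        VCV% = 100 * VCD*1e6 [cells/mL] * (4/3)*pi*(d/2)^3 [µm^3] / 1e12 [µm^3/mL]

    Accepts scalars or numpy arrays.
    """
    diam = np.asarray(diam, dtype=float)
    vcd = np.asarray(vcd, dtype=float)
    if np.any(diam < 0) or np.any(vcd < 0):
        raise ValueError("diameter and VCD must be non-negative")
    out = (math.pi / 6.0) * diam**3 * vcd * _VCV_FACTOR
    return float(out) if out.ndim == 0 else out


def bolus_volume(volume_l, glc_measured, glc_target=GLC_BOLUS_TARGET,
                 stock_conc=GLC_BOLUS_STOCK, trigger=GLC_BOLUS_TRIGGER):
    """Glucose-bolus decision and volume.

    A bolus is triggered when the measured glucose is below ``trigger`` (g/L);
    its volume v (L) solves the mixing equation

        (glc_measured*V + stock_conc*v) / (V + v) = glc_target

    Returns ``(triggered, volume_l)``; volume is 0.0 when not triggered.
    """
    if stock_conc <= glc_target:
        raise ValueError(
            f"stock concentration {stock_conc} g/L cannot reach target "
            f"{glc_target} g/L (target unreachable)")
    if glc_target <= 0 or volume_l <= 0:
        raise ValueError("target concentration and volume must be positive")
    if glc_measured >= trigger:
        return False, 0.0
    v = volume_l * (glc_target - glc_measured) / (stock_conc - glc_target)
    return True, v


@dataclass(frozen=True)
class ModelSpec:
    """Declares which columns of a run are modeled and how.

    species
        Mass-balanced concentration-like variables: their production rates obey
        the discretized balance with feed/bleed/permeate flow corrections.
    intensive
        Variables with plain per-day increment dynamics and no flow terms
        (viability, diameter).
    setpoints
        Manipulated inputs, piecewise constant per day.
    retained
        Species held back by the cell-retention membrane (no permeate outflow).
    clones
        Declared clone label set; encoding order is fixed by this tuple so it
        is stable across retraining.
    """

    species: tuple = ("VCD", "DCD", "Glc", "Gln", "Glu", "Lac", "Amm", "Titer")
    intensive: tuple = ("Via", "Diam")
    setpoints: tuple = ("Temp", "Stir", "VVD", "Pyr")
    retained: tuple = ("VCD", "DCD")
    clones: tuple = ("A", "B")

    @property
    def modeled(self):
        """All variables the model predicts rates/increments for."""
        return self.species + self.intensive

    def feature_names(self):
        """GP input feature order: modeled states, setpoints, clone one-hot."""
        return list(self.modeled) + list(self.setpoints) + [
            f"clone_{c}" for c in self.clones]


PERFUSION_SPEC = ModelSpec()

FEDBATCH_SPEC = ModelSpec(
    species=("VCD", "DCD", "Lysed", "Glc", "Gln", "Lac", "Amm", "Titer"),
    intensive=(),
    setpoints=("Stir", "DO"),
    retained=("VCD", "DCD", "Lysed"),
    clones=("X", "Y"),
)

#: State columns stored for each mode (order used in CSV round trips).
PERFUSION_STATE_COLS = ["V", "VCD", "DCD", "Via", "Diam", "Glc", "Gln", "Glu",
                        "Lac", "Amm", "Titer", "Temp", "Stir", "VVD", "Pyr", "DO"]
FEDBATCH_STATE_COLS = ["V", "VCD", "DCD", "Lysed", "Via", "Diam", "Glc", "Gln",
                       "Glu", "Lac", "Amm", "Titer", "Temp", "Stir", "VVD",
                       "Pyr", "DO"]


def flow_columns(species):
    """Flow-table column names for a species tuple."""
    cols = []
    for kind in ("feed", "bleed", "perm"):
        cols += [f"{kind}_{sp}" for sp in species]
    cols.append("dVdt")
    return cols


@dataclass
class RunRecord:
    """One reactor's time-ordered daily states and interval flows.

    ``states`` is indexed by integer day 0..t_f; ``flows`` by day 0..t_f-1 with
    columns ``feed_<sp>``, ``bleed_<sp>``, ``perm_<sp>`` (species-unit·L/d,
    interval totals divided by the 1-day interval length) and ``dVdt`` (L/d).
    """

    run_id: str
    clone: str
    states: pd.DataFrame
    flows: pd.DataFrame
    mode: str = "perfusion"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def duration(self):
        """Process duration t_f in days (number of day intervals)."""
        return int(self.states.index[-1])

    def validate(self):
        s = self.states
        days = np.asarray(s.index)
        if len(days) < 1 or not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
            raise ValueError(f"run {self.run_id}: non-contiguous integer day index")
        if len(self.flows) != len(s) - 1:
            raise ValueError(
                f"run {self.run_id}: flows must have one row per day interval "
                f"({len(s) - 1}), got {len(self.flows)}")
        if (s["V"] <= 0).any():
            raise ValueError(f"run {self.run_id}: non-positive volume")
        conc_cols = [c for c in s.columns if c not in ("Temp", "Stir", "VVD", "Pyr", "DO")]
        neg = s[conc_cols] < -1e-9
        if neg.any().any():
            col = neg.any()[neg.any()].index[0]
            raise ValueError(f"run {self.run_id}: negative {col}")
        if ((s["Via"] < 0) | (s["Via"] > 100 + 1e-9)).any():
            raise ValueError(f"run {self.run_id}: viability outside [0, 100]")
        if "Diam" in s and ((s["VCD"] > 0) & (s["Diam"] <= 0)).any():
            raise ValueError(f"run {self.run_id}: zero diameter with live cells")
        if self.mode == "perfusion" and not np.allclose(s["V"], s["V"].iloc[0], rtol=1e-9):
            raise ValueError(f"run {self.run_id}: perfusion volume must be constant")
        return self

    def truncated(self, day):
        """Copy containing only data observed up to and including ``day``."""
        return RunRecord(self.run_id, self.clone,
                         self.states.loc[:day].copy(),
                         self.flows.loc[:max(day - 1, -1)].copy()
                         if day >= 1 else self.flows.iloc[:0].copy(),
                         mode=self.mode, metadata=dict(self.metadata))

    def with_states(self, states, flows):
        return replace(self, states=states, flows=flows)


@dataclass
class Campaign:
    """A set of runs plus the factor design that generated them."""

    runs: list
    design_table: pd.DataFrame | None = None
    bounds: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate run_ids in campaign")
        if self.design_table is not None:
            for factor, (lo, hi) in self.bounds.items():
                if factor in self.design_table:
                    vals = self.design_table[factor]
                    if ((vals < lo - 1e-9) | (vals > hi + 1e-9)).any():
                        raise ValueError(f"design level for {factor} outside bounds")

    def __len__(self):
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    def run(self, run_id):
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(run_id)

    @property
    def clones(self):
        return sorted({r.clone for r in self.runs})
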