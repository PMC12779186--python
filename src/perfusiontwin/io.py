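"""Campaign CSV readers/writers.

Storage dialect: tidy UTF-8 CSV, one row per reactor-day, '.' decimal.
State columns carry unit suffixes (``VCD`` is dimension-free in the header
because its unit 1e6 cells/mL has no compact ASCII form); flow columns are
``feed_<sp>``/``bleed_<sp>``/``perm_<sp>`` interval totals (species-unit·L/d)
attributed to the interval starting at that row's day, plus ``dVdt`` (L/d).
The final day of each run has empty flow cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (Campaign, RunRecord, FEDBATCH_STATE_COLS,
                        PERFUSION_STATE_COLS)

__all__ = ["write_campaign", "read_campaign", "CampaignValidationError"]

#: internal state column -> CSV header
_CSV_NAMES = {
    "V": "V_L", "VCD": "VCD", "DCD": "DCD", "Lysed": "Lysed",
    "Via": "Via_pct", "Diam": "Diam_um", "Glc": "Glc_gL", "Gln": "Gln_mM",
    "Glu": "Glu_mM", "Lac": "Lac_gL", "Amm": "Amm_mM", "Titer": "Titer_mgL",
    "Temp": "Temp_C", "Stir": "Stir_rpm", "VVD": "VVD_d", "Pyr": "Pyr_gLd",
    "DO": "DO_pct",
}
_FROM_CSV = {v: k for k, v in _CSV_NAMES.items()}


class CampaignValidationError(ValueError):
    """Raised when a campaign file violates the schema or a state invariant."""


def write_campaign(path, campaign):
    """Write a :class:`Campaign` to a tidy CSV (lossless round trip)."""
    frames = []
    for run in campaign.runs:
        df = run.states.copy()
        df.insert(0, "day", df.index)
        df.insert(0, "clone", run.clone)
        df.insert(0, "run_id", run.run_id)
        df.insert(3, "mode", run.mode)
        fl = run.flows.reindex(df["day"])  # final day -> NaN flow cells
        fl.index = df.index
        frames.append(pd.concat([df, fl], axis=1))
    tidy = pd.concat(frames, ignore_index=True)
    tidy = tidy.rename(columns=_CSV_NAMES)
    tidy.to_csv(path, index=False, float_format="%.12g")
    if campaign.design_table is not None:
        design_path = _design_path(path)
        campaign.design_table.to_csv(design_path, index=False, float_format="%.12g")
    return path


def _design_path(path):
    p = str(path)
    return (p[:-4] + ".design.csv") if p.endswith(".csv") else p + ".design.csv"


def read_campaign(path, bounds=None):
    """Read a campaign CSV written by :func:`write_campaign`.

    Validates the schema and the per-run state invariants; errors name the
    offending run and row.
    """
    tidy = pd.read_csv(path)
    required = {"run_id", "clone", "day", "mode", "V_L", "VCD", "Via_pct"}
    missing = required - set(tidy.columns)
    if missing:
        raise CampaignValidationError(f"missing columns: {sorted(missing)}")
    dup = tidy.duplicated(subset=["run_id", "day"])
    if dup.any():
        row = tidy[dup].iloc[0]
        raise CampaignValidationError(
            f"duplicated (run_id, day) = ({row['run_id']}, {row['day']})")
    tidy = tidy.rename(columns=_FROM_CSV)

    runs = []
    for run_id, grp in tidy.groupby("run_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
            raise CampaignValidationError(
                f"run {run_id}: non-monotone or gapped day index")
        mode = grp["mode"].iloc[0]
        state_cols = FEDBATCH_STATE_COLS if mode == "fed-batch" else PERFUSION_STATE_COLS
        state_cols = [c for c in state_cols if c in grp.columns]
        states = grp[state_cols].copy()
        states.index = days
        fcols = [c for c in grp.columns
                 if c.startswith(("feed_", "bleed_", "perm_")) or c == "dVdt"]
        flows = grp[fcols].iloc[:-1].copy()
        flows.index = days[:-1]
        try:
            run = RunRecord(str(run_id), str(grp["clone"].iloc[0]), states,
                            flows, mode=mode)
        except ValueError as exc:
            raise CampaignValidationError(str(exc)) from exc
        runs.append(run)

    design = None
    try:
        design = pd.read_csv(_design_path(path))
    except (FileNotFoundError, OSError):
        pass
    camp = Campaign(runs, design_table=design, bounds=dict(bounds or {}))
    if bounds:
        for run in runs:
            for sp, (lo, hi) in bounds.items():
                if sp in run.states.columns:
                    v = run.states[sp]
                    bad = (v < lo - 1e-9) | (v > hi + 1e-9)
                    if bad.any():
                        raise CampaignValidationError(
                            f"run {run.run_id} day {v.index[bad][0]}: "
                            f"{sp}={v[bad].iloc[0]} outside [{lo}, {hi}]")
    return camp
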