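"""Perceptual weight-estimate normalization and condition summaries.

Magnitude estimation lets each participant rate perceived heaviness on a
self-chosen, unbounded positive scale, so raw reports are only meaningful
up to a positive affine transform.  Standardizing within participant
(z-scores over the valid trials) removes that arbitrary scale and makes
reports comparable across participants; the same standardization is
applied to the force-rate peaks before computing perception/force
contrasts.

The per-participant condition means (8 transition conditions) feed the
split-plot ANOVA; the previous-light minus previous-heavy differences of
those means quantify the perceptual bias (positive = the object feels
heavier after a light lift, the expected direction) and, for the z-scored
force peaks, the sensorimotor-memory effect (stored as previous-heavy
minus previous-light, positive = higher rates after a heavy lift, the
expected direction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "zscore_by_participant",
    "zscore_metrics",
    "condition_means",
    "bias_contrasts",
]

CONDITIONS = ("LLS", "HLS", "LHS", "HHS", "LLD", "HLD", "LHD", "HHD")


def _zscore(values: pd.Series, ddof: int = 1) -> pd.Series:
    sd = values.std(ddof=ddof)
    return (values - values.mean()) / sd


def zscore_by_participant(table: pd.DataFrame,
                          value_col: str = "raw_estimate",
                          out_col: str = "z_estimate",
                          valid_col: str = "perceptual_valid",
                          include_dummy: bool = True,
                          ddof: int = 1) -> pd.DataFrame:
    """Standardize a report column within each participant.

    The mean and sample SD (``ddof=1``) are computed over the
    participant's valid trials — by default including dummy-object lifts,
    which were real lifts with real reports; set ``include_dummy=False``
    to restrict the normalization to light/heavy trials.  Invalid trials
    are excluded from the mean/SD and left unscored (NaN).

    Raises
    ------
    ValueError
        If a participant has fewer than 2 valid trials or zero variance
        (the participant is named in the message).
    """
    out = table.copy()
    valid = (out[valid_col].astype(bool) if valid_col in out.columns
             else pd.Series(True, index=out.index))
    used = valid.copy()
    if not include_dummy and "current_weight" in out.columns:
        used &= out["current_weight"].isin(["L", "H"])
    vals = out.loc[used, value_col].astype(float)
    g = vals.groupby(out.loc[used, "participant"])
    counts = g.size()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValueError(f"participant {bad!r}: fewer than 2 valid reports")
    sd = g.std(ddof=ddof)
    if (~np.isfinite(sd) | (sd == 0)).any():
        bad = sd.index[~np.isfinite(sd) | (sd == 0)][0]
        raise ValueError(f"participant {bad!r}: zero variance in reports, "
                         "cannot z-score")
    out[out_col] = np.nan
    out.loc[used, out_col] = (vals - g.transform("mean")) \
        / g.transform("std", ddof=ddof)
    return out


def zscore_metrics(table: pd.DataFrame,
                   metric_cols: tuple[str, ...] = ("peakGFR1", "peakLFR1"),
                   valid_col: str = "force_valid",
                   ddof: int = 1) -> pd.DataFrame:
    """Per-participant z-scores of force metrics (columns ``z_<metric>``).

    Only trials valid for the force analysis enter the mean/SD; invalid
    trials are left unscored.
    """
    out = table.copy()
    valid = (out[valid_col].astype(bool) if valid_col in out.columns
             else pd.Series(True, index=out.index))
    for col in metric_cols:
        zcol = f"z_{col}"
        usable = valid & out[col].notna()
        vals = out.loc[usable, col].astype(float)
        g = vals.groupby(out.loc[usable, "participant"])
        sd = g.std(ddof=ddof)
        if (~np.isfinite(sd) | (sd == 0)).any():
            bad = sd.index[~np.isfinite(sd) | (sd == 0)][0]
            raise ValueError(f"participant {bad!r}: zero variance in {col}")
        out[zcol] = np.nan
        out.loc[usable, zcol] = (vals - g.transform("mean")) \
            / g.transform("std", ddof=ddof)
    return out


def condition_means(table: pd.DataFrame,
                    percept_col: str = "z_estimate",
                    metric_cols: tuple[str, ...] = ("peakGFR1", "peakLFR1", "lpd"),
                    require_complete: bool = True) -> pd.DataFrame:
    """Per participant x condition means of percepts and force metrics.

    Percept means average over perceptually valid analyzable trials,
    metric means over force-valid analyzable trials.  Returns a wide table
    with one row per participant x condition, the group label (if
    present), ``n_trials`` (percept count) and ``n_force_trials``.

    Raises
    ------
    ValueError
        If ``require_complete`` and any participant misses one of the 8
        conditions entirely (the offending cells are listed).
    """
    t = table[table["analyzable"].astype(bool)]
    pv = (t["perceptual_valid"].astype(bool) if "perceptual_valid" in t.columns
          else pd.Series(True, index=t.index))
    fv = (t["force_valid"].astype(bool) if "force_valid" in t.columns
          else pd.Series(True, index=t.index))
    key = ["participant", "condition"]

    pt = t[pv]
    agg = {"n_trials": ("condition", "size")}
    if percept_col in t.columns:
        agg[f"mean_{percept_col}"] = (percept_col, "mean")
    out = pt.groupby(key).agg(**agg)

    fagg = {"n_force_trials": ("condition", "size")}
    fagg.update({f"mean_{c}": (c, "mean") for c in metric_cols
                 if c in t.columns})
    out = out.join(t[fv].groupby(key).agg(**fagg), how="outer")
    if "group" in t.columns:
        out = out.join(t.groupby(key)["group"].first(), how="left")
    for col in ("n_trials", "n_force_trials"):
        out[col] = out[col].fillna(0).astype(int)

    if require_complete:
        participants = t["participant"].unique()
        full = pd.MultiIndex.from_product([sorted(participants), CONDITIONS],
                                          names=key)
        missing = sorted(full.difference(out.index))
        missing += list(out.index[out["n_trials"] == 0])
        if missing:
            raise ValueError(f"empty participant x condition cells: {missing}")
    out = out.reset_index()
    front = ["participant", "condition"] + (["group"] if "group" in out else [])
    out = out[front + [c for c in out.columns if c not in front]]
    return out.sort_values(key, kind="stable").reset_index(drop=True)


def bias_contrasts(summaries: pd.DataFrame,
                   percept_col: str = "mean_z_estimate",
                   force_cols: tuple[str, ...] = ("mean_z_peakGFR1", "mean_z_peakLFR1"),
                   ) -> pd.DataFrame:
    """Previous-weight contrasts per participant x (current weight, hand order).

    ``perceptual_bias``  = mean z(previous light) - mean z(previous heavy);
    positive values are a bias in the expected direction (an object feels
    heavier after a light lift).  ``force_diff_*`` = previous heavy -
    previous light of the per-participant z-scored peaks; positive values
    are the expected sensorimotor-memory effect (higher planned rates
    after a heavy lift).  Contrasts are plain differences of condition
    means, hence linear in the inputs.
    """
    need = {c for c in CONDITIONS}
    rows = []
    for pid, sub in summaries.groupby("participant", sort=False):
        have = set(sub["condition"])
        if not need <= have:
            raise ValueError(f"participant {pid!r} misses conditions {need - have}")
        s = sub.set_index("condition")
        for cur, cur_code in (("light", "L"), ("heavy", "H")):
            for order, code in (("same", "S"), ("different", "D")):
                prev_l = f"L{cur_code}{code}"
                prev_h = f"H{cur_code}{code}"
                row = {
                    "participant": pid,
                    "current_weight": cur_code,
                    "hand_order": order,
                }
                if "group" in sub.columns:
                    row["group"] = sub["group"].iloc[0]
                if percept_col in s.columns:
                    row["perceptual_bias"] = (s.loc[prev_l, percept_col]
                                              - s.loc[prev_h, percept_col])
                for col in force_cols:
                    if col in s.columns:
                        short = col.replace("mean_z_peak", "force_diff_").replace("1", "")
                        row[short] = s.loc[prev_h, col] - s.loc[prev_l, col]
                rows.append(row)
    return pd.DataFrame(rows)
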