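"""End-to-end pipeline: simulate -> extract -> zscore -> summarize -> stats -> report.

A run is driven by a :class:`RunConfig` (design spec, simulator
parameters, extraction thresholds, seed) and writes a reproducible
results bundle into one directory:

    trials.tsv            per-trial table with labels, metrics, reports
    summaries.tsv         per participant x condition means
    contrasts.tsv         previous-weight contrasts (bias / memory effect)
    anova_<dv>.tsv        split-plot ANOVA tables (4 dependent variables)
    posthoc.tsv           Bonferroni post-hocs for the previous-hand x
                          previous-weight decomposition
    ar1_<dv>.tsv          AR(1) mixed-model Wald tables for the
                          perception/force coupling
    correlations.tsv      per-condition perception/force correlations
    summary_<dv>.png      plain per-condition summary figure
    manifest.json         config hash, package/library versions, seed

Identical config + seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignSpec
from .kinetics import KineticsConfig, apply_exclusions, extract_metrics
from .perception import (bias_contrasts, condition_means, zscore_by_participant,
                         zscore_metrics)
from .anova import MixedAnovaResults, condition_correlations, mixed_anova, \
    posthoc_ttests
from .ar1 import AR1Regression
from .simulate import Cohort, SimParams, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "attach_metrics", "anova_tables",
           "load_config"]

DEPENDENTS = {
    "z_estimate": "mean_z_estimate",
    "peakGFR1": "mean_peakGFR1",
    "peakLFR1": "mean_peakLFR1",
    "lpd": "mean_lpd",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    design: DesignSpec = field(default_factory=DesignSpec)
    sim: SimParams = field(default_factory=SimParams)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    group_sizes: tuple[int, int, int, int] = (20, 20, 10, 10)
    seed: int = 0
    trace_extraction: bool = False   # re-extract metrics from synthesized traces
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = DesignSpec(**d["design"])
        if "sim" in d:
            d["sim"] = SimParams(**d["sim"])
        if "kinetics" in d:
            d["kinetics"] = KineticsConfig(**d["kinetics"])
        if "group_sizes" in d:
            d["group_sizes"] = tuple(d["group_sizes"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def attach_metrics(cohort: Cohort, config: KineticsConfig | None = None,
                   ) -> pd.DataFrame:
    """Fill the metric columns of a traces-mode cohort by extraction.

    Regenerates every trial's force trace and runs the kinetics pipeline;
    trials whose extraction fails are flagged via ``error_not_lifted`` so
    the standard exclusion rules pick them up.
    """
    trials = cohort.trials.copy()
    config = config or KineticsConfig()
    peak_g = np.full(len(trials), np.nan)
    peak_l = np.full(len(trials), np.nan)
    lpd = np.full(len(trials), np.nan)
    fallback = np.zeros(len(trials), dtype=bool)
    failed = np.zeros(len(trials), dtype=bool)
    for k, row in enumerate(trials.itertuples(index=False)):
        trace, _ = cohort.trace(row.participant, row.index)
        m = extract_metrics(trace, row.W_true, config)
        if m.valid:
            peak_g[k], peak_l[k], lpd[k] = m.peakGFR1, m.peakLFR1, m.lpd
            fallback[k] = m.gfr_used_max_fallback or m.lfr_used_max_fallback
        else:
            failed[k] = True
    trials["peakGFR1"] = peak_g
    trials["peakLFR1"] = peak_l
    trials["lpd"] = lpd
    trials["used_max_fallback"] = fallback
    trials["error_not_lifted"] = trials.get(
        "error_not_lifted", pd.Series(False, index=trials.index)) | failed
    return trials


def summarize(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score reports and metrics, then build condition means and contrasts."""
    t = apply_exclusions(trials)
    t = zscore_by_participant(t)
    t = zscore_metrics(t)
    summaries = condition_means(
        t, metric_cols=("peakGFR1", "peakLFR1", "lpd",
                        "z_peakGFR1", "z_peakLFR1"))
    contrasts = bias_contrasts(summaries)
    return summaries, contrasts


def _with_design_columns(summaries: pd.DataFrame) -> pd.DataFrame:
    s = summaries.copy()
    s["previous_weight"] = s["condition"].str[0]
    s["current_weight_f"] = s["condition"].str[1]
    s["previous_hand"] = np.where(s["condition"].str[2] == "S",
                                  "same", "different")
    gh = s["group"].str.split("-", expand=True)
    s["handedness"] = np.where(gh[0] == "RH", "right", "left")
    s["current_hand"] = gh[1]
    return s


def anova_tables(summaries: pd.DataFrame) -> dict[str, MixedAnovaResults]:
    """The four split-plot ANOVAs (percepts, peakGFR1, peakLFR1, LPD)."""
    s = _with_design_columns(summaries)
    out = {}
    for dv, col in DEPENDENTS.items():
        if col not in s.columns or s[col].isna().all():
            continue
        out[dv] = mixed_anova(
            s, dv=col, subject="participant",
            within=("previous_hand", "previous_weight", "current_weight_f"),
            between=("handedness", "current_hand"))
    return out


def previous_weight_posthocs(summaries: pd.DataFrame, dv_col: str,
                             ) -> pd.DataFrame:
    """Simple-effect family decomposing previous hand x previous weight.

    Four paired comparisons (previous light vs heavy within each hand
    order; same vs different hand within each previous weight),
    Bonferroni-corrected as one family.
    """
    s = _with_design_columns(summaries)
    cell = s.pivot_table(index="participant", values=dv_col,
                         columns=["previous_hand", "previous_weight"],
                         aggfunc="mean")
    comps = [
        ("prevL vs prevH | same hand", cell[("same", "L")], cell[("same", "H")], True),
        ("prevL vs prevH | different hand", cell[("different", "L")],
         cell[("different", "H")], True),
        ("same vs different | prev light", cell[("same", "L")],
         cell[("different", "L")], True),
        ("same vs different | prev heavy", cell[("same", "H")],
         cell[("different", "H")], True),
    ]
    return posthoc_ttests(comps)


def ar1_bias_model(contrasts: pd.DataFrame, force_col: str) -> pd.DataFrame:
    """Perception/force coupling on previous-weight differences.

    Perceptual bias as response, the force-scaling difference as
    covariate, the design factors (handedness, current hand, previous
    hand, current weight) as fixed effects, AR(1) errors within
    participant over the four strata.
    """
    c = contrasts.copy()
    gh = c["group"].str.split("-", expand=True)
    c["handedness"] = np.where(gh[0] == "RH", "right", "left")
    c["current_hand_f"] = gh[1]
    c = c.sort_values(["participant", "current_weight", "hand_order"],
                      kind="stable")
    terms = [("handedness",), ("current_hand_f",), ("hand_order",),
             ("current_weight",), (force_col,),
             ("handedness", force_col), ("current_hand_f", force_col),
             ("hand_order", force_col), ("current_weight", force_col)]
    model = AR1Regression.from_dataframe(
        c, dv="perceptual_bias", terms=terms, groups="participant")
    res = model.fit()
    table = res.wald_table().reset_index()
    table.insert(0, "rho", res.rho)
    return table


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def plot_condition_summary(summaries: pd.DataFrame, dv_col: str, path) -> None:
    """Per-condition group means with SEM bars, one panel per current weight."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = _with_design_columns(summaries)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, cw in zip(axes, ("L", "H")):
        sub = s[s["current_weight_f"] == cw]
        for (grp, ph), block in sub.groupby(["group", "previous_hand"]):
            agg = block.groupby("previous_weight")[dv_col].agg(["mean", "sem"])
            agg = agg.reindex(["L", "H"])
            style = "-" if ph == "same" else "--"
            ax.errorbar(["L", "H"], agg["mean"], yerr=agg["sem"],
                        fmt=style, marker="o", label=f"{grp} {ph}")
        ax.set_title(f"current {'light' if cw == 'L' else 'heavy'}")
        ax.set_xlabel("previous weight")
    axes[0].set_ylabel(dv_col)
    axes[1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write the results bundle to ``outdir``.

    Returns a dict with the in-memory artefacts (trial table, summaries,
    contrasts, ANOVA results, post-hoc/AR(1)/correlation tables).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    mode = "traces" if config.trace_extraction else "analytic"
    cohort = simulate_cohort(spec=config.design, group_sizes=config.group_sizes,
                             params=config.sim, seed=config.seed, mode=mode)
    if config.trace_extraction:
        trials = attach_metrics(cohort, config.kinetics)
    else:
        trials = cohort.trials.copy()

    summaries, contrasts = summarize(trials)
    _write(trials, out / "trials.tsv")
    _write(summaries, out / "summaries.tsv")
    _write(contrasts, out / "contrasts.tsv")

    anovas = anova_tables(summaries)
    for dv, res in anovas.items():
        _write(res.table.reset_index(), out / f"anova_{dv}.tsv")

    posthocs = []
    for dv, col in DEPENDENTS.items():
        if dv in anovas:
            ph = previous_weight_posthocs(summaries, col)
            ph.insert(0, "dependent", dv)
            posthocs.append(ph)
    posthoc = pd.concat(posthocs, ignore_index=True)
    _write(posthoc, out / "posthoc.tsv")

    ar1_tables = {}
    for force in ("force_diff_GFR", "force_diff_LFR"):
        tab = ar1_bias_model(contrasts, force)
        ar1_tables[force] = tab
        _write(tab, out / f"ar1_{force}.tsv")

    corr = []
    for force in ("force_diff_GFR", "force_diff_LFR"):
        c = condition_correlations(contrasts, force)
        c.insert(0, "force_parameter", force)
        corr.append(c)
    correlations = pd.concat(corr, ignore_index=True)
    _write(correlations, out / "correlations.tsv")

    if config.make_plots:
        for dv, col in DEPENDENTS.items():
            if dv in anovas:
                plot_condition_summary(summaries, col,
                                       out / f"summary_{dv}.png")

    manifest = {
        "package": "gripshift",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "versions": {m.__name__: m.__version__
                     for m in (np, pd)},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {"trials": trials, "summaries": summaries, "contrasts": contrasts,
            "anovas": anovas, "posthoc": posthoc, "ar1": ar1_tables,
            "correlations": correlations, "manifest": manifest}
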