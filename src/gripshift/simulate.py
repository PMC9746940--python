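"""Synthetic grip-lift experiments with planted, analytically known effects.

The generator emulates the study conditions end to end: four participant
groups (handedness x analysis hand, 20/20/10/10 participants), each with
their own constrained 151-trial sequence, per-trial fingertip-force
traces and magnitude-estimation reports.  Every measured quantity has a
closed-form ground truth so that pipeline recovery can be tested without
external data.

Force model
-----------
The planned load-force rate follows a single smooth pulse,
``LFR(tau) = R1 sin^2(pi tau / T1)``, whose integral is the planned load
``W_plan = W_exp + overshoot`` (one plans to exceed the expected weight —
otherwise the object would never accelerate upward).  The planned peak
rate scales with the expected weight, ``R1 = alpha * W_exp``.  The
expected weight mixes sensorimotor memory of the previous lift with a
baseline prior:

    W_exp = lam_eff * W_prev + (1 - lam_eff) * W_baseline,
    lam_eff = lambda_mem * (gamma_transfer if hand changed else 1).

If the plan undershoots (``W_exp < W_true``) a slower corrective pulse
loads the remainder, lengthening the loading phase — the classic
signature of lifting a heavy object after a light one.  Grip force tracks
load force linearly (``GF = gf_margin + gf_ratio * LF``) after its own
gentle pre-loading ramp from contact.

Percept model
-------------
Reports are a participant-specific positive affine transform (the
self-chosen magnitude-estimation scale) of a latent heaviness

    latent = beta * log(W_true / W_ref) + delta_right * [right hand]
             - kappa_bias * [prev heavy] * [same hand] * gate + noise,

where the gate mirrors the planted group asymmetry: right-handed
participants carry the sequential bias for light and heavy current
objects, left-handed participants only for light ones.  With the default
``beta`` and report noise the latent is approximately in z-units, so
``kappa_bias`` is approximately the planted bias magnitude after
pipeline z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .design import (DesignSpec, GROUPS, analysis_hand, handedness,
                     generate_sequence, label_trials, sequence_frame,
                     sensor_weight, LIGHT, HEAVY, DUMMY, RIGHT)
from .kinetics import AXES, ForceTrace

__all__ = ["SimParams", "LoadingProfile", "simulate_trace",
           "simulate_percept", "simulate_cohort", "Cohort", "GROUP_ORDER"]

GROUP_ORDER = ("RH-right", "RH-left", "LH-right", "LH-left")


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the synthetic cohort.

    Rates are in N/s per N (``alpha``), weights in N, durations in s,
    percept quantities in approximate z-units.  Defaults are chosen so
    that simulated first-rate peaks sit in the tens of N/s and loading
    phases last a few hundred ms, the ranges typical of precision-grip
    lifts of 2-6.5 N objects, with planted effect sizes large relative to
    their noise, as in the study this design emulates.
    """

    # force plan
    alpha: float = 8.0                 # planned peak rate gain (N/s)/N
    lambda_mem: float = 0.4            # sensorimotor-memory weight in [0, 1]
    gamma_transfer: float = 1.0        # transfer multiplier on hand change [0, 1]
    overshoot: float = 0.4             # planned load surplus (N)
    gf_ratio: float = 0.7              # GF/LF coupling
    gf_margin: float = 0.2             # grip-force safety margin (N)
    gf_preload: float = 0.2            # grip pre-ramp duration (s)
    # percept plan
    kappa_bias: float = 0.35           # same-hand sequential bias (z-units)
    delta_right: float = 0.15          # right-hand heaviness offset (z-units)
    beta: float = 1.8                  # psychophysical exponent (log-log slope)
    # noise / heterogeneity
    noise_force: float = 0.02          # per-channel sensor noise SD (N)
    noise_rate: float = 0.10           # trial-level planned-rate lognormal SD
    noise_meas: float = 0.03           # metric measurement lognormal SD
    noise_lpd: float = 0.010           # LPD measurement noise SD (s)
    noise_report: float = 0.30         # latent percept noise SD (z-units)
    sd_alpha: float = 0.12             # participant lognormal SD of alpha
    sd_gf_ratio: float = 0.10          # participant lognormal SD of gf_ratio
    sd_lambda: float = 0.08            # participant SD of lambda_mem
    # error injection (per-trial probabilities)
    p_procedure_error: float = 0.005
    p_force_error: float = 0.010
    # bookkeeping
    sample_rate: float = 1000.0
    rest: float = 0.2                  # pre-contact baseline (s)
    hold: float = 0.3                  # post-lift-off hold (s)

    def __post_init__(self) -> None:
        for name in ("lambda_mem", "gamma_transfer"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("p_procedure_error", "p_force_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")
        positives = ("alpha", "overshoot", "gf_ratio", "gf_preload",
                     "sample_rate", "rest", "hold")
        if any(getattr(self, n) <= 0 for n in positives):
            raise ValueError("scale parameters must be positive")
        nonneg = ("gf_margin", "kappa_bias", "noise_force", "noise_rate",
                  "noise_meas", "noise_lpd", "noise_report", "sd_alpha",
                  "sd_gf_ratio", "sd_lambda")
        if any(getattr(self, n) < 0 for n in nonneg):
            raise ValueError("variance parameters must be non-negative")

    def baseline_weight(self, spec: DesignSpec) -> float:
        """Expected weight with no memory: midpoint of light/heavy weights."""
        return 0.5 * (spec.object_weight(LIGHT) + spec.object_weight(HEAVY))


# ---------------------------------------------------------------------------
# loading profile (closed form)
# ---------------------------------------------------------------------------

def _pulse_cdf(u: np.ndarray | float):
    """Integral of the unit sin^2 pulse: fraction loaded at phase fraction u."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


# monotone inverse of _pulse_cdf on a fine grid (vectorized via interp)
_U_GRID = np.linspace(0.0, 1.0, 4001)
_CDF_GRID = _pulse_cdf(_U_GRID)


def _pulse_inv(q, precise: bool = False):
    """Phase fraction at which the unit pulse has loaded fraction ``q``."""
    if precise:
        return brentq(lambda u: _pulse_cdf(u) - q, 0.0, 1.0, xtol=1e-12)
    return np.interp(q, _CDF_GRID, _U_GRID)


@dataclass(frozen=True)
class LoadingProfile:
    """Noise-free load-force profile of one lift, in closed form.

    Time ``tau`` is measured from load-force onset start (tau = 0).
    Phase 1 loads ``w_plan`` with peak rate ``r1`` over ``t1`` seconds;
    an optional corrective phase 2 loads the remaining
    ``w_final - w_plan`` with peak rate ``r2`` over ``t2`` seconds.
    """

    w_true: float
    w_plan: float
    r1: float
    w_final: float
    r2: float = 0.0

    @property
    def t1(self) -> float:
        return 2.0 * self.w_plan / self.r1

    @property
    def t2(self) -> float:
        extra = self.w_final - self.w_plan
        return 2.0 * extra / self.r2 if extra > 0 else 0.0

    @property
    def duration(self) -> float:
        return self.t1 + self.t2

    def lf(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, float)
        out = self.w_plan * _pulse_cdf(tau / self.t1)
        if self.t2 > 0:
            out = out + (self.w_final - self.w_plan) * _pulse_cdf(
                (tau - self.t1) / self.t2)
        return out

    def lfr(self, tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, float)
        in1 = (tau >= 0) & (tau <= self.t1)
        out = np.where(in1, self.r1 * np.sin(np.pi * np.clip(tau, 0, self.t1)
                                             / self.t1) ** 2, 0.0)
        if self.t2 > 0:
            in2 = (tau > self.t1) & (tau <= self.t1 + self.t2)
            out = out + np.where(
                in2, self.r2 * np.sin(np.pi * np.clip(tau - self.t1, 0, self.t2)
                                      / self.t2) ** 2, 0.0)
        return out

    def crossing(self, level: float, precise: bool = True) -> float:
        """First time LF reaches ``level`` (requires level <= w_final)."""
        if level > self.w_final:
            raise ValueError("profile never reaches the requested level")
        if level <= self.w_plan:
            return self.t1 * _pulse_inv(level / self.w_plan, precise)
        frac = (level - self.w_plan) / (self.w_final - self.w_plan)
        return self.t1 + self.t2 * _pulse_inv(frac, precise)

    def analytic_lpd(self, onset_threshold: float = 0.1,
                     precise: bool = True) -> float:
        """Loading-phase duration between LF onset and lift-off."""
        return (self.crossing(self.w_true, precise)
                - self.crossing(onset_threshold, precise))


def make_profile(w_true: float, w_exp: float, params: SimParams,
                 r1: float | None = None) -> LoadingProfile:
    """Loading profile for an expected weight ``w_exp`` and true weight ``w_true``.

    ``r1`` overrides the deterministic planned peak rate
    ``alpha * w_exp`` (used to inject trial-level rate variability).
    """
    if w_true <= 0 or w_exp <= 0:
        raise ValueError("weights must be positive")
    r1 = float(r1) if r1 is not None else params.alpha * w_exp
    w_plan = w_exp + params.overshoot
    w_final = max(w_true, w_exp) + params.overshoot
    if w_final > w_plan:   # corrective phase needed
        extra = w_final - w_plan
        r2 = min(0.5 * params.alpha * extra + 1.0, 0.8 * r1)
        return LoadingProfile(w_true=w_true, w_plan=w_plan, r1=r1,
                              w_final=w_final, r2=r2)
    return LoadingProfile(w_true=w_true, w_plan=w_plan, r1=r1, w_final=w_final)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def simulate_trace(w_true: float, w_exp: float, params: SimParams | None = None,
                   seed: int | np.random.Generator = 0,
                   r1: float | None = None) -> tuple[ForceTrace, dict]:
    """Synthesize one trial's two-sensor force trace plus its ground truth.

    Timeline: ``rest`` seconds of baseline, a grip pre-ramp of
    ``gf_preload`` seconds up to ``gf_margin`` N, the load phase(s), and a
    ``hold`` period at the final load.  The two sensors share the load
    symmetrically (each vertical channel carries LF/2; both grip-normal
    channels equal GF).  Additive Gaussian sensor noise on every channel.

    Returns the trace and a dict with the planted quantities
    (``r1``, ``peakGFR1``, absolute ``t_onset``/``t_liftoff``, ``lpd``).
    """
    params = params or SimParams()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    profile = make_profile(w_true, w_exp, params, r1=r1)

    fs = params.sample_rate
    t0 = params.rest + params.gf_preload           # load onset start
    total = t0 + profile.duration + params.hold
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs

    lf = np.where(t >= t0, profile.lf(t - t0), 0.0)
    lf = np.where(t >= t0 + profile.duration, profile.w_final, lf)

    # grip force: pre-ramp from rest, then margin + coupling to LF
    u = (t - params.rest) / params.gf_preload
    gf = params.gf_margin * _pulse_cdf(u)
    gf = gf + params.gf_ratio * lf

    noise = lambda: rng.normal(0.0, params.noise_force, size=n)
    zeros = np.zeros(n)
    thumb = np.column_stack([gf + noise(), zeros + noise(), lf / 2 + noise()])
    index = np.column_stack([gf + noise(), zeros + noise(), lf / 2 + noise()])
    trace = ForceTrace(thumb=thumb, index=index, sample_rate=fs)

    truth = {
        "w_true": w_true,
        "w_exp": w_exp,
        "r1": profile.r1,
        "peakGFR1": params.gf_ratio * profile.r1,
        "t_onset": t0 + profile.crossing(0.1),
        "t_liftoff": t0 + profile.crossing(w_true),
        "lpd": profile.analytic_lpd(),
        "corrective": profile.t2 > 0,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# percepts
# ---------------------------------------------------------------------------

def simulate_percept(w_true: float, *, prev_weight: str, hand_order: str,
                     current_hand: str, current_weight: str, group: str,
                     params: SimParams | None = None,
                     seed: int | np.random.Generator = 0,
                     w_ref: float | None = None,
                     noise: float | None = None) -> float:
    """Latent heaviness (approximate z-units) for one trial.

    The sequential bias fires only on same-hand trials following a heavy
    lift, gated by handedness: right-handers show it for light and heavy
    current objects, left-handers for light only.
    """
    params = params or SimParams()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w_ref = w_ref if w_ref is not None else np.sqrt(
        sensor_weight(105.0) * sensor_weight(525.0))
    gate = 0.0
    if current_weight in ("L", "H"):
        if handedness(group) == "right":
            gate = 1.0
        else:
            gate = 1.0 if current_weight == "L" else 0.0
    latent = params.beta * np.log(w_true / w_ref)
    latent += params.delta_right * (1.0 if current_hand == RIGHT else 0.0)
    if prev_weight == "H" and hand_order == "same":
        latent -= params.kappa_bias * gate
    sd = params.noise_report if noise is None else noise
    return float(latent + rng.normal(0.0, sd))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

_PROC_ERRORS = ("error_wrong_object", "error_wrong_hand", "error_not_lifted")
_FORCE_ERRORS = ("error_double_lift", "error_premature_lift",
                 "error_push_before_lift")


@dataclass
class Cohort:
    """A complete synthetic experiment: trial table plus regenerable traces.

    ``trials`` holds one row per trial with design labels, generative
    ground truth (``W_exp``, ``R1``, ``true_lpd``), observed metrics and
    reports, and error flags.  In ``analytic`` mode the observed metrics
    are emitted directly from the generative model; in ``traces`` mode
    they are left NaN and :meth:`trace` regenerates any trial's raw force
    trace deterministically for the extraction pipeline.
    """

    trials: pd.DataFrame
    params: SimParams
    spec: DesignSpec
    group_sizes: tuple[int, int, int, int]
    seed: int
    mode: str

    def trace(self, participant: str, index: int) -> tuple[ForceTrace, dict]:
        row = self.trials[(self.trials["participant"] == participant)
                          & (self.trials["index"] == index)]
        if row.empty:
            raise KeyError((participant, index))
        r = row.iloc[0]
        return simulate_trace(r["W_true"], r["W_exp"], self.params,
                              seed=np.random.default_rng(int(r["trial_seed"])),
                              r1=r["R1"])

    def iter_traces(self):
        for (pid, idx) in self.trials[["participant", "index"]].itertuples(
                index=False):
            yield pid, idx, *self.trace(pid, idx)


def simulate_cohort(spec: DesignSpec | None = None,
                    group_sizes: tuple[int, int, int, int] = (20, 20, 10, 10),
                    params: SimParams | None = None,
                    seed: int = 0,
                    mode: str = "analytic") -> Cohort:
    """Simulate a full cohort across the four handedness x hand groups.

    Each participant gets an independent constrained trial sequence,
    participant-level parameter heterogeneity, per-trial planted force
    metrics and percept reports, and (at the configured rates) injected
    procedure/lifting errors.  ``mode='analytic'`` emits observed metrics
    directly from the generative ground truth; ``mode='traces'`` leaves
    them NaN for downstream extraction from regenerated traces.
    """
    spec = spec or DesignSpec()
    params = params or SimParams()
    if mode not in ("analytic", "traces"):
        raise ValueError("mode must be 'analytic' or 'traces'")
    if len(group_sizes) != len(GROUP_ORDER):
        raise ValueError("need one size per group")

    root = np.random.SeedSequence(seed)
    w_base = params.baseline_weight(spec)
    w_ref = np.sqrt(spec.object_weight(LIGHT) * spec.object_weight(HEAVY))
    wmap = {obj: spec.object_weight(obj) for obj in (LIGHT, HEAVY, DUMMY)}

    frames = []
    pnum = 0
    for group, size in zip(GROUP_ORDER, group_sizes):
        gspec = replace(spec, group=group)
        for _ in range(size):
            pnum += 1
            pid = f"P{pnum:03d}"
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            seq_seed = int(rng.integers(2 ** 31))
            sequence = generate_sequence(gspec, seed=seq_seed)
            labels = label_trials(sequence, group)
            frame = sequence_frame(sequence, labels)
            n = len(frame)

            # participant-level heterogeneity
            alpha_i = params.alpha * np.exp(rng.normal(0, params.sd_alpha))
            gfr_i = params.gf_ratio * np.exp(rng.normal(0, params.sd_gf_ratio))
            lam_i = float(np.clip(params.lambda_mem
                                  + rng.normal(0, params.sd_lambda), 0.0, 1.0))
            scale_a = rng.uniform(5.0, 20.0)
            scale_b = rng.uniform(60.0, 100.0)

            objs = frame["object"].to_numpy()
            hands = frame["cued_hand"].to_numpy()
            w_true = np.array([wmap[o] for o in objs])
            w_prev = np.roll(w_true, 1)
            same = np.concatenate([[True], hands[1:] == hands[:-1]])
            lam_eff = lam_i * np.where(same, 1.0, params.gamma_transfer)
            w_exp = lam_eff * w_prev + (1.0 - lam_eff) * w_base
            w_exp[0] = w_base

            r1 = alpha_i * w_exp * np.exp(rng.normal(0, params.noise_rate, n))

            # closed-form loading-phase durations (vectorized pulse inversion)
            w_plan = w_exp + params.overshoot
            w_final = np.maximum(w_true, w_exp) + params.overshoot
            t1 = 2.0 * w_plan / r1
            extra = w_final - w_plan
            has2 = extra > 1e-12
            r2 = np.minimum(0.5 * params.alpha * extra + 1.0, 0.8 * r1)
            t2 = np.where(has2, 2.0 * extra / np.maximum(r2, 1e-9), 0.0)
            t_on = t1 * _pulse_inv(0.1 / w_plan)
            in1 = w_true <= w_plan
            t_lo = np.where(
                in1, t1 * _pulse_inv(np.minimum(w_true / w_plan, 1.0)),
                t1 + t2 * _pulse_inv(
                    np.clip((w_true - w_plan) / np.where(has2, extra, 1.0),
                            0.0, 1.0)))
            true_lpd = t_lo - t_on

            # percepts
            gate = np.zeros(n)
            hnd = handedness(group)
            cw = frame["current_weight"].to_numpy()
            gate[(cw == "L")] = 1.0
            if hnd == "right":
                gate[(cw == "H")] = 1.0
            prev_w = frame["previous_weight"].to_numpy()
            order = frame["hand_order"].to_numpy()
            latent = params.beta * np.log(w_true / w_ref)
            latent += params.delta_right * (hands == RIGHT)
            latent -= params.kappa_bias * gate * ((prev_w == "H")
                                                  & (order == "same"))
            latent += rng.normal(0, params.noise_report, n)
            reports = scale_a * latent + scale_b

            frame["participant"] = pid
            frame["group"] = group
            frame["handedness"] = hnd
            frame["current_hand"] = analysis_hand(group)
            frame["W_true"] = w_true
            frame["W_exp"] = w_exp
            frame["R1"] = r1
            frame["true_lpd"] = true_lpd
            frame["raw_estimate"] = reports
            frame["trial_seed"] = rng.integers(2 ** 31, size=n)

            if mode == "analytic":
                frame["peakLFR1"] = r1 * np.exp(
                    rng.normal(0, params.noise_meas, n))
                frame["peakGFR1"] = gfr_i * r1 * np.exp(
                    rng.normal(0, params.noise_meas, n))
                frame["lpd"] = np.maximum(
                    true_lpd + rng.normal(0, params.noise_lpd, n), 0.02)
            else:
                frame["peakLFR1"] = np.nan
                frame["peakGFR1"] = np.nan
                frame["lpd"] = np.nan

            for col in _PROC_ERRORS + _FORCE_ERRORS:
                frame[col] = False
            kproc = rng.random(n) < params.p_procedure_error
            kforce = rng.random(n) < params.p_force_error
            which_p = rng.integers(len(_PROC_ERRORS), size=n)
            which_f = rng.integers(len(_FORCE_ERRORS), size=n)
            for j, col in enumerate(_PROC_ERRORS):
                frame[col] = kproc & (which_p == j)
            for j, col in enumerate(_FORCE_ERRORS):
                frame[col] = kforce & (which_f == j)

            frames.append(frame)

    trials = pd.concat(frames, ignore_index=True)
    return Cohort(trials=trials, params=params, spec=spec,
                  group_sizes=tuple(group_sizes), seed=seed, mode=mode)
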