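"""Fingertip-force kinetics: from raw two-sensor recordings to lift metrics.

A precision-grip trial is recorded by two 3-axis force sensors (thumb and
index finger) at 1000 Hz.  By convention the z axis is vertical (gravity)
and the x axis is the grip normal (horizontal, into the object).  The load
force LF is the sum of the two vertical components, the grip force GF the
average of the two grip-normal components.  All channels are low-pass
filtered (zero-phase, 2nd-order Butterworth, 15 Hz cut-off) before
combination and differentiation; because both the filter and the channel
combination are linear, the order of those two steps does not matter (this
equivalence is tested).

Per trial we extract:

* ``peakGFR1`` / ``peakLFR1`` — the first peak of the grip/load force rate
  between contact (GF > 0.1 N) and 50 ms after lift-off (LF reaches the
  object weight).  The first peak reflects the predictively planned force;
  to skip contact bumps, the earliest local maximum of at least 30% of the
  window maximum is used, falling back to the window maximum itself.
* ``LPD`` — loading-phase duration, from load-force onset (LF > 0.1 N) to
  lift-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "AXES",
    "ForceTrace",
    "DerivedSeries",
    "LiftEvents",
    "LiftMetrics",
    "KineticsConfig",
    "lowpass_filter",
    "derive_series",
    "detect_events",
    "first_peak_rate",
    "extract_metrics",
    "apply_exclusions",
    "read_trace",
    "write_trace",
]

AXES = ("x", "y", "z")  # x: grip normal, y: spare horizontal, z: vertical
TRACE_COLUMNS = ["t"] + [f"{s}_{a}" for s in ("thumb", "index") for a in AXES]


@dataclass
class KineticsConfig:
    """Thresholds and filter settings for metric extraction (SI units)."""

    contact_threshold: float = 0.1     # N, on GF
    onset_threshold: float = 0.1       # N, on LF
    peak_fraction: float = 0.30        # first-peak acceptance fraction
    window_extension: float = 0.050    # s after lift-off
    filter_cutoff: float = 15.0        # Hz
    filter_order: int = 2              # per pass (bidirectional)

    def __post_init__(self) -> None:
        if not (self.contact_threshold > 0 and self.onset_threshold > 0
                and self.window_extension > 0 and self.filter_cutoff > 0):
            raise ValueError("thresholds must be positive")
        if not 0 < self.peak_fraction <= 1:
            raise ValueError("peak_fraction must lie in (0, 1]")


@dataclass
class ForceTrace:
    """Raw two-sensor, three-axis force recording of one trial.

    ``thumb`` and ``index`` are (n, 3) arrays ordered (x, y, z);
    sampling is uniform at ``sample_rate`` Hz starting at t = 0.
    """

    thumb: np.ndarray
    index: np.ndarray
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.thumb = np.asarray(self.thumb, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        if self.thumb.shape != self.index.shape or self.thumb.ndim != 2 \
                or self.thumb.shape[1] != len(AXES):
            raise ValueError("sensor arrays must both have shape (n, 3)")
        if self.thumb.shape[0] < 0.1 * self.sample_rate:
            raise ValueError("trace shorter than 100 ms")
        if not (np.isfinite(self.thumb).all() and np.isfinite(self.index).all()):
            raise ValueError("non-finite force samples")

    @property
    def n(self) -> int:
        return self.thumb.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.sample_rate

    def channel(self, sensor: str, axis: str) -> np.ndarray:
        arr = {"thumb": self.thumb, "index": self.index}[sensor]
        return arr[:, AXES.index(axis)]

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        for s in ("thumb", "index"):
            for a in AXES:
                data[f"{s}_{a}"] = self.channel(s, a)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ForceTrace":
        missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"trace table misses columns {missing} "
                             "(declared axis convention requires x/y/z per sensor)")
        t = frame["t"].to_numpy(float)
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling grid")
        fs = 1.0 / dt[0] if len(dt) else 1000.0
        thumb = frame[[f"thumb_{a}" for a in AXES]].to_numpy(float)
        index = frame[[f"index_{a}" for a in AXES]].to_numpy(float)
        return cls(thumb=thumb, index=index, sample_rate=fs)


@dataclass
class DerivedSeries:
    """Filtered LF/GF (N) and their time-derivatives (N/s) on one grid."""

    t: np.ndarray
    lf: np.ndarray
    gf: np.ndarray
    lfr: np.ndarray
    gfr: np.ndarray
    sample_rate: float


@dataclass
class LiftEvents:
    t_contact: float
    t_onset: float
    t_liftoff: float
    t_window_end: float
    window_clamped: bool = False


@dataclass
class LiftMetrics:
    peakGFR1: float = np.nan
    peakLFR1: float = np.nan
    lpd: float = np.nan
    t_peak_gfr: float = np.nan
    t_peak_lfr: float = np.nan
    gfr_used_max_fallback: bool = False
    lfr_used_max_fallback: bool = False
    events: LiftEvents | None = None
    valid: bool = False
    invalid_reason: str = "none"   # no_contact / no_liftoff / none


def lowpass_filter(series: np.ndarray, cutoff: float, sample_rate: float,
                   order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    ``order`` is the design order of each pass; the bidirectional
    application squares the magnitude response, giving
    ``|H(f)|^2 = 1 / (1 + (f/fc)^(2*order))`` and no phase distortion.
    """
    series = np.asarray(series, dtype=float)
    nyquist = sample_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, series)


def derive_series(trace: ForceTrace, config: KineticsConfig | None = None) -> DerivedSeries:
    """Filter raw channels, combine into LF/GF and differentiate.

    LF = thumb_z + index_z (vertical), GF = (thumb_x + index_x) / 2 (grip
    normal); rates by central differences on the filtered signals.
    """
    config = config or KineticsConfig()
    filt = lambda x: lowpass_filter(x, config.filter_cutoff, trace.sample_rate,
                                    config.filter_order)
    lf = filt(trace.channel("thumb", "z")) + filt(trace.channel("index", "z"))
    gf = (filt(trace.channel("thumb", "x")) + filt(trace.channel("index", "x"))) / 2.0
    t = trace.t
    lfr = np.gradient(lf, t)
    gfr = np.gradient(gf, t)
    return DerivedSeries(t=t, lf=lf, gf=gf, lfr=lfr, gfr=gfr,
                         sample_rate=trace.sample_rate)


def _first_crossing(x: np.ndarray, threshold: float, strict: bool = True) -> int | None:
    """Index of the first sample exceeding ``threshold`` (left-to-right scan)."""
    mask = x > threshold if strict else x >= threshold
    idx = np.flatnonzero(mask)
    return int(idx[0]) if idx.size else None


def detect_events(series: DerivedSeries, object_weight: float,
                  config: KineticsConfig | None = None) -> tuple[LiftEvents | None, str]:
    """Locate contact, load-force onset and lift-off.

    Contact: first GF > 0.1 N.  Onset: first LF > 0.1 N.  Lift-off: first
    LF >= object weight (the object leaves the support once the load force
    carries its full weight).  The analysis window ends 50 ms after
    lift-off, clamped to the trace end.

    Returns ``(events, reason)`` with ``events`` None and a diagnostic
    reason (``no_contact`` / ``no_liftoff``) when a threshold is never
    crossed.
    """
    config = config or KineticsConfig()
    if object_weight <= 0:
        raise ValueError("object weight must be positive")
    i_contact = _first_crossing(series.gf, config.contact_threshold)
    if i_contact is None:
        return None, "no_contact"
    i_onset = _first_crossing(series.lf, config.onset_threshold)
    i_liftoff = _first_crossing(series.lf, object_weight, strict=False)
    if i_onset is None or i_liftoff is None:
        return None, "no_liftoff"
    t = series.t
    t_end = t[i_liftoff] + config.window_extension
    clamped = t_end > t[-1]
    events = LiftEvents(t_contact=t[i_contact], t_onset=t[i_onset],
                        t_liftoff=t[i_liftoff],
                        t_window_end=min(t_end, t[-1]),
                        window_clamped=bool(clamped))
    return events, "none"


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus report their first sample."""
    peaks, props = signal.find_peaks(x, plateau_size=1)
    return props["left_edges"]


def first_peak_rate(rate: np.ndarray, t: np.ndarray, t_start: float, t_end: float,
                    peak_fraction: float = 0.30) -> tuple[float, float, bool]:
    """First peak of a force-rate signal within ``[t_start, t_end]``.

    Returns the earliest local maximum of at least ``peak_fraction`` times
    the window maximum; if every local maximum before the global maximum is
    smaller than that, the global maximum is returned with the fallback
    flag set.  A window whose only peak is the global maximum returns that
    peak (it is both the first and the maximum peak).
    """
    sel = (t >= t_start) & (t <= t_end)
    if not sel.any():
        raise ValueError("empty peak-search window")
    w = rate[sel]
    tw = t[sel]
    if np.nanmax(w) <= 0:
        raise ValueError("force rate non-positive over the whole window")
    vmax = float(np.max(w))
    peaks = _local_maxima(w)
    # numerical ripples of a flat segment are not peaks of the signal
    peaks = peaks[w[peaks] > 1e-8 * vmax]
    good = peaks[w[peaks] >= peak_fraction * vmax]
    if good.size:
        i = int(good[0])
        # if the earliest qualifying peak is the window maximum itself and
        # smaller peaks preceded it, the 30% rule fell back to the maximum
        fallback = bool((peaks < i).any()) and w[i] == vmax
    else:
        i = int(np.argmax(w))
        # only a genuine fallback if an earlier (too small) peak existed
        fallback = bool(peaks.size)
    return float(w[i]), float(tw[i]), fallback


def extract_metrics(trace: ForceTrace, object_weight: float,
                    config: KineticsConfig | None = None) -> LiftMetrics:
    """Full per-trial pipeline: filter -> combine -> events -> first peaks -> LPD."""
    config = config or KineticsConfig()
    series = derive_series(trace, config)
    events, reason = detect_events(series, object_weight, config)
    if events is None:
        return LiftMetrics(valid=False, invalid_reason=reason)
    gfr_peak, t_gfr, gfr_fb = first_peak_rate(
        series.gfr, series.t, events.t_contact, events.t_window_end,
        config.peak_fraction)
    lfr_peak, t_lfr, lfr_fb = first_peak_rate(
        series.lfr, series.t, events.t_contact, events.t_window_end,
        config.peak_fraction)
    return LiftMetrics(
        peakGFR1=gfr_peak, peakLFR1=lfr_peak,
        lpd=events.t_liftoff - events.t_onset,
        t_peak_gfr=t_gfr, t_peak_lfr=t_lfr,
        gfr_used_max_fallback=gfr_fb, lfr_used_max_fallback=lfr_fb,
        events=events, valid=True, invalid_reason="none")


# ---------------------------------------------------------------------------
# trial-table exclusions
# ---------------------------------------------------------------------------

PROCEDURE_FLAGS = ("error_wrong_object", "error_wrong_hand", "error_not_lifted")
FORCE_FLAGS = ("error_double_lift", "error_premature_lift", "error_push_before_lift")


def apply_exclusions(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``perceptual_valid`` and ``force_valid`` columns to a trial table.

    Procedure errors (wrong object placed, wrong hand used, object not
    lifted) invalidate the trial *and its successor* for both analyses,
    because the intended previous/current order is broken.  Lifting errors
    (double lift, lift before recording started, push before lifting)
    additionally invalidate the trial itself — but only for the force
    analysis; the perceptual report is still usable.

    Missing flag columns are treated as all-False.  Successor propagation
    stays within a participant (``participant`` column, if present).
    """
    out = table.copy()
    for col in PROCEDURE_FLAGS + FORCE_FLAGS:
        if col not in out.columns:
            out[col] = False
    group_key = out["participant"] if "participant" in out.columns else None

    proc = out[list(PROCEDURE_FLAGS)].any(axis=1)
    if group_key is not None:
        follows = proc.groupby(group_key, sort=False).shift(1, fill_value=False)
    else:
        follows = proc.shift(1, fill_value=False)
    out["perceptual_valid"] = ~(proc | follows)
    force_err = out[list(FORCE_FLAGS)].any(axis=1)
    out["force_valid"] = out["perceptual_valid"] & ~force_err
    return out


# ---------------------------------------------------------------------------
# tidy-file IO
# ---------------------------------------------------------------------------

def write_trace(trace: ForceTrace, path) -> None:
    """Write a trace as a tab-separated table (t + 6 force channels, SI units)."""
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trace(path) -> ForceTrace:
    return ForceTrace.from_frame(pd.read_csv(path, sep="\t"))
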