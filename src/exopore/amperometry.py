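"""Amperometric event detection and spike / pre-spike foot statistics.

Detection follows the two-tier selection used in carbon-fiber amperometry of
chromaffin cells: events with peak amplitude above 4 pA and charge between
10 and 5000 fC count toward the event frequency; waveform kinetics
(50-90% rise time, half width) are reported only for events above 7 pA.

The pre-spike foot is delimited by back-extrapolating the line through the
35% and 65% rise points of the main spike to the baseline (takeoff) and by
the earliest preceding point at which the current stays continuously above
baseline + 2 x noise SD.  Fusion-pore flicker is quantified on the current
derivative, additionally low-passed at 1.2 kHz: excursions beyond
+/-6 pA/ms are counted, the fluctuation frequency is that count divided by
the foot duration (kHz when the duration is in ms), and the rms noise is
the SD of the filtered derivative over the foot window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .conditioning import BaselineModel, differentiate, estimate_baseline, lowpass_array
from .trace import Trace

# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass
class FootStats:
    """Pre-spike foot geometry and fusion-pore fluctuation statistics."""

    foot_onset_ms: float
    takeoff_ms: float
    duration_ms: float
    mean_amplitude_pA: float
    charge_fC: float
    eligible_for_fluct: bool
    fluctuation_count: int | None = None
    fluctuation_frequency_kHz: float | None = None
    rms_noise_pA_per_ms: float | None = None

    def __post_init__(self) -> None:
        if self.duration_ms < 0:
            raise ValueError("foot duration must be non-negative")


@dataclass
class AmperometricEvent:
    """One detected event with its waveform parameters."""

    onset_ms: float
    end_ms: float
    peak_time_ms: float
    amplitude_pA: float
    charge_fC: float
    rise_time_50_90_ms: float | None = None
    half_width_ms: float | None = None
    foot: FootStats | None = None
    kinetics_eligible: bool = False
    overlap_rejected: bool = False
    multiple_rise_crossings: bool = False
    foot_rejected_pathological: bool = False
    peak_index: int = 0

    def __post_init__(self) -> None:
        if not self.onset_ms <= self.peak_time_ms <= self.end_ms:
            raise ValueError("event boundaries must bracket the peak")


@dataclass
class EventTable:
    """Ordered, non-overlapping events plus analysis provenance."""

    events: list[AmperometricEvent]
    trace_id: str = ""
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        self.events.sort(key=lambda e: e.onset_ms)
        for a, b in zip(self.events[:-1], self.events[1:]):
            if b.onset_ms < a.end_ms:
                raise ValueError("events overlap")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            row = {
                "onset_ms": e.onset_ms,
                "end_ms": e.end_ms,
                "peak_time_ms": e.peak_time_ms,
                "amplitude_pA": e.amplitude_pA,
                "charge_fC": e.charge_fC,
                "rise_time_50_90_ms": e.rise_time_50_90_ms,
                "half_width_ms": e.half_width_ms,
                "kinetics_eligible": e.kinetics_eligible,
                "overlap_rejected": e.overlap_rejected,
                "foot_duration_ms": e.foot.duration_ms if e.foot else None,
                "foot_amplitude_pA": e.foot.mean_amplitude_pA if e.foot else None,
                "foot_charge_fC": e.foot.charge_fC if e.foot else None,
                "foot_eligible_for_fluct": e.foot.eligible_for_fluct if e.foot else False,
                "fluctuation_count": e.foot.fluctuation_count if e.foot else None,
                "fluctuation_frequency_kHz": (
                    e.foot.fluctuation_frequency_kHz if e.foot else None
                ),
                "rms_noise_pA_per_ms": e.foot.rms_noise_pA_per_ms if e.foot else None,
            }
            rows.append(row)
        df = pd.DataFrame(rows)
        df["trace_id"] = self.trace_id
        df["config"] = self.config.to_json()
        return df

    def to_tsv(self, path: str) -> str:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        return path


# ---------------------------------------------------------------------------
# interpolation helpers
# ---------------------------------------------------------------------------


def _cross_time(x: np.ndarray, i: int, level: float, dt_ms: float, rising: bool) -> float:
    """Linear-interpolated time (ms) where x crosses *level* between i and i+1."""
    x0, x1 = x[i], x[i + 1]
    if x1 == x0:
        return i * dt_ms
    frac = (level - x0) / (x1 - x0)
    frac = min(max(frac, 0.0), 1.0)
    return (i + frac) * dt_ms


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean array."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    diff = np.diff(m)
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(m.size)
    return list(zip(starts, stops))


def count_excursions(d: np.ndarray, threshold: float) -> int:
    """Number of contiguous runs beyond +threshold plus runs below -threshold."""
    return len(_runs(d > threshold)) + len(_runs(d < -threshold))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_events(
    trace: Trace,
    baseline: BaselineModel,
    config: AnalysisConfig | None = None,
) -> EventTable:
    """Detect candidate events and apply the amplitude / charge selection.

    A candidate starts where the baseline-subtracted current stays above
    ``detect_start_k x noise SD`` for at least ``min_above_samples`` samples;
    its onset and end are the outward crossings of the lower
    ``boundary_k x noise SD`` level, sub-sample interpolated.  Candidates are
    kept when the peak exceeds 4 pA and the charge lies in 10-5000 fC.
    Events closer than ``min_gap_ms`` are flagged ``overlap_rejected`` and
    excluded from kinetics.
    """
    config = config or AnalysisConfig()
    if baseline is None:
        raise ValueError("a baseline estimate is required for detection")
    x = trace.samples - baseline.baseline
    dt = trace.dt_ms
    eff_sd = max(baseline.noise_sd, config.noise_floor_pA / config.boundary_k / 2.0)
    trigger = config.detect_start_k * eff_sd
    boundary = max(config.boundary_k * eff_sd, config.noise_floor_pA)
    trigger = max(trigger, boundary)

    above_boundary = x > boundary
    # candidate boundary-level windows around each suprathreshold trigger run
    windows: list[list[int]] = []
    for start, stop in _runs(x > trigger):
        if stop - start < config.min_above_samples:
            continue
        if windows and start <= windows[-1][1]:
            continue  # already inside the previous window
        i0 = start
        while i0 > 0 and above_boundary[i0 - 1]:
            i0 -= 1
        i1 = stop - 1
        while i1 < x.size - 1 and above_boundary[i1 + 1]:
            i1 += 1
        windows.append([i0, i1])
    # a noisy pre-spike foot can dip below the boundary and split an event;
    # windows closer than merge_gap_ms belong to one event
    merge_gap = int(round(config.merge_gap_ms / dt))
    merged: list[list[int]] = []
    for w in windows:
        if merged and w[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], w[1])
        else:
            merged.append(w)

    events: list[AmperometricEvent] = []
    for i0, i1 in merged:
        onset_ms = (
            _cross_time(x, i0 - 1, boundary, dt, rising=True) if i0 > 0 else 0.0
        )
        end_ms = (
            _cross_time(x, i1, boundary, dt, rising=False)
            if i1 < x.size - 1
            else i1 * dt
        )
        seg = slice(i0, i1 + 1)
        pk = i0 + int(np.argmax(x[seg]))
        amplitude = float(x[pk])
        charge = float(np.trapezoid(x[seg], dx=dt))
        if amplitude <= config.min_amplitude_detect_pA:
            continue
        if not config.charge_min_fC <= charge <= config.charge_max_fC:
            continue
        events.append(
            AmperometricEvent(
                onset_ms=onset_ms,
                end_ms=end_ms,
                peak_time_ms=pk * dt,
                amplitude_pA=amplitude,
                charge_fC=charge,
                peak_index=pk,
            )
        )

    for prev, nxt in zip(events[:-1], events[1:]):
        if nxt.onset_ms - prev.end_ms < config.min_gap_ms:
            prev.overlap_rejected = True
            nxt.overlap_rejected = True
    for e in events:
        e.kinetics_eligible = (
            e.amplitude_pA > config.min_amplitude_kinetics_pA and not e.overlap_rejected
        )
    return EventTable(events=events, config=config)


# ---------------------------------------------------------------------------
# spike waveform parameters
# ---------------------------------------------------------------------------


def _rising_crossing(
    x: np.ndarray, i0: int, pk: int, level: float, dt: float
) -> tuple[float | None, bool]:
    """Last upward crossing of *level* before the peak; flags multiples."""
    seg = x[i0 : pk + 1]
    ups = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    if ups.size == 0:
        return None, False
    i = i0 + int(ups[-1])
    return _cross_time(x, i, level, dt, rising=True), ups.size > 1


def _falling_crossing(x: np.ndarray, pk: int, i1: int, level: float, dt: float) -> float | None:
    seg = x[pk : i1 + 1]
    downs = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if downs.size == 0:
        return None
    i = pk + int(downs[0])
    return _cross_time(x, i, level, dt, rising=False)


def spike_parameters(
    trace: Trace,
    baseline: BaselineModel,
    event: AmperometricEvent,
    config: AnalysisConfig | None = None,
) -> AmperometricEvent:
    """Fill 50-90% rise time and half width (FWHM), sub-sample interpolated.

    With fusion-pore flicker running into the spike the rising phase can
    cross a level more than once; the last crossing before the peak is used
    and the event is flagged.
    """
    config = config or AnalysisConfig()
    x = trace.samples - baseline.baseline
    dt = trace.dt_ms
    i0 = max(0, int(np.floor(event.onset_ms / dt)))
    i1 = min(x.size - 1, int(np.ceil(event.end_ms / dt)))
    pk = event.peak_index
    a = event.amplitude_pA

    t50, multi50 = _rising_crossing(x, i0, pk, 0.5 * a, dt)
    t90, multi90 = _rising_crossing(x, i0, pk, 0.9 * a, dt)
    event.multiple_rise_crossings = multi50 or multi90
    if t50 is not None and t90 is not None and t90 >= t50:
        event.rise_time_50_90_ms = t90 - t50
    t50_fall = _falling_crossing(x, pk, i1, 0.5 * a, dt)
    if t50 is not None and t50_fall is not None:
        event.half_width_ms = t50_fall - t50
    return event


# ---------------------------------------------------------------------------
# pre-spike foot
# ---------------------------------------------------------------------------


def detect_foot(
    trace: Trace,
    baseline: BaselineModel,
    event: AmperometricEvent,
    config: AnalysisConfig | None = None,
) -> FootStats | None:
    """Delimit the pre-spike foot of a kinetics-eligible event.

    Takeoff is the baseline intersection of the line through the 35% and 65%
    rise points of the main spike; the foot onset is the earliest preceding
    time at which the current stays continuously above
    baseline + ``foot_k`` x noise SD.  Feet shorter than
    ``min_foot_report_ms`` are not reported.
    """
    config = config or AnalysisConfig()
    x = trace.samples - baseline.baseline
    dt = trace.dt_ms
    i0 = max(0, int(np.floor(event.onset_ms / dt)))
    pk = event.peak_index
    a = event.amplitude_pA

    t_lo, _ = _rising_crossing(x, i0, pk, config.takeoff_lo_frac * a, dt)
    t_hi, _ = _rising_crossing(x, i0, pk, config.takeoff_hi_frac * a, dt)
    if t_lo is None or t_hi is None or t_hi <= t_lo:
        return None
    # back-extrapolate the rising line to the baseline (level 0)
    lo_level = config.takeoff_lo_frac * a
    hi_level = config.takeoff_hi_frac * a
    slope = (hi_level - lo_level) / (t_hi - t_lo)
    takeoff_ms = t_lo - lo_level / slope

    eff_sd = max(baseline.noise_sd, config.noise_floor_pA / config.foot_k)
    level = config.foot_k * eff_sd
    j = int(np.floor(takeoff_ms / dt))
    j = min(max(j, 0), x.size - 1)
    if x[j] <= level:  # pathological geometry: takeoff below the foot level
        event.foot_rejected_pathological = True
        return None
    i = j
    while i > 0 and x[i - 1] > level:
        i -= 1
    foot_onset_ms = _cross_time(x, i - 1, level, dt, rising=True) if i > 0 else 0.0
    if takeoff_ms <= foot_onset_ms:
        event.foot_rejected_pathological = True
        return None
    duration = takeoff_ms - foot_onset_ms
    if duration < config.min_foot_report_ms:
        return None

    k0 = int(np.ceil(foot_onset_ms / dt))
    k1 = int(np.floor(takeoff_ms / dt))
    seg = x[k0 : k1 + 1]
    mean_amp = float(np.mean(seg)) if seg.size else float(x[j])
    charge = float(np.trapezoid(seg, dx=dt)) if seg.size > 1 else 0.0
    return FootStats(
        foot_onset_ms=foot_onset_ms,
        takeoff_ms=takeoff_ms,
        duration_ms=duration,
        mean_amplitude_pA=mean_amp,
        charge_fC=charge,
        eligible_for_fluct=duration > config.min_foot_duration_fluct_ms,
    )


def filtered_derivative(trace: Trace, config: AnalysisConfig | None = None) -> np.ndarray:
    """Current derivative (pA/ms) additionally low-passed at 1.2 kHz."""
    config = config or AnalysisConfig()
    d = differentiate(trace).samples
    return lowpass_array(d, trace.sampling_rate, config.derivative_filter_hz)


def foot_fluctuations(
    trace: Trace,
    foot: FootStats,
    config: AnalysisConfig | None = None,
    deriv: np.ndarray | None = None,
    baseline: BaselineModel | None = None,
) -> FootStats:
    """Count suprathreshold derivative excursions over the foot window.

    Only feet longer than 2 ms qualify.  One excursion is one maximal
    contiguous run beyond +6 pA/ms or below -6 pA/ms of the 1.2 kHz-filtered
    derivative; the fluctuation frequency is the count divided by the foot
    duration.  The rms noise is the SD of the filtered derivative over the
    same window.
    """
    config = config or AnalysisConfig()
    if not foot.eligible_for_fluct:
        return foot
    if deriv is None:
        deriv = filtered_derivative(trace, config)
    dt = trace.dt_ms
    k0 = int(np.ceil(foot.foot_onset_ms / dt))
    k1 = int(np.floor(foot.takeoff_ms / dt))
    if k1 - k0 + 1 < 3:
        return foot
    seg = deriv[k0 : k1 + 1]
    if config.fluct_threshold_mode == "adaptive":
        if baseline is None:
            raise ValueError("adaptive threshold mode needs a derivative noise estimate")
        thr = config.fluct_adaptive_k * baseline.noise_sd
    else:
        thr = config.fluct_threshold_pA_per_ms
    foot.fluctuation_count = count_excursions(seg, thr)
    foot.fluctuation_frequency_kHz = foot.fluctuation_count / foot.duration_ms
    foot.rms_noise_pA_per_ms = float(np.std(seg))
    return foot


# ---------------------------------------------------------------------------
# full per-trace analysis
# ---------------------------------------------------------------------------


def _event_mask(trace: Trace, table: EventTable, margin_ms: float) -> np.ndarray:
    mask = np.zeros(trace.n, dtype=bool)
    dt = trace.dt_ms
    for e in table:
        i0 = max(0, int(np.floor((e.onset_ms - margin_ms) / dt)))
        i1 = min(trace.n, int(np.ceil((e.end_ms + margin_ms) / dt)) + 1)
        mask[i0:i1] = True
    return mask


def analyze_trace(
    trace: Trace,
    config: AnalysisConfig | None = None,
    trace_id: str = "",
) -> EventTable:
    """Two-pass analysis: detect, mask, re-estimate the baseline, re-detect,
    then parameterize every event including its foot and fluctuation
    statistics.  Deterministic for a fixed input and configuration."""
    config = config or AnalysisConfig()
    base1 = estimate_baseline(trace, window_ms=config.baseline_window_ms)
    pass1 = detect_events(trace, base1, config)
    mask = _event_mask(trace, pass1, config.baseline_mask_margin_ms)
    if mask.sum() > 0.9 * trace.n:
        base2 = base1
    else:
        base2 = estimate_baseline(trace, exclusion_mask=mask, window_ms=config.baseline_window_ms)
    table = detect_events(trace, base2, config)

    deriv = filtered_derivative(trace, config)
    for e in table:
        if not e.kinetics_eligible:
            continue
        spike_parameters(trace, base2, e, config)
        foot = detect_foot(trace, base2, e, config)
        if foot is not None:
            foot_fluctuations(trace, foot, config, deriv=deriv)
            e.foot = foot
    table.trace_id = trace_id
    return table
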