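"""Synthetic data with known ground truth for every pipeline stage.

Three generators are provided:

* amperometric traces — a sum of single-vesicle event templates (optional
  pre-spike foot with two-state telegraph flicker, then an exponential
  rise/decay spike) plus Gaussian recording noise shaped by the 2 kHz
  acquisition filter;
* membrane-capacitance traces following the flash-evoked double-exponential
  burst model A0 + A1(1-exp[-t/tau1]) + A2(1-exp[-t/tau2]) + k t with an
  onset delay;
* two-channel punctate images with a controllable colocalized intensity
  fraction.

Every generator is deterministic under a fixed seed and returns the ground
truth needed to score the downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .conditioning import filter_noise_gain, lowpass_array
from .trace import AMPEROMETRY, CAPACITANCE, Trace

# ---------------------------------------------------------------------------
# spike templates
# ---------------------------------------------------------------------------


@dataclass
class SpikeGroundTruth:
    """Parameters of one simulated amperometric event.

    The template is a pre-spike foot (linear onset ramp over ``foot_rise_ms``
    then a plateau of ``foot_amplitude_pA``, optionally multiplied by a
    realized two-state telegraph process) followed by a spike
    ``exp(-u/decay) * [A_start + B(1-exp(-u/rise))]`` that rises continuously
    from the foot level and is normalized so its maximum equals
    ``spike_amplitude_pA``.
    """

    onset_ms: float
    spike_amplitude_pA: float
    rise_tau_ms: float
    decay_tau_ms: float
    foot_duration_ms: float = 0.0
    foot_amplitude_pA: float = 0.0
    foot_rise_ms: float = 0.2
    # realized flicker: transition times (ms, relative to foot onset) and
    # the state before the first transition; state multiplies the plateau.
    flicker_transitions_ms: tuple[float, ...] = ()
    flicker_initial_open: bool = True
    charge_fC: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.spike_amplitude_pA <= 0 or self.rise_tau_ms <= 0 or self.decay_tau_ms <= 0:
            raise ValueError("spike amplitude and time constants must be positive")
        if self.foot_duration_ms < 0 or self.foot_amplitude_pA < 0:
            raise ValueError("foot parameters must be non-negative")
        if self.foot_duration_ms > 0 and self.foot_amplitude_pA >= self.spike_amplitude_pA:
            raise ValueError("foot amplitude must stay below the spike amplitude")
        if self.charge_fC == 0.0:
            self.charge_fC = _analytic_charge(self)

    @property
    def spike_start_level(self) -> float:
        """Current at the foot->spike junction (continuous template)."""
        if self.foot_duration_ms <= 0:
            return 0.0
        return self.foot_amplitude_pA  # telegraph state is forced open at takeoff

    def span_ms(self) -> float:
        """Duration after which the template is numerically negligible."""
        return self.foot_duration_ms + 12.0 * self.decay_tau_ms + 3.0 * self.rise_tau_ms


def _spike_scale(g: SpikeGroundTruth) -> float:
    """Solve for B so the spike peak equals spike_amplitude_pA."""
    a0 = g.spike_start_level
    r, d, target = g.rise_tau_ms, g.decay_tau_ms, g.spike_amplitude_pA

    def peak(b: float) -> float:
        z = r * (a0 + b) / ((r + d) * b)
        if z >= 1.0:
            return a0  # maximum at the junction itself
        u = -r * math.log(z)
        return math.exp(-u / d) * (a0 + b * (1.0 - z))

    lo, hi = 1e-12, max(10.0 * target, 1.0)
    while peak(hi) < target:
        hi *= 4.0
        if hi > 1e12:
            raise RuntimeError("spike normalization failed")
    return brentq(lambda b: peak(b) - target, lo, hi, xtol=1e-12, rtol=1e-14)


def _flicker_state(g: SpikeGroundTruth, t: np.ndarray) -> np.ndarray:
    """Telegraph state (0/1) at times *t* (ms, relative to foot onset)."""
    if not g.flicker_transitions_ms:
        return np.ones_like(t)
    k = np.searchsorted(np.asarray(g.flicker_transitions_ms), t, side="right")
    start = 1 if g.flicker_initial_open else 0
    return ((k + start) % 2 == 1).astype(float)


def _foot_value(g: SpikeGroundTruth, t: np.ndarray) -> np.ndarray:
    ramp = np.clip(t / g.foot_rise_ms, 0.0, 1.0) if g.foot_rise_ms > 0 else np.ones_like(t)
    return g.foot_amplitude_pA * ramp * _flicker_state(g, t)


def template_value(g: SpikeGroundTruth, t_ms: np.ndarray) -> np.ndarray:
    """Noise-free template current at times *t_ms* (relative to event onset)."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    tf = g.foot_duration_ms
    in_foot = (t >= 0) & (t < tf)
    if tf > 0 and np.any(in_foot):
        out[in_foot] = _foot_value(g, t[in_foot])
    u = t - tf
    in_spike = u >= 0
    if np.any(in_spike):
        b = _spike_scale(g)
        uu = u[in_spike]
        out[in_spike] = np.exp(-uu / g.decay_tau_ms) * (
            g.spike_start_level + b * (1.0 - np.exp(-uu / g.rise_tau_ms))
        )
    return out


def _foot_charge(g: SpikeGroundTruth) -> float:
    """Exact integral of the foot segment (ramp x telegraph state)."""
    tf = g.foot_duration_ms
    if tf <= 0 or g.foot_amplitude_pA <= 0:
        return 0.0
    rf = min(g.foot_rise_ms, tf)

    def ramp_integral(a: float, b: float) -> float:
        # integral of min(t/rf, 1) over [a, b]
        total = 0.0
        if a < rf:
            hi = min(b, rf)
            total += (hi**2 - a**2) / (2.0 * rf) if rf > 0 else 0.0
        if b > rf:
            total += b - max(a, rf)
        return total

    # open intervals of the telegraph state on [0, tf]
    edges = [0.0, *[x for x in g.flicker_transitions_ms if 0.0 < x < tf], tf]
    state = 1 if g.flicker_initial_open else 0
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        if state == 1:
            total += ramp_integral(a, b)
        state ^= 1
    return g.foot_amplitude_pA * total


def _analytic_charge(g: SpikeGroundTruth) -> float:
    """Closed-form charge (fC) of the noise-free template."""
    r, d = g.rise_tau_ms, g.decay_tau_ms
    b = _spike_scale(g)
    spike = g.spike_start_level * d + b * d * d / (r + d)
    return _foot_charge(g) + spike


def event_template(g: SpikeGroundTruth, rate_hz: float) -> tuple[np.ndarray, float]:
    """Sample the noise-free template on the acquisition grid.

    Returns ``(samples, analytic_charge_fC)``; sample ``j`` is the template
    value at ``j / rate_hz`` after event onset.
    """
    dt_ms = 1000.0 / rate_hz
    n = int(math.ceil(g.span_ms() / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    return template_value(g, t), _analytic_charge(g)


# ---------------------------------------------------------------------------
# telegraph flicker
# ---------------------------------------------------------------------------


def draw_telegraph(
    rng: np.random.Generator,
    duration_ms: float,
    rate_per_ms: float,
    open_fraction: float,
    force_open_end: bool = True,
) -> tuple[tuple[float, ...], bool]:
    """Stationary two-state telegraph with overall transition rate *rate_per_ms*.

    Exit rates are chosen so the stationary open probability equals
    *open_fraction* while the long-run transition rate (events per ms,
    counting both directions) equals *rate_per_ms*.  With *force_open_end*
    (the default, used when a spike follows) the final state is forced open
    so the foot connects continuously to the spike upstroke; the realized
    transition times are what the ground truth records either way.
    """
    p = open_fraction
    if rate_per_ms <= 0 or p >= 1.0:
        return (), True
    if not 0 < p < 1:
        raise ValueError("open_fraction must be in (0, 1] for flicker")
    mu_open = rate_per_ms / (2.0 * p)        # rate of leaving the open state
    mu_closed = rate_per_ms / (2.0 * (1.0 - p))
    state = bool(rng.random() < p)
    initial = state
    t = 0.0
    transitions: list[float] = []
    while True:
        t += rng.exponential(1.0 / (mu_open if state else mu_closed))
        if t >= duration_ms:
            break
        transitions.append(t)
        state = not state
    if force_open_end and not state:
        if transitions:
            transitions.pop()
        else:
            initial = True
    return tuple(transitions), initial


# ---------------------------------------------------------------------------
# amperometric trace simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventParams:
    """Sampling ranges for simulated events.

    These are plausible testing defaults for chromaffin-cell amperometry
    (spike amplitudes spanning the 4-100 pA selection range, half widths and
    feet of 0.5-10 ms, foot amplitudes of a few pA); they are generator
    choices, not measured distributions.
    """

    amplitude_range_pA: tuple[float, float] = (5.0, 100.0)
    amplitude_log_uniform: bool = True
    rise_tau_range_ms: tuple[float, float] = (0.15, 0.6)
    decay_tau_range_ms: tuple[float, float] = (0.8, 8.0)
    foot_probability: float = 0.7
    foot_duration_range_ms: tuple[float, float] = (0.5, 10.0)
    foot_amplitude_range_pA: tuple[float, float] = (1.0, 10.0)
    foot_rise_ms: float = 0.2
    flicker_rate_per_ms: float = 0.0
    flicker_open_fraction: float = 0.7


def _draw_range(rng: np.random.Generator, lo: float, hi: float, log: bool = False) -> float:
    if log:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def draw_event(rng: np.random.Generator, params: EventParams, onset_ms: float) -> SpikeGroundTruth:
    amp = _draw_range(rng, *params.amplitude_range_pA, log=params.amplitude_log_uniform)
    rise = _draw_range(rng, *params.rise_tau_range_ms, log=True)
    decay = _draw_range(rng, *params.decay_tau_range_ms, log=True)
    foot_dur = 0.0
    foot_amp = 0.0
    transitions: tuple[float, ...] = ()
    initial = True
    if rng.random() < params.foot_probability:
        foot_dur = _draw_range(rng, *params.foot_duration_range_ms)
        lo, hi = params.foot_amplitude_range_pA
        foot_amp = _draw_range(rng, lo, min(hi, 0.5 * amp))
        if params.flicker_rate_per_ms > 0:
            transitions, initial = draw_telegraph(
                rng, foot_dur, params.flicker_rate_per_ms, params.flicker_open_fraction
            )
    return SpikeGroundTruth(
        onset_ms=onset_ms,
        spike_amplitude_pA=amp,
        rise_tau_ms=rise,
        decay_tau_ms=decay,
        foot_duration_ms=foot_dur,
        foot_amplitude_pA=foot_amp,
        foot_rise_ms=min(params.foot_rise_ms, foot_dur) if foot_dur > 0 else params.foot_rise_ms,
        flicker_transitions_ms=transitions,
        flicker_initial_open=initial,
    )


def shaped_noise(
    rng: np.random.Generator,
    n: int,
    post_filter_sd: float,
    rate_hz: float,
    cutoff_hz: float,
) -> np.ndarray:
    """Gaussian white noise low-passed at *cutoff_hz*, scaled so the
    post-filter SD equals *post_filter_sd*."""
    if post_filter_sd <= 0:
        return np.zeros(n)
    gain = filter_noise_gain(rate_hz, cutoff_hz)
    white = rng.normal(0.0, post_filter_sd / gain, n)
    return lowpass_array(white, rate_hz, cutoff_hz)


def simulate_amperometric_trace(
    n_events: int,
    param_distributions: EventParams | None = None,
    noise_sd_pA: float = 1.0,
    duration_ms: float = 10000.0,
    rate_hz: float = 25000.0,
    seed: int | None = None,
    min_gap_ms: float = 50.0,
    edge_margin_ms: float = 100.0,
    filter_cutoff_hz: float = 2000.0,
) -> tuple[Trace, list[SpikeGroundTruth]]:
    """Simulate a gap-free amperometric recording with known events.

    Event onsets are snapped to the sample grid and separated by at least
    *min_gap_ms* so the ground truth is unambiguous.  Noise is Gaussian,
    shaped by the acquisition low-pass, with post-filter SD *noise_sd_pA*.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducible simulation")
    params = param_distributions or EventParams()
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / rate_hz
    n = int(round(duration_ms / dt_ms))

    truths: list[SpikeGroundTruth] = []
    if n_events > 0:
        slack = duration_ms - 2 * edge_margin_ms - n_events * min_gap_ms
        if slack < 0:
            raise ValueError(
                f"cannot place {n_events} events with a {min_gap_ms} ms gap in "
                f"{duration_ms} ms"
            )
        offsets = np.sort(rng.uniform(0.0, slack, n_events))
        onsets = edge_margin_ms + offsets + np.arange(n_events) * min_gap_ms
        onsets = np.round(onsets / dt_ms) * dt_ms  # snap to the sample grid
        truths = [draw_event(rng, params, float(t)) for t in onsets]

    samples = np.zeros(n)
    for g in truths:
        tmpl, _ = event_template(g, rate_hz)
        i0 = int(round(g.onset_ms / dt_ms))
        i1 = min(n, i0 + tmpl.size)
        samples[i0:i1] += tmpl[: i1 - i0]
    samples += shaped_noise(rng, n, noise_sd_pA, rate_hz, filter_cutoff_hz)

    trace = Trace(
        samples=samples,
        sampling_rate=rate_hz,
        kind=AMPEROMETRY,
        filter_cutoff=filter_cutoff_hz,
    )
    return trace, truths


# ---------------------------------------------------------------------------
# capacitance trace simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CmGroundTruth:
    """Ground truth of a flash-evoked capacitance response.

    ``A1, tau1`` is the fast (readily releasable pool) component and
    ``A2, tau2`` the slow (slowly releasable pool) component; ``k`` is the
    sustained rate and ``onset_delay_ms`` the secretory delay after the flash.
    """

    A0_fF: float = 5000.0
    A1_fF: float = 150.0
    tau1_ms: float = 20.0
    A2_fF: float = 250.0
    tau2_ms: float = 200.0
    k_fF_per_s: float = 20.0
    onset_delay_ms: float = 5.0
    noise_sd_fF: float = 5.0

    def __post_init__(self) -> None:
        if not self.tau1_ms < self.tau2_ms:
            raise ValueError("tau1 must be smaller than tau2 (fast pool first)")
        if self.A1_fF < 0 or self.A2_fF < 0:
            raise ValueError("pool amplitudes must be non-negative")


def cm_model(
    t_ms: np.ndarray,
    A0: float,
    A1: float,
    tau1: float,
    A2: float,
    tau2: float,
    k_per_s: float,
    t_on_ms: float,
) -> np.ndarray:
    """Double-exponential burst model with onset; time in ms, k in fF/s."""
    t = np.asarray(t_ms, dtype=float)
    u = np.clip(t - t_on_ms, 0.0, None)
    active = (t >= t_on_ms).astype(float)
    return A0 + active * (
        A1 * (1.0 - np.exp(-u / tau1))
        + A2 * (1.0 - np.exp(-u / tau2))
        + (k_per_s / 1000.0) * u
    )


def simulate_cm_trace(
    g: CmGroundTruth,
    duration_ms: float = 2000.0,
    rate_hz: float = 2000.0,
    flash_time_ms: float = 200.0,
    seed: int | None = None,
) -> Trace:
    """Simulate a capacitance trace with a flash annotation."""
    if seed is None:
        raise ValueError("seed is mandatory for reproducible simulation")
    if not flash_time_ms + g.onset_delay_ms < duration_ms:
        raise ValueError("flash time plus onset delay must fall inside the trace")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_ms * rate_hz / 1000.0))) * (1000.0 / rate_hz)
    cm = cm_model(
        t, g.A0_fF, g.A1_fF, g.tau1_ms, g.A2_fF, g.tau2_ms, g.k_fF_per_s,
        flash_time_ms + g.onset_delay_ms,
    )
    if g.noise_sd_fF > 0:
        cm = cm + rng.normal(0.0, g.noise_sd_fF, t.size)
    return Trace(
        samples=cm,
        sampling_rate=rate_hz,
        kind=CAPACITANCE,
        annotations={"flash": flash_time_ms / 1000.0},
    )


# ---------------------------------------------------------------------------
# two-channel image simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGroundTruth:
    """Punctate two-channel image with a controllable colocalized fraction."""

    shape: tuple[int, int] = (256, 256)
    n_granules_ch1: int = 40
    n_extra_ch2: int = 10
    colocalized_fraction: float = 0.5
    amplitude_ch1: float = 180.0
    amplitude_ch2: float = 200.0
    sigma_ch1_px: float = 2.0
    sigma_ch2_px: float = 2.6
    baseline: float = 10.0
    noise_sd: float = 2.0
    min_separation_px: float = 18.0
    margin_px: float = 12.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.colocalized_fraction <= 1.0:
            raise ValueError("colocalized_fraction must lie in [0, 1]")


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
    existing: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place granules with the requested separation")
        y = rng.uniform(margin, shape[0] - margin)
        x = rng.uniform(margin, shape[1] - margin)
        if all(
            (y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2
            for cy, cx in centers + existing
        ):
            centers.append((y, x))
    return centers


def _render(
    shape: tuple[int, int],
    centers: list[tuple[float, float]],
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, dtype=float)
    for cy, cx in centers:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
    return img


def simulate_image_pair(
    g: ImageGroundTruth, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a two-channel granule image pair (uint16)."""
    if seed is None:
        raise ValueError("seed is mandatory for reproducible simulation")
    rng = np.random.default_rng(seed)
    img1, img2 = noise_free_image_pair(g, rng)
    img1 = img1 + rng.normal(0.0, g.noise_sd, g.shape)
    img2 = img2 + rng.normal(0.0, g.noise_sd, g.shape)
    return (
        np.clip(np.round(img1), 0, 65535).astype(np.uint16),
        np.clip(np.round(img2), 0, 65535).astype(np.uint16),
    )


def noise_free_image_pair(
    g: ImageGroundTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free blob images; channel-2 blobs cover the thresholded support
    of every colocalized channel-1 granule, so the intensity-weighted
    colocalized fraction equals ``round(f * n) / n``."""
    n1 = g.n_granules_ch1
    k = int(round(g.colocalized_fraction * n1))
    centers1 = _place_centers(rng, n1, g.shape, g.margin_px, g.min_separation_px, [])
    coloc = centers1[:k]
    extra2 = _place_centers(
        rng, g.n_extra_ch2, g.shape, g.margin_px, g.min_separation_px, centers1
    )
    img1 = g.baseline + _render(g.shape, centers1, g.amplitude_ch1, g.sigma_ch1_px)
    img2 = g.baseline + _render(g.shape, coloc + extra2, g.amplitude_ch2, g.sigma_ch2_px)
    return img1, img2
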