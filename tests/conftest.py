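"""Shared fixtures and scoring helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from exopore.synthetic import SpikeGroundTruth, _spike_scale, event_template
from exopore.trace import Trace


def truth_peak_ms(g: SpikeGroundTruth) -> float:
    """Closed-form time of the template peak (ms from trace start)."""
    r, d = g.rise_tau_ms, g.decay_tau_ms
    b = _spike_scale(g)
    a0 = g.spike_start_level
    z = r * (a0 + b) / ((r + d) * b)
    u = -r * math.log(z) if z < 1 else 0.0
    return g.onset_ms + g.foot_duration_ms + u


def match_by_peak(table, truths, tol_ms: float = 2.0):
    """Greedy one-to-one matching of detected events to ground truth by peak
    time.  Returns (n_matched, matched_pairs)."""
    det_pk = np.array([e.peak_time_ms for e in table])
    used = np.zeros(len(det_pk), dtype=bool)
    pairs = []
    for g in truths:
        if det_pk.size == 0:
            break
        d = np.abs(det_pk - truth_peak_ms(g))
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] < tol_ms:
            used[j] = True
            pairs.append((g, table.events[j]))
    return len(pairs), pairs


def embed_template(g: SpikeGroundTruth, duration_ms: float = 1000.0,
                   rate_hz: float = 25000.0) -> Trace:
    """Noise-free trace containing a single event template at its onset."""
    dt = 1000.0 / rate_hz
    n = int(round(duration_ms / dt))
    samples = np.zeros(n)
    tmpl, _ = event_template(g, rate_hz)
    i0 = int(round(g.onset_ms / dt))
    i1 = min(n, i0 + tmpl.size)
    samples[i0:i1] += tmpl[: i1 - i0]
    return Trace(samples, rate_hz)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
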