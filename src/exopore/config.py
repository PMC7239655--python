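"""Analysis configuration: every tunable threshold of the pipeline in one place.

Defaults reproduce the selection and filtering rules of the carbon-fiber
amperometry protocol this package implements: events are accepted for the
frequency tier when their peak exceeds 4 pA and their charge lies in
10–5000 fC; kinetic (waveform) parameters are reported only above 7 pA;
fluctuation statistics of the pre-spike foot use the current derivative
low-pass filtered at 1.2 kHz with a +/-6 pA/ms excursion threshold, and only
feet longer than 2 ms qualify; a cell enters cohort statistics with more
than 20 events.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and numerical settings for the whole pipeline.

    Units follow the internal convention: current pA, time ms, charge fC,
    derivative pA/ms, capacitance fF.
    """

    # --- event selection (frequency tier) ---
    min_amplitude_detect_pA: float = 4.0     # peak amplitude for event counting
    charge_min_fC: float = 10.0
    charge_max_fC: float = 5000.0
    # --- kinetics tier ---
    min_amplitude_kinetics_pA: float = 7.0   # waveform parameters only above this
    # --- foot / fluctuation analysis ---
    derivative_filter_hz: float = 1200.0     # extra low-pass on the current derivative
    fluct_threshold_pA_per_ms: float = 6.0   # +/- excursion threshold on the derivative
    fluct_threshold_mode: str = "fixed"      # "fixed" or "adaptive" (k x derivative noise)
    fluct_adaptive_k: float = 4.0
    min_foot_duration_fluct_ms: float = 2.0  # feet must be longer than this to qualify
    foot_k: float = 2.0                      # foot onset level, multiples of baseline noise
    min_foot_report_ms: float = 0.25         # feet shorter than this are not reported
    takeoff_lo_frac: float = 0.35            # rising-phase points defining the
    takeoff_hi_frac: float = 0.65            # back-extrapolation line for foot takeoff
    # --- cohort aggregation ---
    min_events_per_cell: int = 21            # ">20 events" inclusion rule
    # --- detection internals ---
    detect_start_k: float = 4.0              # candidate trigger, multiples of noise SD
    boundary_k: float = 1.0                  # onset/end outward crossing level
    min_above_samples: int = 3               # samples required above trigger level
    min_gap_ms: float = 3.0                  # closer events are flagged as overlapping
    merge_gap_ms: float = 1.0                # closer candidate windows are one event
    noise_floor_pA: float = 0.2              # threshold floor for (near-)noiseless traces
    # --- baseline estimation ---
    baseline_window_ms: float = 500.0
    baseline_mask_margin_ms: float = 5.0     # padding around events on the second pass
    # --- capacitance fitting ---
    cm_fit_window_ms: float = 1000.0
    cm_pre_window_ms: float = 200.0
    # --- recording defaults ---
    analysis_window_s: float = 120.0
    default_rate_hz: float = 25000.0
    default_filter_hz: float = 2000.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        """Build a config from a mapping; unknown keys are a hard error."""
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise KeyError(
                "unknown configuration key(s): " + ", ".join(sorted(unknown))
            )
        return cls(**d)
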