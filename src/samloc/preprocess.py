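"""Head-saccade detection and quality control for orientation traces.

Saccade onset and offset are the first upward and the following downward
crossing of a 10 deg/s velocity threshold after stimulus onset.  Responses
are discarded when no crossing exists (null response), when the velocity
profile between onset and offset is not single-peaked (anomalous profile),
or when the reaction time is shorter than 150 ms (predictive response).
The endpoint is the mean orientation over a 100 ms hold window starting
50 ms after offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import HeadTrace

__all__ = [
    "SaccadeEvent",
    "compute_velocity",
    "detect_saccade",
    "qc_filter",
    "head_still_check",
    "events_to_frame",
]

QC_OK = "ok"
QC_NULL = "null_response"
QC_ANOMALOUS = "anomalous_profile"
QC_EARLY = "early_rt"


@dataclass
class SaccadeEvent:
    """A detected head movement with QC status."""

    onset_ms: float
    offset_ms: float
    endpoint_el: float
    endpoint_az: float
    peak_velocity: float
    rt_ms: float
    qc: str
    trial: int | None = None


def compute_velocity(trace: HeadTrace, smooth_cutoff_hz: float = 40.0) -> np.ndarray:
    """Vectorial head speed (deg/s) from a 2D orientation trace.

    Azimuth and elevation are zero-phase low-pass filtered at
    ``smooth_cutoff_hz`` (default 40 Hz: below the 120 Hz acquisition limit,
    above head-saccade dynamics) before central differencing; the returned
    speed is the Euclidean norm of the two derivatives.
    """
    n = trace.t.size
    sos = signal.butter(4, smooth_cutoff_hz, fs=trace.fs_hz, output="sos")
    padlen = 3 * 6  # sosfiltfilt default pad for a 4th-order section pair
    if n <= padlen:
        raise ValueError("trace shorter than the smoothing filter length")
    az = signal.sosfiltfilt(sos, trace.azimuth)
    el = signal.sosfiltfilt(sos, trace.elevation)
    vaz = np.gradient(az, trace.t)
    vel = np.gradient(el, trace.t)
    return np.hypot(vaz, vel)


def _count_peaks(speed_seg: np.ndarray, threshold: float) -> int:
    """Local velocity maxima above threshold within a saccade segment."""
    peaks, _ = signal.find_peaks(speed_seg, height=threshold, prominence=threshold / 2)
    if peaks.size == 0 and speed_seg.size > 0 and speed_seg.max() >= threshold:
        return 1  # single monotone-up/monotone-down lobe
    return int(peaks.size)


def detect_saccade(
    trace: HeadTrace,
    threshold: float = 10.0,
    stimulus_onset_ms: float = 0.0,
    hold_delay_ms: float = 50.0,
    hold_window_ms: float = 100.0,
    smooth_cutoff_hz: float = 40.0,
    edge_guard_ms: float = 25.0,
    trial: int | None = None,
) -> SaccadeEvent:
    """Detect the first head saccade after stimulus onset.

    Onset is the first upward crossing of ``threshold`` (deg/s) at or after
    ``stimulus_onset_ms``; offset is the next downward crossing.  The
    endpoint is the mean orientation over ``hold_window_ms`` starting
    ``hold_delay_ms`` after offset.  QC is ``null_response`` when the speed
    never reaches threshold and ``anomalous_profile`` when more than one
    velocity peak exceeds threshold between onset and offset; the early-RT
    flag is applied by :func:`qc_filter`.
    """
    speed = compute_velocity(trace, smooth_cutoff_hz)
    t_ms = trace.t * 1000.0
    # the first/last few filter lengths carry zero-phase-filtering edge
    # transients; exclude them from the search window
    searchable = (t_ms >= max(stimulus_onset_ms, edge_guard_ms)) & (
        t_ms <= t_ms[-1] - edge_guard_ms
    )
    speed = np.where(searchable, speed, 0.0)
    above = speed >= threshold
    if not np.any(above):
        return SaccadeEvent(
            np.nan, np.nan, np.nan, np.nan, float(speed.max()), np.nan, QC_NULL, trial
        )
    i_on = int(np.argmax(above))
    below_after = (speed < threshold) & (np.arange(speed.size) > i_on)
    i_off = int(np.argmax(below_after)) if np.any(below_after) else speed.size - 1
    onset_ms = float(t_ms[i_on])
    offset_ms = float(t_ms[i_off])
    n_peaks = _count_peaks(speed[i_on : i_off + 1], threshold)
    # also catch later re-acceleration (a second saccade after the first)
    later = speed[i_off:]
    if later.size and _count_peaks(later, threshold) > 0 and n_peaks >= 1:
        n_peaks += _count_peaks(later, threshold)
    qc = QC_OK if n_peaks <= 1 else QC_ANOMALOUS
    h0 = offset_ms + hold_delay_ms
    hold = (t_ms >= h0) & (t_ms < h0 + hold_window_ms)
    if not np.any(hold):
        hold = t_ms >= offset_ms
    return SaccadeEvent(
        onset_ms=onset_ms,
        offset_ms=offset_ms,
        endpoint_el=float(trace.elevation[hold].mean()),
        endpoint_az=float(trace.azimuth[hold].mean()),
        peak_velocity=float(speed[i_on : i_off + 1].max()),
        rt_ms=onset_ms - stimulus_onset_ms,
        qc=qc,
        trial=trial,
    )


def qc_filter(
    events: list[SaccadeEvent], min_rt_ms: float = 150.0
) -> tuple[list[SaccadeEvent], list[SaccadeEvent]]:
    """Split events into (kept, discarded) by the selection rules.

    Discards null responses, anomalous (multi-peaked) profiles, and
    reaction times shorter than ``min_rt_ms`` (re-flagged ``early_rt``);
    an RT exactly at the cut is kept.
    """
    kept: list[SaccadeEvent] = []
    discarded: list[SaccadeEvent] = []
    for ev in events:
        if ev.qc != QC_OK:
            discarded.append(ev)
        elif ev.rt_ms < min_rt_ms:
            discarded.append(
                SaccadeEvent(
                    ev.onset_ms, ev.offset_ms, ev.endpoint_el, ev.endpoint_az,
                    ev.peak_velocity, ev.rt_ms, QC_EARLY, ev.trial,
                )
            )
        else:
            kept.append(ev)
    return kept, discarded


def head_still_check(
    trace: HeadTrace,
    max_excursion_deg: float = 5.0,
    stimulus_onset_ms: float = 0.0,
    stimulus_offset_ms: float | None = None,
) -> bool:
    """True iff the head stayed within ``max_excursion_deg`` of its initial
    orientation during the stimulus (inclusive at the limit).

    Used to reject discrimination trials in which the listener moved the
    head (which could create dynamic localization cues).
    """
    t_ms = trace.t * 1000.0
    if stimulus_offset_ms is None:
        stimulus_offset_ms = float(t_ms[-1])
    pre = t_ms <= stimulus_onset_ms
    az0 = trace.azimuth[pre].mean() if np.any(pre) else trace.azimuth[0]
    el0 = trace.elevation[pre].mean() if np.any(pre) else trace.elevation[0]
    win = (t_ms >= stimulus_onset_ms) & (t_ms <= stimulus_offset_ms)
    exc = np.hypot(trace.azimuth[win] - az0, trace.elevation[win] - el0)
    return bool(exc.max() <= max_excursion_deg)


def events_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    """Tabulate events (one row each) for CSV export."""
    return pd.DataFrame(
        [
            dict(
                trial=ev.trial,
                onset_ms=ev.onset_ms,
                offset_ms=ev.offset_ms,
                endpoint_el=ev.endpoint_el,
                endpoint_az=ev.endpoint_az,
                peak_velocity=ev.peak_velocity,
                rt_ms=ev.rt_ms,
                qc=ev.qc,
            )
            for ev in events
        ]
    )
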