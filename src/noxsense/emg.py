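"""EMG reflex-withdrawal quantification.

Signals are band-passed 10-500 Hz with notches at 50 Hz and its harmonics,
full-wave rectified, cut into epochs from 2 s before to 4 s after each
stimulus, screened for baseline-period artifacts, and summarised as the mean
RMS over the first four 250 ms windows after the stimulus (the first second).
Per-subject baseline reflex sensitivity is the median — not the mean — of the
accepted experimental-trial magnitudes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import extract_epochs, reject_artifacts

__all__ = ["preprocess_emg", "reflex_magnitude", "summarise_reflex"]


def preprocess_emg(signal: np.ndarray, sampling_rate: float,
                   band: tuple[float, float] = (10.0, 500.0),
                   notch_base: float | None = 50.0,
                   notch_max: float = 450.0,
                   order: int = 4, notch_q: float = 30.0) -> np.ndarray:
    """Zero-phase band-pass, harmonic mains notches, then rectification."""
    lo, hi = band
    if sampling_rate <= 2.0 * hi:
        raise ValueError("sampling rate too low for the requested band")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sampling_rate,
                     output="sos")
    out = sps.sosfiltfilt(sos, np.asarray(signal, float))
    if notch_base is not None:
        f = notch_base
        while f <= min(notch_max, hi):
            b, a = sps.iirnotch(f, notch_q, fs=sampling_rate)
            out = sps.filtfilt(b, a, out)
            f += notch_base
    return np.abs(out)   # rectification last


def reflex_magnitude(signal: np.ndarray, sampling_rate: float,
                     events: pd.DataFrame,
                     pre_s: float = 2.0, post_s: float = 4.0,
                     window_ms: float = 250.0,
                     n_windows: int = 4,
                     baseline_threshold_uv: float = 100.0,
                     subject_id: str | None = None) -> pd.DataFrame:
    """Per-trial reflex magnitudes from a preprocessed (rectified) recording.

    The magnitude is the arithmetic mean of the RMS over the first
    ``n_windows`` post-stimulus windows of ``window_ms`` each. Trials with
    baseline-period amplitudes above ``baseline_threshold_uv`` or clipped at
    the record edge are flagged, not dropped.
    """
    epochs = extract_epochs(signal, sampling_rate, events,
                            pre_ms=pre_s * 1000.0, post_ms=post_s * 1000.0,
                            baseline_correct=False, subject_id=subject_id)
    epochs = reject_artifacts(epochs, baseline_threshold_uv, window="baseline")
    n_per = int(round(window_ms * sampling_rate / 1000.0))
    start = epochs.sample_index(0.0)

    rows = []
    for k in range(epochs.n_trials):
        if epochs.accepted[k]:
            rms = [float(np.sqrt(np.mean(
                epochs.trials[k, start + i * n_per: start + (i + 1) * n_per] ** 2)))
                for i in range(n_windows)]
            mag = float(np.mean(rms))
        else:
            rms = [np.nan] * n_windows
            mag = np.nan
        row = {
            "subject_id": (epochs.subject_ids[k]
                           if epochs.subject_ids is not None else "s0000"),
            "event_label": epochs.event_labels[k],
            "magnitude": mag,
            "accepted": bool(epochs.accepted[k]),
            "reason": epochs.reasons[k],
        }
        row.update({f"rms_w{i + 1}": rms[i] for i in range(n_windows)})
        rows.append(row)
    return pd.DataFrame(rows)


def summarise_reflex(magnitudes: pd.DataFrame,
                     group_by: str = "subject_id") -> pd.DataFrame:
    """Per-subject baseline reflex sensitivity (median of accepted
    experimental trials; midpoint convention for even counts) and median
    clinical reflex response."""
    acc = magnitudes[magnitudes["accepted"]]
    out = []
    for sid, grp in magnitudes.groupby(group_by, sort=True):
        exp = acc[(acc[group_by] == sid) & (acc["event_label"] == "experimental")]
        clin = acc[(acc[group_by] == sid) & (acc["event_label"] == "clinical")]
        if len(exp) < 1:
            baseline = np.nan
        else:
            baseline = float(exp["magnitude"].median())
        out.append({
            "subject_id": sid,
            "baseline_reflex_sensitivity": baseline,
            "clinical_reflex_response": (float(clin["magnitude"].median())
                                         if len(clin) else np.nan),
            "n_accepted_experimental": len(exp),
        })
    return pd.DataFrame(out)
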