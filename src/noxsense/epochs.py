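"""Epoch extraction and artifact screening shared by the EEG and EMG chains."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "extract_epochs", "reject_artifacts"]


@dataclass
class EpochSet:
    """Trial x time matrix cut around stimulus events.

    The time axis runs from ``-pre_ms`` to ``+post_ms`` relative to each
    event (t = 0 at stimulus contact). ``accepted``/``reasons`` carry the
    per-trial screening state and ``shifts_ms`` the latency-alignment shift
    applied to each trial (0 until alignment has run).
    """

    trials: np.ndarray            # (n_trials, n_samples); rejected rows may be NaN
    sampling_rate: float
    pre_ms: float
    post_ms: float
    event_labels: np.ndarray
    accepted: np.ndarray
    reasons: np.ndarray
    shifts_ms: np.ndarray
    subject_ids: np.ndarray | None = None
    at_bound: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.at_bound is None:
            self.at_bound = np.zeros(len(self.trials), bool)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.trials.shape[1]
        return (np.arange(n) - self._pre_samples) * 1000.0 / self.sampling_rate

    @property
    def _pre_samples(self) -> int:
        return int(round(self.pre_ms * self.sampling_rate / 1000.0))

    def sample_index(self, t_ms: float) -> int:
        """Column index of a time in ms relative to the event (nearest sample)."""
        return self._pre_samples + int(round(t_ms * self.sampling_rate / 1000.0))

    def copy(self) -> "EpochSet":
        return EpochSet(self.trials.copy(), self.sampling_rate, self.pre_ms,
                        self.post_ms, self.event_labels.copy(),
                        self.accepted.copy(), self.reasons.copy(),
                        self.shifts_ms.copy(),
                        None if self.subject_ids is None else self.subject_ids.copy(),
                        self.at_bound.copy())


def extract_epochs(signal: np.ndarray,
                   sampling_rate: float,
                   events: pd.DataFrame,
                   pre_ms: float = 500.0,
                   post_ms: float = 1000.0,
                   baseline_correct: bool = True,
                   subject_id: str | None = None) -> EpochSet:
    """Cut per-event epochs and (optionally) subtract the pre-stimulus mean.

    An event at time ``t`` maps to sample ``i = round(t * rate)``; the epoch
    covers samples ``i - pre .. i + post - 1`` inclusive. Events with
    insufficient signal on either side are flagged rejected with reason
    "edge" (the epoch row is NaN), never dropped.
    """
    signal = np.asarray(signal, float)
    fs = sampling_rate
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    n_len = n_pre + n_post
    n_ev = len(events)

    trials = np.full((n_ev, n_len), np.nan)
    accepted = np.ones(n_ev, bool)
    reasons = np.array([""] * n_ev, dtype=object)
    for k, t in enumerate(events["time_s"].to_numpy(float)):
        i = int(round(t * fs))
        lo, hi = i - n_pre, i + n_post
        if lo < 0 or hi > signal.size:
            accepted[k] = False
            reasons[k] = "edge"
            continue
        ep = signal[lo:hi].copy()
        if baseline_correct:
            ep -= ep[:n_pre].mean()
        trials[k] = ep

    labels = events["label"].to_numpy() if "label" in events else \
        np.array(["experimental"] * n_ev)
    sid = None
    if subject_id is not None:
        sid = np.array([subject_id] * n_ev)
    elif "subject_id" in events:
        sid = events["subject_id"].to_numpy()
    return EpochSet(trials, fs, pre_ms, post_ms, labels, accepted,
                    reasons, np.zeros(n_ev), sid)


def reject_artifacts(epochs: EpochSet,
                     amplitude_threshold_uv: float = 100.0,
                     window: str = "all") -> EpochSet:
    """Flag trials whose absolute amplitude exceeds a threshold.

    ``window="baseline"`` screens the pre-stimulus interval only (the EMG
    rule); ``"all"`` screens the full epoch. Already-rejected trials keep
    their original reason.
    """
    if amplitude_threshold_uv <= 0:
        raise ValueError("amplitude threshold must be > 0")
    out = epochs.copy()
    if window == "baseline":
        seg = out.trials[:, :out._pre_samples]
    elif window == "all":
        seg = out.trials
    else:
        raise ValueError("window must be 'all' or 'baseline'")
    with np.errstate(invalid="ignore"):
        bad = np.nanmax(np.abs(seg), axis=1) > amplitude_threshold_uv
    newly = bad & out.accepted
    out.accepted[newly] = False
    out.reasons[newly] = "amplitude"
    if not out.accepted.any():
        warnings.warn("all trials rejected by artifact screening", stacklevel=2)
    return out
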