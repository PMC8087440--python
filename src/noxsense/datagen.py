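"""Synthetic inputs: cohort tables, a surrogate evoked-potential template, and
raw single-channel recordings with known embedded ground truth.

The cohort generator implements the trial-simulation model used for the power
study: per-subject baseline sensitivity ``x`` is uniform on ``[x_min, x_max]``,
the clinical response is ``y = slope * x + intercept + eps`` with Gaussian
residuals, and intervention-arm responses are reduced by a multiplicative
``effect``. The recording generator embeds a template-shaped deflection at a
jittered latency after each stimulus event in coloured background noise, so the
whole signal-processing chain can be exercised against stored ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenerativeConfig",
    "TemplateWaveform",
    "SyntheticRecording",
    "gen_cohort",
    "gen_template",
    "gen_recording",
    "as_rng",
]

GROUP_CONTROL = "control"
GROUP_INTERVENTION = "intervention"


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator from a seed, Generator or SeedSequence."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the cohort generative model.

    Parameters
    ----------
    n_per_group : int
        Subjects per arm (balanced design; total rows ``2 * n_per_group``).
    slope, intercept : float
        Linear map from baseline sensitivity ``x`` to clinical response ``y``,
        both in template-weight units.
    resid_sd : float
        Standard deviation of the Gaussian residual of the ``x``-``y``
        relationship (template-weight units).
    x_min, x_max : float
        Support of the uniform baseline-sensitivity distribution.
    effect : float
        Proportional reduction of the intervention arm's clinical responses,
        in ``[0, 1]``; 0.40 means responses are multiplied by 0.6.
    scale : {"response", "signal"}
        "response" multiplies the whole simulated response (noise included) by
        ``1 - effect``; "signal" scales only the noise-free component and adds
        the residual afterwards.
    """

    n_per_group: int = 16
    slope: float = 2.62
    intercept: float = -0.75
    resid_sd: float = 0.37
    x_min: float = 0.15
    x_max: float = 1.85
    effect: float = 0.40
    scale: str = "response"
    seed: int | None = None

    def __post_init__(self):
        vals = (self.slope, self.intercept, self.resid_sd,
                self.x_min, self.x_max, self.effect)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite generative parameter in {vals!r}")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be < x_max")
        if self.scale not in ("response", "signal"):
            raise ValueError("scale must be 'response' or 'signal'")

    def with_(self, **kwargs) -> "GenerativeConfig":
        return replace(self, **kwargs)


def gen_cohort(config: GenerativeConfig,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one balanced two-arm cohort.

    Returns a data frame with columns ``subject_id, x, y, group``; control
    rows first. Draw order is fixed (all ``x`` then all residuals) so that a
    given generator state always yields the identical cohort.
    """
    rng = as_rng(config.seed if rng is None else rng)
    n = config.n_per_group
    x = rng.uniform(config.x_min, config.x_max, size=2 * n)
    eps = rng.normal(0.0, config.resid_sd, size=2 * n)
    signal = config.slope * x + config.intercept
    keep = 1.0 - config.effect
    if config.scale == "response":
        y = signal + eps
        y[n:] *= keep
    else:
        y = signal.copy()
        y[n:] *= keep
        y += eps
    return pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(2 * n)],
        "x": x,
        "y": y,
        "group": [GROUP_CONTROL] * n + [GROUP_INTERVENTION] * n,
    })


@dataclass(frozen=True)
class TemplateWaveform:
    """A unit-norm evoked-potential shape spanning ``span_ms`` milliseconds."""

    samples: np.ndarray
    sampling_rate: float
    span_ms: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, float))
        n_expected = int(round(self.span_ms * self.sampling_rate / 1000.0))
        if self.samples.size != n_expected:
            raise ValueError(
                f"template length {self.samples.size} != "
                f"span_ms*rate/1000 = {n_expected}")
        norm = np.linalg.norm(self.samples)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"template must be unit-norm (got {norm})")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * 1000.0 / self.sampling_rate

    def resampled(self, n: int) -> np.ndarray:
        """Linear-interpolation resample to ``n`` samples, re-normalised."""
        if n == self.samples.size:
            return self.samples
        old = np.linspace(0.0, 1.0, self.samples.size)
        new = np.linspace(0.0, 1.0, n)
        out = np.interp(new, old, self.samples)
        return out / np.linalg.norm(out)


def gen_template(sampling_rate: float = 2000.0,
                 span_ms: float = 300.0,
                 neg_latency_ms: float = 90.0,
                 neg_width_ms: float = 30.0,
                 pos_latency_ms: float = 190.0,
                 pos_width_ms: float = 45.0,
                 pos_amp_ratio: float = 1.25) -> TemplateWaveform:
    """Deterministic biphasic surrogate template.

    A negative Gaussian lobe followed by a positive one — the canonical
    negative/positive deflection of the infant noxious-evoked vertex
    potential — normalised to unit Euclidean norm. The surrogate stands in
    for an empirically derived waveform; every downstream operator accepts
    any unit-norm waveform loaded from file.
    """
    if span_ms <= 0:
        raise ValueError("span_ms must be > 0")
    for lat in (neg_latency_ms, pos_latency_ms):
        if not 0.0 <= lat <= span_ms:
            raise ValueError(f"peak latency {lat} ms outside span 0..{span_ms} ms")
    n = int(round(span_ms * sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sampling_rate
    w = (-np.exp(-0.5 * ((t - neg_latency_ms) / neg_width_ms) ** 2)
         + pos_amp_ratio * np.exp(-0.5 * ((t - pos_latency_ms) / pos_width_ms) ** 2))
    w /= np.linalg.norm(w)
    return TemplateWaveform(w, sampling_rate, span_ms)


@dataclass
class SyntheticRecording:
    """A continuous single-channel recording with event annotations.

    ``events`` has columns ``time_s, label``; ``ground_truth`` one row per
    non-background event with the embedded amplitude (template-weight units),
    the embedded latency jitter (ms) and an ``in_window`` flag that is False
    when the jitter pushed the template outside the nominal analysis epoch.
    """

    signal: np.ndarray
    sampling_rate: float
    events: pd.DataFrame
    ground_truth: pd.DataFrame
    background: np.ndarray | None = field(default=None, repr=False)

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.sampling_rate

    def __post_init__(self):
        if len(self.events) and self.events["time_s"].max() >= self.duration_s:
            raise ValueError("event time outside signal duration")
        n_stim = int((self.events["label"] != "background").sum())
        if len(self.ground_truth) != n_stim:
            raise ValueError("ground_truth must have one row per stimulus event")


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power background noise scaled to the requested SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def gen_recording(cohort_row,
                  template: TemplateWaveform,
                  n_trials: int = 15,
                  n_clinical: int = 1,
                  isi_s: float = 10.0,
                  latency_ms: float = 400.0,
                  jitter_sd_ms: float = 10.0,
                  max_jitter_ms: float = 50.0,
                  trial_noise_sd: float = 0.1,
                  background: tuple[str, float] = ("one_over_f", 0.05),
                  pre_ms: float = 500.0,
                  post_ms: float = 1000.0,
                  seed=None) -> SyntheticRecording:
    """Simulate a stimulation session for one subject.

    ``n_trials`` experimental stimuli followed by ``n_clinical`` clinical
    stimuli are spaced ``isi_s`` apart (the stimulation protocol uses trains
    of 10-20 trials at a minimum inter-stimulus interval of 10 s). Each
    stimulus embeds ``amplitude * template`` starting ``latency_ms + jitter``
    after the event, where the amplitude is the subject's baseline
    sensitivity ``x`` (experimental) or clinical response ``y`` (clinical)
    plus ``Normal(0, trial_noise_sd)``, and the jitter is truncated-normal
    within ``±max_jitter_ms`` so that latency correction can recover it.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if isi_s < 10.0:
        raise ValueError("isi_s must be >= 10 s")
    kind, bg_sd = background
    if kind not in ("white", "one_over_f"):
        raise ValueError(f"unknown background noise model {kind!r}")

    rng = as_rng(seed)
    fs = template.sampling_rate
    lead_in_s = max(2.0, pre_ms / 1000.0 + 1.0)
    n_events = n_trials + n_clinical
    labels = ["experimental"] * n_trials + ["clinical"] * n_clinical
    times = lead_in_s + isi_s * np.arange(n_events)
    total_s = times[-1] + max(4.0, post_ms / 1000.0 + 1.0)
    n_samples = int(round(total_s * fs))

    jitter = rng.normal(0.0, jitter_sd_ms, size=n_events)
    # truncated-Normal: redraw outside the alignment search bound
    for _ in range(100):
        bad = np.abs(jitter) > max_jitter_ms
        if not bad.any():
            break
        jitter[bad] = rng.normal(0.0, jitter_sd_ms, size=int(bad.sum()))
    jitter = np.clip(jitter, -max_jitter_ms, max_jitter_ms)

    amp_noise = rng.normal(0.0, trial_noise_sd, size=n_events)
    base = {"experimental": float(cohort_row["x"]),
            "clinical": float(cohort_row["y"])}
    amplitudes = np.array([base[lab] for lab in labels]) + amp_noise

    signal = np.zeros(n_samples)
    tpl = template.samples
    in_window = np.ones(n_events, bool)
    for k in range(n_events):
        onset = int(round((times[k] + (latency_ms + jitter[k]) / 1000.0) * fs))
        end = onset + tpl.size
        ev_idx = int(round(times[k] * fs))
        epoch_end = ev_idx + int(round(post_ms * fs / 1000.0))
        if end > epoch_end or end > n_samples:
            in_window[k] = False  # flagged, never silently dropped
        sl = slice(onset, min(end, n_samples))
        signal[sl] += amplitudes[k] * tpl[: sl.stop - sl.start]

    if bg_sd > 0:
        noise = (rng.normal(0.0, bg_sd, n_samples) if kind == "white"
                 else _pink_noise(n_samples, bg_sd, rng))
    else:
        noise = np.zeros(n_samples)

    events = pd.DataFrame({"time_s": times, "label": labels})
    gt = pd.DataFrame({
        "time_s": times, "label": labels,
        "amplitude": amplitudes, "jitter_ms": jitter,
        "in_window": in_window,
        "subject_id": str(cohort_row.get("subject_id", "s0000")),
    })
    return SyntheticRecording(signal + noise, fs, events, gt, background=noise)
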