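"""File formats: cohort/template/event CSV conventions, ground-truth JSON
sidecars, and EDF for continuous recordings.

EDF writing is a minimal single-purpose implementation (plain EDF, 16-bit,
one-second data records, zero-padded final record); reading goes through
mne's EDF reader. Cohort tables, event sheets and templates are plain CSV so
every artifact except the raw recordings stays human-readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import SyntheticRecording, TemplateWaveform

__all__ = [
    "write_cohort_csv", "read_cohort_csv",
    "write_template_csv", "read_template_csv",
    "write_events_csv", "read_events_csv",
    "write_edf", "read_edf",
    "write_recording", "read_recording",
]


# --- cohort tables ---------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort[["subject_id", "x", "y", "group"]].to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "x", "y", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    return df


# --- templates -------------------------------------------------------------

def write_template_csv(template: TemplateWaveform, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={template.sampling_rate} "
                 f"span_ms={template.span_ms}\n")
        fh.write("amplitude\n")
        for v in template.samples:
            fh.write(f"{float(v)!r}\n")
    return path


def read_template_csv(path) -> TemplateWaveform:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError("template CSV must start with a '# key=value' header line")
    meta = dict(tok.split("=") for tok in header[1:].split())
    samples = pd.read_csv(path, skiprows=1,
                          float_precision="round_trip")["amplitude"].to_numpy()
    return TemplateWaveform(samples, float(meta["sampling_rate_hz"]),
                            float(meta["span_ms"]))


# --- event sheets ----------------------------------------------------------

def write_events_csv(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events.to_csv(path, index=False)
    return path


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_s" not in df or "label" not in df:
        raise ValueError("event CSV needs time_s and label columns")
    return df


# --- EDF -------------------------------------------------------------------

def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(path, signals, sampling_rate: float,
              labels=None, physical_dim: str = "uV") -> Path:
    """Write channels to a plain EDF file (16-bit, 1 s data records).

    ``signals`` is (n_channels, n_samples) or a 1-D array; the final data
    record is zero-padded to a whole second. ``sampling_rate`` must be a
    whole number of samples per second.
    """
    sig = np.atleast_2d(np.asarray(signals, float))
    n_ch, n_samp = sig.shape
    spr = int(round(sampling_rate))
    if abs(spr - sampling_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = sig

    dig_min, dig_max = -32768, 32767
    # digitise against the header-rounded bounds so reader and writer agree;
    # widen before rounding so the 6-significant-figure header still covers
    # the data, and clip so no sample can wrap the 16-bit range
    lo = np.minimum(padded.min(1), -1e-6)
    hi = np.maximum(padded.max(1), 1e-6)
    lo -= np.abs(lo) * 1e-4
    hi += np.abs(hi) * 1e-4
    phys_min = np.array([float(f"{v:.6g}"[:8]) for v in lo])
    phys_max = np.array([float(f"{v:.6g}"[:8]) for v in hi])
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * scale[:, None]
                      + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))                  # patient id (anonymous)
        fh.write(_pad("Startdate X X X X", 80))        # recording id
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))                         # record duration 1 s
        fh.write(_pad(str(n_ch), 4))
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))                     # transducer
        for _ in range(n_ch):
            fh.write(_pad(physical_dim, 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))                     # prefiltering
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())
    return Path(path)


def read_edf(path):
    """Read an EDF file; returns (signals (n_ch, n_samples) in µV, rate)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6          # mne scales µV channels to volts
    return data, float(raw.info["sfreq"])


# --- synthetic recordings (EDF + CSV events + JSON ground truth) -----------

def write_recording(rec: SyntheticRecording, stem) -> dict:
    """Write signal as EDF plus the event sheet and ground-truth sidecar.

    Returns the paths written, keyed 'edf', 'events', 'ground_truth'.
    """
    stem = Path(stem)
    paths = {
        "edf": write_edf(stem.with_suffix(".edf"), rec.signal,
                         rec.sampling_rate, labels=["Cz"]),
        "events": write_events_csv(rec.events, stem.parent / (stem.name + "_events.csv")),
        "ground_truth": stem.parent / (stem.name + "_truth.json"),
    }
    truth = rec.ground_truth.to_dict(orient="list")
    truth["in_window"] = [bool(v) for v in truth["in_window"]]
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def read_recording(stem) -> SyntheticRecording:
    stem = Path(stem)
    signals, fs = read_edf(stem.with_suffix(".edf"))
    events = read_events_csv(stem.parent / (stem.name + "_events.csv"))
    with open(stem.parent / (stem.name + "_truth.json")) as fh:
        truth = pd.DataFrame(json.load(fh))
    return SyntheticRecording(signals[0], fs, events, truth)
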