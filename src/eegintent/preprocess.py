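"""Cleaning and epoching of raw question recordings.

Fixed pipeline order: anti-aliased resample to 250 Hz; zero-phase 1 Hz
high-pass; notch at the line frequency and its first harmonic; bad-channel
detection (flat line or low correlation with every other channel) with
distance-weighted interpolation; average re-reference over the full montage.
Interactive artifact-subspace / ICA cleaning used on real lab data is out of
scope; the bad-channel stage plus an optional amplitude-threshold epoch
rejection stand in for it, and every applied step is recorded in the log so
users can substitute heavier cleaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from eegintent.channels import position_array
from eegintent.synth import RawRecording


class RecordingRejectedError(RuntimeError):
    """Raised when too many channels fail quality checks to interpolate."""


@dataclass(frozen=True)
class PreprocessParams:
    target_fs: float = 250.0
    highpass_hz: float = 1.0
    highpass_order: int = 4
    line_freq_hz: float = 50.0
    notch_bandwidth_hz: float = 1.0
    flat_variance_uv2: float = 1e-10
    min_neighbor_corr: float = 0.4
    max_bad_fraction: float = 0.5


@dataclass
class CleanRecording:
    channel_names: tuple[str, ...]
    signal: np.ndarray  # (n_channels, n_samples) at target_fs
    fs: float
    subject: str = ""
    question: int = 0
    scenario_type: str = ""
    answer: str = ""
    responded: bool = True
    interpolated: list[str] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    signal: np.ndarray  # (n_channels, n)
    fs: float
    start: float       # seconds within the question
    duration: float
    channel_names: tuple[str, ...]
    subject: str = ""
    question: int = 0
    scenario_type: str = ""
    answer: str = ""


def _resample(signal: np.ndarray, fs: float, target: float) -> np.ndarray:
    if fs == target:
        return signal.copy()
    g = math.gcd(int(round(target * 1000)), int(round(fs * 1000)))
    up = int(round(target * 1000)) // g
    down = int(round(fs * 1000)) // g
    return sps.resample_poly(signal, up, down, axis=1)


def detect_bad_channels(signal: np.ndarray, params: PreprocessParams) -> list[int]:
    """Indices of flat-line or low-correlation channels."""
    bad: set[int] = set()
    var = signal.var(axis=1)
    bad.update(np.nonzero(var < params.flat_variance_uv2)[0].tolist())
    ok = np.nonzero(var >= params.flat_variance_uv2)[0]
    if len(ok) >= 2:
        corr = np.corrcoef(signal[ok])
        np.fill_diagonal(corr, 0.0)
        max_corr = np.abs(corr).max(axis=1)
        for k, c in enumerate(ok):
            if max_corr[k] < params.min_neighbor_corr:
                bad.add(int(c))
    return sorted(bad)


def interpolate_channels(
    signal: np.ndarray, channel_names: tuple[str, ...], bad: list[int]
) -> np.ndarray:
    """Inverse-squared-distance interpolation of bad channels from good ones."""
    out = signal.copy()
    good = [i for i in range(signal.shape[0]) if i not in bad]
    if not bad:
        return out
    if not good:
        raise RecordingRejectedError("no good channels left to interpolate from")
    pos = position_array(channel_names)
    for b in bad:
        d2 = ((pos[good] - pos[b]) ** 2).sum(axis=1)
        w = 1.0 / np.maximum(d2, 1e-6)
        w /= w.sum()
        out[b] = w @ signal[good]
    return out


def preprocess_recording(
    raw: RawRecording, params: PreprocessParams | None = None
) -> CleanRecording:
    """Run the fixed cleaning pipeline on one question recording."""
    params = params or PreprocessParams()
    if raw.fs < params.target_fs:
        raise ValueError(f"sampling rate {raw.fs} Hz below target {params.target_fs} Hz")
    if raw.duration < 2.0:
        raise ValueError("recording must provide at least 2 s of signal")

    log: list[dict] = []
    x = _resample(raw.signal, raw.fs, params.target_fs)
    fs = params.target_fs
    log.append({"step": "resample", "from_hz": raw.fs, "to_hz": fs})

    sos = sps.butter(params.highpass_order, params.highpass_hz, btype="highpass",
                     fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    log.append({"step": "highpass", "cutoff_hz": params.highpass_hz,
                "order": params.highpass_order, "zero_phase": True})

    for f0 in (params.line_freq_hz, 2 * params.line_freq_hz):
        if 0 < f0 < fs / 2:
            b, a = sps.iirnotch(f0, f0 / params.notch_bandwidth_hz, fs=fs)
            x = sps.filtfilt(b, a, x, axis=1)
            log.append({"step": "notch", "freq_hz": f0,
                        "bandwidth_hz": params.notch_bandwidth_hz})

    bad = detect_bad_channels(x, params)
    if len(bad) > params.max_bad_fraction * x.shape[0]:
        raise RecordingRejectedError(
            f"{len(bad)} of {x.shape[0]} channels flagged bad "
            f"(> {params.max_bad_fraction:.0%}): "
            f"{[raw.channel_names[i] for i in bad]}"
        )
    x = interpolate_channels(x, raw.channel_names, bad)
    log.append({"step": "bad_channels",
                "interpolated": [raw.channel_names[i] for i in bad]})

    x = x - x.mean(axis=0, keepdims=True)
    log.append({"step": "average_reference", "n_channels": x.shape[0]})

    return CleanRecording(
        channel_names=raw.channel_names,
        signal=x,
        fs=fs,
        subject=raw.subject,
        question=raw.question,
        scenario_type=raw.scenario_type,
        answer=raw.answer,
        responded=raw.responded,
        interpolated=[raw.channel_names[i] for i in bad],
        log=log,
    )


def epoch_question(
    clean: CleanRecording,
    window: float = 2.0,
    step: float = 1.0,
    min_len: float = 1.0,
    amplitude_reject_uv: float | None = None,
) -> list[Epoch]:
    """Cut a cleaned question into sliding windows.

    Full ``window``-second epochs start at 0, step, 2*step, ...; a recording
    shorter than ``window`` but at least ``min_len`` long is emitted whole as
    one short epoch; anything shorter yields no epochs.  A 30 s question at the
    2 s / 1 s defaults gives 29 epochs.  ``amplitude_reject_uv`` optionally
    drops epochs whose absolute amplitude exceeds the threshold (off by
    default).
    """
    T = clean.duration
    fs = clean.fs
    epochs: list[Epoch] = []

    def emit(start: float, dur: float) -> None:
        i0 = int(round(start * fs))
        n = int(round(dur * fs))
        seg = clean.signal[:, i0 : i0 + n]
        if amplitude_reject_uv is not None and np.abs(seg).max() > amplitude_reject_uv:
            return
        epochs.append(
            Epoch(
                signal=seg,
                fs=fs,
                start=start,
                duration=dur,
                channel_names=clean.channel_names,
                subject=clean.subject,
                question=clean.question,
                scenario_type=clean.scenario_type,
                answer=clean.answer,
            )
        )

    if T >= window:
        k = 0
        # tolerate float rounding at the last full window
        while k * step + window <= T + 1e-9:
            emit(k * step, window)
            k += 1
    elif T >= min_len:
        emit(0.0, T)
    return epochs
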