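"""Seeded synthetic 21-channel EEG for question trials.

The generative model is deliberately minimal: each channel is a sum of
1/f^gamma background noise, band-limited Gaussian oscillations (theta, alpha,
beta) with per-subject log-amplitude offsets, and a flat broadband component.
Class-conditional effects act multiplicatively on band amplitudes:

* ``intent_effect`` shifts log(beta power / alpha power) by its value for
  affirmative answers within insider-threat questions (alertness signature:
  alpha down, beta up);
* ``scenario_effect`` applies the same band shift to all insider questions
  and additionally scales the broadband component, moving entropy-family
  features between scenario types.

A shared across-channel component (mixing fraction ``rho``) gives the
inter-channel correlation real scalp EEG shows, which the bad-channel
detector relies on.  Artifacts (line noise, drift, blinks, dead channels)
are injected separately so the cleaning stage has known targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from eegintent.channels import CHANNELS_1020
from eegintent.seeding import STAGE, as_rng, rng

BANDS = ("theta", "alpha", "beta")
_BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 25.0)}
# baseline RMS amplitudes in microvolts
_BASE_AMP = {"theta": 2.5, "alpha": 4.0, "beta": 1.5}
_BG_RMS = 6.0
_BROADBAND_RMS = 1.5
_RHO = 0.5  # variance fraction shared across channels


@dataclass(frozen=True)
class ArtifactConfig:
    """Amplitudes/rates of injected artifacts; all zero means no-op."""

    line_amplitude_uv: float = 2.0
    line_freq_hz: float = 50.0
    drift_amplitude_uv: float = 5.0
    drift_freq_hz: float = 0.3
    blink_rate_hz: float = 0.2
    blink_amplitude_uv: float = 80.0
    dead_channel_prob: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "line_amplitude_uv",
            "drift_amplitude_uv",
            "blink_rate_hz",
            "blink_amplitude_uv",
            "dead_channel_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactConfig":
        return cls(
            line_amplitude_uv=0.0,
            drift_amplitude_uv=0.0,
            blink_rate_hz=0.0,
            dead_channel_prob=0.0,
        )


@dataclass(frozen=True)
class EffectSpec:
    """Class-conditional effect sizes and nuisance scales.

    ``intent_effect`` and ``scenario_effect`` are shifts of
    log(beta power / alpha power); ``scenario_effect`` additionally scales
    the broadband (entropy-carrying) component by exp(effect / 2).
    Zero effects yield class-exchangeable signals.
    """

    intent_effect: float = 0.0
    scenario_effect: float = 0.0
    subject_variability: float = 0.2
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)

    def __post_init__(self) -> None:
        if self.intent_effect < 0 or self.scenario_effect < 0:
            raise ValueError("effect magnitudes must be >= 0")
        if self.subject_variability < 0:
            raise ValueError("subject_variability must be >= 0")


@dataclass
class RawRecording:
    """One question trial's multichannel signal in microvolts."""

    channel_names: tuple[str, ...]
    signal: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    subject: str = ""
    question: int = 0
    scenario_type: str = ""
    answer: str = ""
    responded: bool = True

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_names):
            raise ValueError("signal must be (n_channels, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "RawRecording":
        return replace(self, signal=self.signal.copy())


def draw_subject_baseline(subject_variability: float, seed) -> dict[str, float]:
    """Per-subject log-amplitude offsets for the three oscillatory bands."""
    g = as_rng(seed)
    return {b: float(g.normal(0.0, subject_variability)) for b in BANDS}


def _one_over_f(n: int, g: np.random.Generator, gamma: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f^gamma noise via spectral shaping."""
    white = g.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]  # avoid div by zero; DC handled by high-pass later anyway
    spec *= f ** (-gamma / 2.0)
    x = np.fft.irfft(spec, n)
    return x / (x.std() + 1e-30)


def _band_noise(n: int, fs: float, band: tuple[float, float], g: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # pad to let the filter settle, then trim
    pad = int(fs)
    x = sps.sosfilt(sos, g.normal(size=n + 2 * pad))[pad:-pad]
    return x / (x.std() + 1e-30)


def _band_amplitudes(trial, effects: EffectSpec, subject_baseline: dict[str, float]):
    """Resolve per-band RMS amplitudes and the broadband scale for a trial."""
    shift = {b: 0.0 for b in BANDS}
    broadband_scale = 1.0
    if trial.scenario_type == "insider":
        shift["beta"] += effects.scenario_effect / 4.0
        shift["alpha"] -= effects.scenario_effect / 4.0
        broadband_scale = float(np.exp(effects.scenario_effect / 2.0))
        if trial.answer == "yes":
            shift["beta"] += effects.intent_effect / 4.0
            shift["alpha"] -= effects.intent_effect / 4.0
    amps = {
        b: _BASE_AMP[b] * float(np.exp(subject_baseline.get(b, 0.0) + shift[b]))
        for b in BANDS
    }
    return amps, broadband_scale


def synthesize_question_recording(
    trial,
    effects: EffectSpec,
    subject_baseline: dict[str, float] | None,
    seed,
    fs: float = 500.0,
    duration: float = 30.0,
) -> RawRecording:
    """Generate one trial's clean (artifact-free) 21-channel recording.

    Deterministic given (trial, effects, baseline, seed).  Amplitude shifts
    follow the trial's scenario type and answer; see module docstring.
    """
    g = as_rng(seed)
    baseline = subject_baseline or {}
    n = int(round(duration * fs))
    amps, broadband_scale = _band_amplitudes(trial, effects, baseline)

    n_ch = len(CHANNELS_1020)
    out = np.zeros((n_ch, n))
    w_common, w_priv = np.sqrt(_RHO), np.sqrt(1.0 - _RHO)

    # shared sources (one realization per component)
    common = {"bg": _one_over_f(n, g)}
    for b in BANDS:
        common[b] = _band_noise(n, fs, _BAND_EDGES[b], g)
    common["bb"] = g.normal(size=n)

    for c in range(n_ch):
        x = _BG_RMS * (w_common * common["bg"] + w_priv * _one_over_f(n, g))
        for b in BANDS:
            priv = _band_noise(n, fs, _BAND_EDGES[b], g)
            x += amps[b] * (w_common * common[b] + w_priv * priv)
        bb = w_common * common["bb"] + w_priv * g.normal(size=n)
        x += _BROADBAND_RMS * broadband_scale * bb
        out[c] = x

    return RawRecording(
        channel_names=CHANNELS_1020,
        signal=out,
        fs=fs,
        subject=getattr(trial, "subject", ""),
        question=getattr(trial, "question", 0),
        scenario_type=getattr(trial, "scenario_type", ""),
        answer=getattr(trial, "answer", ""),
        responded=getattr(trial, "responded", True),
    )


def inject_artifacts(raw: RawRecording, config: ArtifactConfig, seed) -> RawRecording:
    """Add line noise, slow drift, frontopolar blink transients, dead channels.

    With every amplitude/rate/probability at zero this is the identity (up to
    a copy).  Blinks are positive transients on FP1/FPz/FP2 only.
    """
    g = as_rng(seed)
    rec = raw.copy()
    n = rec.n_samples
    t = np.arange(n) / rec.fs

    if config.line_amplitude_uv > 0:
        for c in range(rec.signal.shape[0]):
            phase = g.uniform(0, 2 * np.pi)
            rec.signal[c] += config.line_amplitude_uv * np.sin(
                2 * np.pi * config.line_freq_hz * t + phase
            )

    if config.drift_amplitude_uv > 0:
        for c in range(rec.signal.shape[0]):
            phase = g.uniform(0, 2 * np.pi)
            rec.signal[c] += config.drift_amplitude_uv * np.sin(
                2 * np.pi * config.drift_freq_hz * t + phase
            )

    if config.blink_rate_hz > 0:
        n_blinks = g.poisson(config.blink_rate_hz * rec.duration)
        frontal = [rec.channel_names.index(ch) for ch in ("FP1", "FPz", "FP2")
                   if ch in rec.channel_names]
        weights = {0: 0.9, 1: 1.0, 2: 0.9}
        width = 0.15  # seconds (gaussian sigma)
        for _ in range(n_blinks):
            center = g.uniform(0, rec.duration)
            pulse = config.blink_amplitude_uv * np.exp(-0.5 * ((t - center) / width) ** 2)
            for k, c in enumerate(frontal):
                rec.signal[c] += weights.get(k, 1.0) * pulse

    if config.dead_channel_prob > 0 and g.random() < config.dead_channel_prob:
        c = int(g.integers(0, rec.signal.shape[0]))
        rec.signal[c] = 0.0

    return rec


def synthesize_experiment(
    design,
    effects: EffectSpec,
    seed: int,
    fs: float = 500.0,
    duration: float = 30.0,
    with_artifacts: bool = True,
):
    """Yield one (possibly artifact-laden) RawRecording per trial of a design.

    Per-subject baselines and per-question signal/artifact streams are derived
    from the master seed by the package seed-splitting rule, so any subject or
    question can be regenerated in isolation.
    """
    subjects = design.subjects
    baselines = {
        s: draw_subject_baseline(effects.subject_variability, rng(seed, STAGE["baseline"], i))
        for i, s in enumerate(subjects)
    }
    s_index = {s: i for i, s in enumerate(subjects)}
    for trial in design.trials:
        si = s_index[trial.subject]
        rec = synthesize_question_recording(
            trial,
            effects,
            baselines[trial.subject],
            rng(seed, STAGE["signal"], si, trial.question),
            fs=fs,
            duration=duration,
        )
        if with_artifacts:
            rec = inject_artifacts(
                rec, effects.artifacts, rng(seed, STAGE["artifact"], si, trial.question)
            )
        yield rec
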