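"""Synthetic ECG / PPG / EDA generator emulating a low-cost wearable acquisition chain.

The forward model mirrors a chest-strap sensing front end: biopotential or
optical signal -> analog conditioning (an instrumentation amplifier for ECG,
a resistive voltage divider for EDA) -> additive 50 Hz mains pick-up and
EMG-like motion artifact -> 12-bit ADC sampling against a 3.3 V reference.

Emotion-class-conditional parameters (heart rate, heart-rate variability,
tonic skin resistance, skin-conductance-response rate, pulse amplitude) make
the generated recordings a labelled dataset on which classifier recovery can
be measured against known ground truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

EMOTION_LABELS = (
    "Afraid",
    "Angry",
    "Disgusted",
    "Happy",
    "Neutral",
    "Sad",
    "Surprised",
)

CHANNELS = ("ECG", "PPG", "EDA")


@dataclass(frozen=True)
class SimConfig:
    """Acquisition-chain parameters.

    Defaults reflect the emulated hardware: a 12-bit ADC referenced at
    3.3 V (quantization step 3.3/4096 ~= 0.0008 V), a 500 kOhm series
    resistor in the EDA voltage divider, and European 50 Hz mains.
    The sampling rate is a package default (250 Hz), chosen so that the
    48-52 Hz stop band sits well below Nyquist.
    """

    sampling_rate_hz: float = 250.0
    duration_s: float = 10.0
    adc_bits: int = 12
    vref_volts: float = 3.3
    divider_r1_ohms: float = 5.0e5
    mains_freq_hz: float = 50.0
    mains_amplitude: float = 0.02
    motion_artifact_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise InvalidParameterError("sampling rate and duration must be positive")
        if self.sampling_rate_hz <= 2.0 * self.mains_freq_hz:
            raise InvalidParameterError(
                f"sampling_rate_hz={self.sampling_rate_hz} must exceed twice the "
                f"mains frequency ({self.mains_freq_hz} Hz) for the contaminant "
                "to exist in-band"
            )
        if self.adc_bits < 1:
            raise InvalidParameterError("adc_bits must be >= 1")
        if self.vref_volts <= 0:
            raise InvalidParameterError("vref_volts must be positive")
        if self.divider_r1_ohms <= 0:
            raise InvalidParameterError("divider_r1_ohms must be positive")
        if self.mains_amplitude < 0 or self.motion_artifact_level < 0:
            raise InvalidParameterError("noise amplitudes must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    @property
    def adc_step_volts(self) -> float:
        return self.vref_volts / (2 ** self.adc_bits)


@dataclass(frozen=True)
class EmotionClassParams:
    """Class-conditional physiology for one emotion label.

    heart_rate_bpm drives both ECG beat spacing and the PPG pulse train;
    hr_variability is the standard deviation of the beat-to-beat interval
    as a fraction of the mean interval; eda_tonic_level_ohms is the slowly
    drifting baseline skin resistance; eda_scr_rate_per_min the Poisson rate
    of phasic skin-conductance responses; ppg_amplitude the pulse height in
    volts at the ADC input.
    """

    label: str
    heart_rate_bpm: float
    hr_variability: float
    eda_tonic_level_ohms: float
    eda_scr_rate_per_min: float
    ppg_amplitude: float

    def __post_init__(self) -> None:
        if self.label not in EMOTION_LABELS:
            raise InvalidParameterError(f"unknown emotion label {self.label!r}")
        if self.heart_rate_bpm <= 0:
            raise InvalidParameterError("heart_rate_bpm must be positive")
        if self.hr_variability < 0:
            raise InvalidParameterError("hr_variability must be non-negative")
        if self.eda_tonic_level_ohms <= 0:
            raise InvalidParameterError("eda_tonic_level_ohms must be positive")
        if self.eda_scr_rate_per_min < 0:
            raise InvalidParameterError("eda_scr_rate_per_min must be non-negative")
        if self.ppg_amplitude <= 0:
            raise InvalidParameterError("ppg_amplitude must be positive")


# Arousal/valence-plausible, separable-but-overlapping defaults. High-arousal
# states get faster hearts, more SCRs and lower tonic skin resistance.
DEFAULT_CLASS_PARAMS: tuple[EmotionClassParams, ...] = (
    EmotionClassParams("Afraid", 100.0, 0.09, 5.5e5, 8.0, 0.45),
    EmotionClassParams("Angry", 95.0, 0.07, 6.0e5, 7.0, 0.55),
    EmotionClassParams("Disgusted", 78.0, 0.06, 7.5e5, 4.0, 0.50),
    EmotionClassParams("Happy", 84.0, 0.05, 7.0e5, 5.0, 0.65),
    EmotionClassParams("Neutral", 66.0, 0.04, 9.0e5, 1.5, 0.50),
    EmotionClassParams("Sad", 58.0, 0.05, 1.05e6, 1.0, 0.40),
    EmotionClassParams("Surprised", 90.0, 0.08, 6.5e5, 6.0, 0.60),
)


@dataclass
class Biosignal:
    """One uniformly sampled channel, in volts (or snapped to the ADC grid)."""

    channel: str
    samples: np.ndarray
    sampling_rate_hz: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise InvalidParameterError(f"unknown channel kind {self.channel!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional")
        if self.samples.size < 3:
            raise InvalidParameterError("a biosignal needs at least 3 samples")
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz


def eda_divider_voltage(skin_resistance_ohms, config: SimConfig):
    """Voltage across the series resistor R1 of the EDA divider.

    The skin (resistance RL, megaohm range) and a fixed R1 form a divider
    driven by the battery voltage, so V = vref * R1 / (R1 + RL): strictly
    decreasing in RL and bounded in (0, vref). Accepts scalars or arrays.
    """
    rl = np.asarray(skin_resistance_ohms, dtype=float)
    if np.any(rl <= 0):
        raise InvalidParameterError("skin resistance must be positive")
    r1 = config.divider_r1_ohms
    out = config.vref_volts * r1 / (r1 + rl)
    return float(out) if out.ndim == 0 else out


def quantize_adc(signal: Biosignal, config: SimConfig) -> Biosignal:
    """Clip to [0, vref] and snap to the ADC code grid.

    Values are returned in volts on the grid (multiples of vref / 2^bits)
    so downstream arithmetic stays unit-stable; over-range samples saturate
    rather than error, mirroring a real converter.
    """
    step = config.adc_step_volts
    clipped = np.clip(signal.samples, 0.0, config.vref_volts)
    snapped = np.round(clipped / step) * step
    # the top code cannot exceed full scale
    snapped = np.minimum(snapped, config.vref_volts)
    return Biosignal(signal.channel, snapped, signal.sampling_rate_hz, signal.label)


def adc_counts(signal: Biosignal, config: SimConfig) -> np.ndarray:
    """Integer ADC codes for a quantized (or raw, volts) signal."""
    step = config.adc_step_volts
    clipped = np.clip(signal.samples, 0.0, config.vref_volts)
    return np.round(clipped / step).astype(int)


def _beat_times(rng: np.random.Generator, params: EmotionClassParams, duration_s: float) -> np.ndarray:
    """Beat onset times with Gaussian beat-to-beat jitter."""
    mean_rr = 60.0 / params.heart_rate_bpm
    times = []
    t = -mean_rr * float(rng.uniform(0.0, 1.0))  # random phase so recordings differ
    while t < duration_s + mean_rr:
        times.append(t)
        rr = mean_rr * max(0.3, 1.0 + params.hr_variability * float(rng.standard_normal()))
        t += rr
    return np.asarray(times)


# PQRST as a sum of Gaussians: (delay from beat onset [s], amplitude [V], width [s]).
# Morphological realism beyond spectral/statistical plausibility is not needed;
# the downstream pipeline consumes only per-recording statistics.
_PQRST = (
    (0.00, 0.04, 0.020),   # P
    (0.14, -0.04, 0.010),  # Q
    (0.16, 0.45, 0.008),   # R
    (0.18, -0.08, 0.010),  # S
    (0.34, 0.10, 0.030),   # T
)


def _render_gaussians(t: np.ndarray, centers: np.ndarray, amps: np.ndarray, widths: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for c, a, w in zip(centers, amps, widths):
        lo = np.searchsorted(t, c - 5 * w)
        hi = np.searchsorted(t, c + 5 * w)
        seg = t[lo:hi]
        out[lo:hi] += a * np.exp(-0.5 * ((seg - c) / w) ** 2)
    return out


def _ecg_clean(t: np.ndarray, rng: np.random.Generator, params: EmotionClassParams) -> np.ndarray:
    baseline = 1.45
    sig = np.full_like(t, baseline)
    for onset in _beat_times(rng, params, t[-1] if t.size else 0.0):
        centers = np.asarray([onset + d for d, _, _ in _PQRST])
        amps = np.asarray([a for _, a, _ in _PQRST])
        widths = np.asarray([w for _, _, w in _PQRST])
        sig += _render_gaussians(t, centers, amps, widths)
    # slow respiratory baseline wander
    sig += 0.03 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    return sig


def _ppg_clean(t: np.ndarray, rng: np.random.Generator, params: EmotionClassParams) -> np.ndarray:
    baseline = 1.2
    sig = np.full_like(t, baseline)
    for onset in _beat_times(rng, params, t[-1] if t.size else 0.0):
        # systolic upstroke plus a smaller dicrotic bump
        centers = np.asarray([onset + 0.20, onset + 0.45])
        amps = params.ppg_amplitude * np.asarray([1.0, 0.35])
        widths = np.asarray([0.09, 0.12])
        sig += _render_gaussians(t, centers, amps, widths)
    return sig


def _eda_resistance(t: np.ndarray, rng: np.random.Generator, params: EmotionClassParams) -> np.ndarray:
    """Tonic drift plus exponential-decay phasic drops in skin resistance."""
    tonic = params.eda_tonic_level_ohms * (
        1.0
        + 0.05 * np.sin(2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
        + 0.02 * np.sin(2 * np.pi * 0.055 * t + rng.uniform(0, 2 * np.pi))
    )
    resistance = tonic.copy()
    duration = t[-1] if t.size else 0.0
    n_scr = rng.poisson(params.eda_scr_rate_per_min * duration / 60.0)
    for onset in np.sort(rng.uniform(0.0, duration, size=n_scr)):
        mask = t >= onset
        dt = t[mask] - onset
        rise, decay = 0.75, 3.5  # seconds; typical SCR shape
        drop = rng.uniform(0.05, 0.15) * params.eda_tonic_level_ohms
        resistance[mask] -= drop * (1 - np.exp(-dt / rise)) * np.exp(-dt / decay)
    return np.maximum(resistance, 1e4)


def simulate_channel(channel: str, params: EmotionClassParams, config: SimConfig) -> Biosignal:
    """Simulate one labelled channel through the full acquisition chain.

    Deterministic for a given config.seed. Mains contamination is a sinusoid
    at config.mains_freq_hz; motion artifact is EMG-like broadband noise
    high-pass shaped above ~20 Hz and scaled by motion_artifact_level.
    """
    if channel not in CHANNELS:
        raise InvalidParameterError(f"unknown channel kind {channel!r}")
    n = config.n_samples
    if n < 3:
        raise InvalidParameterError(
            "duration too short: need at least 3 samples at this sampling rate"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, CHANNELS.index(channel)])
    )
    t = np.arange(n) / config.sampling_rate_hz
    if channel == "ECG":
        clean = _ecg_clean(t, rng, params)
    elif channel == "PPG":
        clean = _ppg_clean(t, rng, params)
    else:
        clean = eda_divider_voltage(_eda_resistance(t, rng, params), config)

    noisy = clean.copy()
    if config.mains_amplitude > 0:
        noisy = noisy + config.mains_amplitude * np.sin(
            2 * np.pi * config.mains_freq_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if config.motion_artifact_level > 0:
        white = rng.standard_normal(n)
        # first difference shapes white noise toward high frequencies (EMG-like)
        emg = np.diff(white, prepend=white[0])
        rms = np.sqrt(np.mean(emg**2))
        if rms > 0:
            noisy = noisy + config.motion_artifact_level * emg / rms

    raw = Biosignal(channel, noisy, config.sampling_rate_hz, params.label)
    return quantize_adc(raw, config)


def simulate_recording(params: EmotionClassParams, config: SimConfig) -> tuple[Biosignal, Biosignal, Biosignal]:
    """One labelled (ECG, PPG, EDA) triple."""
    return tuple(simulate_channel(ch, params, config) for ch in CHANNELS)  # type: ignore[return-value]


def simulate_labeled_dataset(
    class_params: Sequence[EmotionClassParams],
    n_per_class: int,
    config: SimConfig,
) -> list[tuple[Biosignal, Biosignal, Biosignal]]:
    """n_per_class labelled (ECG, PPG, EDA) triples per emotion class.

    Per-recording seeds are spawned deterministically from config.seed, so the
    whole dataset is reproducible and recordings are mutually independent.
    """
    if n_per_class < 1:
        raise InvalidParameterError("n_per_class must be >= 1")
    if not 1 <= len(class_params) <= len(EMOTION_LABELS):
        raise InvalidParameterError("need between 1 and 7 emotion classes")
    labels = [p.label for p in class_params]
    if len(set(labels)) != len(labels):
        raise InvalidParameterError("duplicate labels in class_params")

    base = np.random.SeedSequence(config.seed & 0x7FFFFFFF)
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in base.spawn(len(class_params) * n_per_class)]
    dataset = []
    k = 0
    for params in class_params:
        for _ in range(n_per_class):
            rec_config = replace(config, seed=child_seeds[k])
            dataset.append(simulate_recording(params, rec_config))
            k += 1
    return dataset


# ---------------------------------------------------------------------------
# plain-text recording I/O: CSV per channel + JSON sidecar
# ---------------------------------------------------------------------------

def write_recording(signal: Biosignal, csv_path: str | Path, seed: int | None = None) -> Path:
    """Write one channel as `time_s,value` CSV plus a JSON sidecar."""
    csv_path = Path(csv_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(signal.times(), signal.samples):
            writer.writerow([f"{t:.6f}", f"{v:.6f}"])
    sidecar = {
        "channel": signal.channel,
        "sampling_rate_hz": signal.sampling_rate_hz,
        "label": signal.label,
        "seed": seed,
    }
    sidecar_path = csv_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return csv_path


def read_recording(csv_path: str | Path) -> Biosignal:
    """Read a channel written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    values = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            values.append(float(row["value"]))
    return Biosignal(
        channel=sidecar["channel"],
        samples=np.asarray(values),
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        label=sidecar.get("label"),
    )
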