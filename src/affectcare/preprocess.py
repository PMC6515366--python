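"""Powerline-noise removal: a Butterworth band-stop filter around 50 Hz.

The default design (order 3, stop band 48-52 Hz) removes European mains
interference from the biosignals before feature extraction. Application is
zero-phase (forward-backward), appropriate for offline windowed processing;
note this doubles the effective order of the magnitude response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError
from .signal_sim import Biosignal


@dataclass(frozen=True)
class FilterSpec:
    """A designed digital band-stop filter as rational transfer-function coefficients."""

    order: int
    low_cutoff_hz: float
    high_cutoff_hz: float
    sampling_rate_hz: float
    numerator: tuple[float, ...]
    denominator: tuple[float, ...]
    response: str = "bandstop"
    family: str = "Butterworth"

    @property
    def padlen(self) -> int:
        """Reflect-padding length used by apply_filter: 3x the tap order."""
        return 3 * (max(len(self.numerator), len(self.denominator)) - 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "response": self.response,
                "family": self.family,
                "order": self.order,
                "low_cutoff_hz": self.low_cutoff_hz,
                "high_cutoff_hz": self.high_cutoff_hz,
                "sampling_rate_hz": self.sampling_rate_hz,
                "numerator": list(self.numerator),
                "denominator": list(self.denominator),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterSpec":
        d = json.loads(text)
        return cls(
            order=d["order"],
            low_cutoff_hz=d["low_cutoff_hz"],
            high_cutoff_hz=d["high_cutoff_hz"],
            sampling_rate_hz=d["sampling_rate_hz"],
            numerator=tuple(d["numerator"]),
            denominator=tuple(d["denominator"]),
            response=d.get("response", "bandstop"),
            family=d.get("family", "Butterworth"),
        )


def design_bandstop(
    order: int = 3,
    low_hz: float = 48.0,
    high_hz: float = 52.0,
    fs_hz: float = 250.0,
) -> FilterSpec:
    """Design the band-stop Butterworth filter.

    Raises InvalidParameterError if the cutoffs are not strictly ordered
    inside (0, Nyquist). The returned denominator is normalized to a leading
    coefficient of 1 and all its roots lie strictly inside the unit circle.
    """
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    nyquist = fs_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyquist):
        raise InvalidParameterError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyquist})"
        )
    b, a = sps.butter(order, [low_hz, high_hz], btype="bandstop", fs=fs_hz)
    b = b / a[0]
    a = a / a[0]
    return FilterSpec(
        order=order,
        low_cutoff_hz=low_hz,
        high_cutoff_hz=high_hz,
        sampling_rate_hz=fs_hz,
        numerator=tuple(b),
        denominator=tuple(a),
    )


def apply_filter(spec: FilterSpec, signal: Biosignal) -> Biosignal:
    """Zero-phase (forward-backward) application of the filter.

    The signal is reflect-padded by spec.padlen samples before the
    forward-backward pass so that the output is reproducible bit-for-bit
    given the same convention. Output length equals input length.
    """
    if spec.sampling_rate_hz != signal.sampling_rate_hz:
        raise InvalidParameterError(
            f"filter designed for {spec.sampling_rate_hz} Hz but signal is "
            f"{signal.sampling_rate_hz} Hz"
        )
    if len(signal) <= spec.padlen:
        raise InvalidParameterError(
            f"signal length {len(signal)} too short for padding {spec.padlen}"
        )
    filtered = sps.filtfilt(
        spec.numerator,
        spec.denominator,
        signal.samples,
        padtype="even",
        padlen=spec.padlen,
    )
    return Biosignal(signal.channel, filtered, signal.sampling_rate_hz, signal.label)


def filter_response(spec: FilterSpec, freqs_hz: Sequence[float]) -> np.ndarray:
    """Magnitude response 20*log10|H(f)| in dB at the requested frequencies.

    At the exact notch zero the true response is -infinity; values are
    floored at -300 dB to keep the output finite.
    """
    freqs = np.asarray(freqs_hz, dtype=float)
    if freqs.size == 0:
        return np.empty(0)
    nyquist = spec.sampling_rate_hz / 2.0
    if np.any(freqs < 0) or np.any(freqs >= nyquist):
        raise InvalidParameterError(f"frequencies must lie in [0, {nyquist})")
    _, h = sps.freqz(spec.numerator, spec.denominator, worN=freqs, fs=spec.sampling_rate_hz)
    mag = np.abs(h)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag)
    return np.maximum(db, -300.0)
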