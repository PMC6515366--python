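"""Per-channel statistical features and assembly of the classifier input.

Each channel is summarised by six classic affective-computing statistics:
the mean, the sample standard deviation, and the mean absolute first and
second differences computed on both the raw and the z-normalized samples
(AFD, AFDN, ASD, ASDN). Three channels (ECG, PPG, EDA) times six statistics
give the fixed 18-dimensional input of the emotion classifier.

Conventions: the standard deviation uses the sample (1/(N-1)) normalization
everywhere, including inside z-normalization; the normalized variants are the
same difference statistics evaluated on the z-scored samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateSignalError, InvalidParameterError
from .signal_sim import CHANNELS, Biosignal

FEATURE_NAMES = ("mean", "std", "afd", "afdn", "asd", "asdn")

#: Column order of the assembled 18-vector: ECG block, PPG block, EDA block,
#: six statistics each in FEATURE_NAMES order. Stable across package versions.
VECTOR_COLUMNS = tuple(
    f"{ch.lower()}_{stat}" for ch in CHANNELS for stat in FEATURE_NAMES
)


@dataclass(frozen=True)
class ChannelFeatures:
    """The six statistics of one channel."""

    mean: float
    std: float
    afd: float
    afdn: float
    asd: float
    asdn: float

    def as_array(self) -> np.ndarray:
        return np.asarray([getattr(self, f.name) for f in dc_fields(self)])


@dataclass
class FeatureVector:
    """The assembled 18-dimensional classifier input, optionally labelled."""

    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (18,):
            raise InvalidParameterError(
                f"a feature vector has exactly 18 entries, got shape {self.values.shape}"
            )


def _sample_std(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def znormalize(signal: Biosignal) -> Biosignal:
    """Z-score the samples: subtract the mean, divide by the sample std.

    Raises DegenerateSignalError for a constant signal, where the statistic
    is undefined; the caller decides the fallback.
    """
    x = signal.samples
    sd = _sample_std(x)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSignalError("cannot z-normalize a constant signal")
    z = (x - np.mean(x)) / sd
    return Biosignal(signal.channel, z, signal.sampling_rate_hz, signal.label)


def _mean_abs_diff(x: np.ndarray, lag: int) -> float:
    return float(np.mean(np.abs(x[lag:] - x[:-lag])))


def channel_features(signal: Biosignal, allow_constant: bool = False) -> ChannelFeatures:
    """Compute the six statistics for one channel.

    With allow_constant=True a zero-variance signal yields 0.0 for the
    normalized statistics instead of raising (its raw difference statistics
    are already 0, so the limit is well defined).
    """
    x = signal.samples
    n = x.size
    if n < 3:
        raise InvalidParameterError("channel features need at least 3 samples")
    mean = float(np.mean(x))
    std = _sample_std(x)
    afd = _mean_abs_diff(x, 1)
    asd = _mean_abs_diff(x, 2)
    if std == 0.0:
        if not allow_constant:
            raise DegenerateSignalError(
                "normalized statistics are undefined for a constant signal"
            )
        afdn = asdn = 0.0
    else:
        z = (x - mean) / std
        afdn = _mean_abs_diff(z, 1)
        asdn = _mean_abs_diff(z, 2)
    return ChannelFeatures(mean=mean, std=std, afd=afd, afdn=afdn, asd=asd, asdn=asdn)


def assemble_vector(
    ecg: ChannelFeatures | None = None,
    ppg: ChannelFeatures | None = None,
    eda: ChannelFeatures | None = None,
    label: str | None = None,
) -> FeatureVector:
    """Concatenate the three channel blocks in the fixed ECG, PPG, EDA order.

    Assembly is by declared channel keyword, not argument position.
    """
    blocks = {"ECG": ecg, "PPG": ppg, "EDA": eda}
    missing = [ch for ch, blk in blocks.items() if blk is None]
    if missing:
        raise InvalidParameterError(f"missing channel features: {', '.join(missing)}")
    values = np.concatenate([blocks[ch].as_array() for ch in CHANNELS])
    return FeatureVector(values, label=label)


def extract_vector(
    recording: Sequence[Biosignal],
    filter_spec=None,
) -> FeatureVector:
    """Features for one (ECG, PPG, EDA) recording, optionally pre-filtered.

    When filter_spec is given each channel is band-stop filtered before the
    statistics are computed (the pipeline default: features are taken from
    the cleaned signal). Channels are routed by their declared kind.
    """
    from .preprocess import apply_filter  # local import avoids a cycle

    by_kind: dict[str, Biosignal] = {}
    for sig in recording:
        by_kind[sig.channel] = sig
    if set(by_kind) != set(CHANNELS):
        raise InvalidParameterError(
            f"a recording needs exactly the channels {CHANNELS}, got {sorted(by_kind)}"
        )
    labels = {sig.label for sig in recording if sig.label is not None}
    label = labels.pop() if len(labels) == 1 else None
    feats = {}
    for ch in CHANNELS:
        sig = by_kind[ch]
        if filter_spec is not None:
            sig = apply_filter(filter_spec, sig)
        feats[ch] = channel_features(sig, allow_constant=True)
    return assemble_vector(ecg=feats["ECG"], ppg=feats["PPG"], eda=feats["EDA"], label=label)


def write_feature_table(vectors: Iterable[FeatureVector], path: str | Path) -> Path:
    """Write feature vectors as CSV with 18 named columns plus a label column."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(VECTOR_COLUMNS) + ["label"])
        for vec in vectors:
            writer.writerow([f"{v:.12g}" for v in vec.values] + [vec.label or ""])
    return path


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            values = np.asarray([float(row[c]) for c in VECTOR_COLUMNS])
            out.append(FeatureVector(values, label=row.get("label") or None))
    return out
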