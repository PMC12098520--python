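"""Raw multichannel recordings -> (S, S, 10) time-frequency input tensors.

The pipeline per 30-s epoch and channel:

1. resample the whole recording to 128 Hz (polyphase, anti-aliased);
2. cut contiguous non-overlapping 30-s epochs (3840 samples at 128 Hz);
3. STFT with a Hamming window, 128-sample window, 50 % overlap and no
   boundary padding -> a 65 × 59 one-sided magnitude spectrogram;
4. bilinear-resize to the model's square input (128 × 128 by default);
5. log(1 + x) compression;
6. z-score per channel with statistics computed on training tensors only.

Tensors are stacked channel-last: (height=frequency, width=time, 10).
Stage labels are encoded W=0, N1=1, N2=2, N3=3, REM=4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as _sk_resize

from .network import ConfigurationError, STAGE_NAMES
from .synthetic import EPOCH_SECONDS, RawRecording

TARGET_FS = 128.0
STFT_WINDOW = 128
STFT_HOP = 64
N_FREQ_BINS = STFT_WINDOW // 2 + 1          # 65
EPOCH_SAMPLES = int(TARGET_FS * EPOCH_SECONDS)  # 3840
N_FRAMES = 1 + (EPOCH_SAMPLES - STFT_WINDOW) // STFT_HOP  # 59

STAGE_TO_INT = {s: i for i, s in enumerate(STAGE_NAMES)}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class SpectrogramEpoch:
    """One model input: a (S, S, 10) tensor with its labels."""

    tensor: np.ndarray
    stage_label: int
    subject_id: int
    domain_label: int | None = None


def resample_signal(signal: np.ndarray, fs_in: float,
                    fs_out: float = TARGET_FS) -> np.ndarray:
    """Anti-aliased polyphase downsampling of a (channels, n) array."""
    if fs_in < fs_out:
        raise ConfigurationError(
            f"refusing to upsample: fs_in={fs_in} < fs_out={fs_out}")
    if not np.all(np.isfinite(signal)):
        raise DataError("non-finite samples in input signal")
    if fs_in == fs_out:
        return np.asarray(signal, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(np.asarray(signal, dtype=float),
                             frac.numerator, frac.denominator, axis=-1)


def segment_epochs(recording: RawRecording
                   ) -> list[tuple[np.ndarray, str]]:
    """Contiguous non-overlapping 30-s epochs; trailing remainder dropped."""
    if recording.fs != TARGET_FS:
        raise ConfigurationError(
            f"recording must be at {TARGET_FS} Hz (got {recording.fs}); "
            "run resample_signal first")
    n = recording.signal.shape[1]
    n_epochs = n // EPOCH_SAMPLES
    if len(recording.hypnogram) != n_epochs:
        raise DataError(
            f"hypnogram length {len(recording.hypnogram)} != "
            f"epoch count {n_epochs}")
    return [(recording.signal[:, k * EPOCH_SAMPLES:(k + 1) * EPOCH_SAMPLES],
             recording.hypnogram[k]) for k in range(n_epochs)]


def stft_magnitude(channel: np.ndarray) -> np.ndarray:
    """One-sided STFT magnitude of a 3840-sample channel -> (65, 59).

    Hamming window, 128-sample window, hop 64, no boundary padding, so
    the frame count is exactly 1 + (3840 − 128)/64 = 59.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != (EPOCH_SAMPLES,):
        raise DataError(
            f"expected {EPOCH_SAMPLES} samples, got {channel.shape}")
    _, _, z = sps.stft(channel, fs=TARGET_FS, window="hamming",
                       nperseg=STFT_WINDOW, noverlap=STFT_WINDOW - STFT_HOP,
                       boundary=None, padded=False)
    mag = np.abs(z)
    assert mag.shape == (N_FREQ_BINS, N_FRAMES)
    return mag


def resize_spectrogram(mag: np.ndarray, size: int = 128) -> np.ndarray:
    """Bilinear interpolation of the (65, 59) magnitude to (size, size)."""
    if mag.shape != (N_FREQ_BINS, N_FRAMES):
        raise DataError(f"expected ({N_FREQ_BINS}, {N_FRAMES}), got {mag.shape}")
    return _sk_resize(mag, (size, size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def build_epoch_tensor(epoch: np.ndarray, size: int = 128) -> np.ndarray:
    """(10, 3840) raw epoch -> (size, size, 10) log-magnitude tensor."""
    n_ch = epoch.shape[0]
    planes = []
    for ch in range(n_ch):
        if not np.all(np.isfinite(epoch[ch])):
            raise DataError(f"non-finite samples in channel {ch}")
        planes.append(resize_spectrogram(stft_magnitude(epoch[ch]), size))
    return np.log1p(np.stack(planes, axis=-1))


def recording_to_epochs(recording: RawRecording, size: int = 128,
                        domain_label: int | None = None
                        ) -> list[SpectrogramEpoch]:
    """Full per-subject pipeline (assumes the recording is at 128 Hz)."""
    return [SpectrogramEpoch(build_epoch_tensor(epoch, size),
                             STAGE_TO_INT[label], recording.subject_id,
                             domain_label)
            for epoch, label in segment_epochs(recording)]


def normalize_dataset(train: np.ndarray, other: np.ndarray | None = None,
                      std_floor: float = 1e-8
                      ) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Per-channel z-scoring with training statistics only.

    ``train``/``other`` are (N, S, S, C) stacks.  The mean and std are
    computed on ``train`` alone and applied to both, so no test-set
    information leaks into the transform.  Channels with std below the
    floor come out as zeros.
    """
    train = np.asarray(train, dtype=np.float32)
    if train.ndim != 4 or train.shape[0] < 1:
        raise ConfigurationError("need at least one training tensor (N,S,S,C)")
    mean = train.mean(axis=(0, 1, 2))
    std = np.maximum(train.std(axis=(0, 1, 2)), std_floor)
    stats = {"mean": mean, "std": std}
    train_n = (train - mean) / std
    other_n = None
    if other is not None:
        other_n = (np.asarray(other, dtype=np.float32) - mean) / std
    return train_n, other_n, stats


def apply_normalization(tensors: np.ndarray, stats: dict) -> np.ndarray:
    return (np.asarray(tensors, dtype=np.float32) - stats["mean"]) / stats["std"]


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------

class SpectrogramPreprocessor:
    """Transformer from raw 128-Hz epochs to normalized input tensors.

    ``fit`` learns per-channel normalization statistics on training
    tensors; ``transform`` applies the full STFT → resize → log1p →
    z-score chain with those statistics.  Compatible with sklearn's
    get_params/set_params protocol via plain attributes.
    """

    def __init__(self, size: int = 128):
        self.size = size

    def get_params(self, deep: bool = True) -> dict:
        return {"size": self.size}

    def set_params(self, **params) -> "SpectrogramPreprocessor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _raw_tensors(self, epochs: list[np.ndarray]) -> np.ndarray:
        return np.stack([build_epoch_tensor(e, self.size) for e in epochs])

    def fit(self, epochs: list[np.ndarray], y=None) -> "SpectrogramPreprocessor":
        tensors = self._raw_tensors(epochs)
        _, _, stats = normalize_dataset(tensors)
        self.mean_ = stats["mean"]
        self.std_ = stats["std"]
        return self

    def transform(self, epochs: list[np.ndarray]) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise RuntimeError("SpectrogramPreprocessor is not fitted")
        tensors = self._raw_tensors(epochs)
        return apply_normalization(tensors, {"mean": self.mean_, "std": self.std_})

    def fit_transform(self, epochs: list[np.ndarray], y=None) -> np.ndarray:
        return self.fit(epochs).transform(epochs)


# ---------------------------------------------------------------------------
# optional EDF input + tensor cache
# ---------------------------------------------------------------------------

def read_edf_recording(edf_path, hypnogram_csv, subject_id: int = 0,
                       channels: list[str] | None = None) -> RawRecording:
    """Read a European-Data-Format recording plus a stage-per-row CSV.

    Requires :mod:`mne` (optional dependency); the CSV must have one stage
    label per 30-s epoch in its last column (header optional).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("EDF reading requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    data = raw.get_data()
    fs = float(raw.info["sfreq"])
    lines = Path(hypnogram_csv).read_text().strip().splitlines()
    labels = []
    for line in lines:
        token = line.split(",")[-1].strip()
        if token in STAGE_TO_INT:
            labels.append(token)
    sig = resample_signal(data, fs, TARGET_FS)
    n_epochs = sig.shape[1] // EPOCH_SAMPLES
    sig = sig[:, : n_epochs * EPOCH_SAMPLES]
    return RawRecording(subject_id, TARGET_FS, sig,
                        tuple(raw.ch_names), labels[:n_epochs])


def save_tensors(path, tensors: np.ndarray, labels: np.ndarray,
                 subject_id: int, size: int, channel_names=None) -> None:
    """Cache tensors as .npz beside a JSON manifest of their provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, tensors=tensors.astype(np.float32),
             labels=np.asarray(labels, dtype=np.int64))
    manifest = {"subject_id": subject_id, "size": size,
                "channel_names": list(channel_names or []),
                "stft": {"window": "hamming", "nperseg": STFT_WINDOW,
                         "hop": STFT_HOP, "fs": TARGET_FS}}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_tensors(path) -> tuple[np.ndarray, np.ndarray, dict]:
    path = Path(path)
    with np.load(path) as data:
        tensors, labels = data["tensors"], data["labels"]
    manifest = json.loads(path.with_suffix(".json").read_text())
    return tensors, labels, manifest
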