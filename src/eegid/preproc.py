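"""Recording I/O, clip segmentation and frequency-band decomposition.

A recording is one continuous multi-channel EEG trial. Identification works on
fixed-length *clips* (default 1000 samples, i.e. 5 s at 200 Hz); each clip is
later divided into five 1-s sub-windows and every sub-window is decomposed
into rhythm bands (theta/alpha/beta/gamma by default) with a zero-phase
Butterworth band-pass.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import signal

__all__ = [
    "RawRecording",
    "Clip",
    "ClipSet",
    "Band",
    "BandSet",
    "BAND_PRESETS",
    "CLIP_LEN",
    "design_bandpass",
    "bandpass_filter",
    "band_decompose",
    "segment_trial",
    "subwindow",
    "banded_clip",
    "save_recording",
    "read_recording",
]

#: samples per identification clip: 5 s at 200 Hz
CLIP_LEN = 1000

#: sub-windows per clip (1 s each at the default rate)
N_SUBWINDOWS = 5

#: default Butterworth order (applied forward-backward, so effective order 8)
FILTER_ORDER = 4


class FormatError(ValueError):
    """A file or array did not match the documented container layout."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawRecording:
    """One continuous EEG trial: ``data`` is channels x samples (microvolt-ish
    arbitrary scale), plus the metadata the downstream protocols key on."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: int
    session_id: int
    trial_id: int
    emotion: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise FormatError("recording data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise FormatError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Clip:
    """A fixed-length identification segment carrying its trial's labels."""

    data: np.ndarray  # channels x clip_len
    fs: float
    subject_id: int
    session_id: int
    trial_id: int
    emotion: str
    clip_index: int = 0

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


ClipSet = list  # a ClipSet is simply an ordered list of Clip


# ---------------------------------------------------------------------------
# band definitions


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float


@dataclass(frozen=True)
class BandSet:
    """Ordered band-pass intervals; all edges must sit inside (0, fs/2)."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        for b in self.bands:
            if not (0 < b.low < b.high):
                raise ValueError(f"bad band edges {b}")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def validate_against_fs(self, fs: float) -> None:
        for b in self.bands:
            if b.high >= fs / 2:
                raise ValueError(
                    f"band {b.name} ({b.low}-{b.high} Hz) exceeds Nyquist "
                    f"({fs / 2} Hz)"
                )

    def single(self, name: str) -> "BandSet":
        """Restrict to one named band (single-band experiments)."""
        for b in self.bands:
            if b.name == name:
                return BandSet((b,))
        raise KeyError(f"no band named {name!r}")

    @staticmethod
    def from_preset(name: str) -> "BandSet":
        try:
            return BAND_PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown band preset {name!r}; choose from "
                f"{sorted(BAND_PRESETS)}"
            ) from None


def _bs(*triples) -> BandSet:
    return BandSet(tuple(Band(n, lo, hi) for n, lo, hi in triples))


#: The three grids in circulation for this pipeline.  "default" is the
#: canonical rhythm table (theta/alpha/beta/gamma); "narrow" is the variant
#: used for the single-band comparisons; "lowfreq" trades gamma for delta.
BAND_PRESETS: dict[str, BandSet] = {
    "default": _bs(("theta", 4, 8), ("alpha", 8, 15), ("beta", 15, 32), ("gamma", 32, 40)),
    "narrow": _bs(("theta", 4, 7), ("alpha", 8, 14), ("beta", 14, 31), ("gamma", 32, 40)),
    "lowfreq": _bs(("delta", 1, 4), ("theta", 5, 8), ("alpha", 9, 15), ("beta", 15, 32)),
}


# ---------------------------------------------------------------------------
# filtering

_SOS_CACHE: dict[tuple, np.ndarray] = {}


def design_bandpass(low: float, high: float, fs: float, order: int = FILTER_ORDER) -> np.ndarray:
    """Butterworth band-pass in second-order sections.

    Cached by (low, high, fs, order); raises if the edges are not strictly
    inside (0, Nyquist).
    """
    key = (float(low), float(high), float(fs), int(order))
    if key not in _SOS_CACHE:
        nyq = fs / 2
        if not (0 < low < high < nyq):
            raise ValueError(
                f"band ({low}, {high}) Hz must satisfy 0 < low < high < {nyq}"
            )
        sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
        if not np.all(np.isfinite(sos)):
            raise ValueError(f"unstable filter design for band ({low}, {high}) at fs={fs}")
        _SOS_CACHE[key] = sos
    return _SOS_CACHE[key]


def bandpass_filter(x: np.ndarray, low: float, high: float, fs: float,
                    order: int = FILTER_ORDER, axis: int = -1) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along ``axis``."""
    sos = design_bandpass(low, high, fs, order)
    return signal.sosfiltfilt(sos, x, axis=axis)


def band_decompose(window: np.ndarray, bands: BandSet, fs: float,
                   order: int = FILTER_ORDER) -> np.ndarray:
    """Filter ``window`` (..., samples) into each band of ``bands``.

    Returns an array of shape (n_bands, ...) + window.shape[-1:], one
    zero-phase filtered copy per band.  Linear and channel-permutation
    equivariant by construction.
    """
    window = np.asarray(window)
    bands.validate_against_fs(fs)
    out = np.empty((len(bands),) + window.shape, dtype=np.float64)
    for i, b in enumerate(bands):
        out[i] = bandpass_filter(window, b.low, b.high, fs, order=order)
    return out


# ---------------------------------------------------------------------------
# segmentation


def segment_trial(recording: RawRecording, clip_len: int = CLIP_LEN) -> ClipSet:
    """Cut a trial into floor(n_samples/clip_len) non-overlapping clips.

    Remainder samples at the trial end are dropped.  Every clip inherits the
    trial's labels and records its temporal index.
    """
    if clip_len < 1:
        raise ValueError("clip_len must be >= 1")
    n = recording.n_samples // clip_len
    if n == 0:
        warnings.warn(
            f"trial of {recording.n_samples} samples shorter than one clip "
            f"({clip_len}); returning empty clip set",
            stacklevel=2,
        )
        return []
    clips = []
    for i in range(n):
        clips.append(
            Clip(
                data=recording.data[:, i * clip_len:(i + 1) * clip_len],
                fs=recording.fs,
                subject_id=recording.subject_id,
                session_id=recording.session_id,
                trial_id=recording.trial_id,
                emotion=recording.emotion,
                clip_index=i,
            )
        )
    return clips


def subwindow(clip_data: np.ndarray, n_sub: int = N_SUBWINDOWS) -> np.ndarray:
    """Split (channels, clip_len) into n_sub contiguous equal windows.

    Returns (n_sub, channels, clip_len // n_sub); concatenating along time
    reproduces the clip exactly.
    """
    data = clip_data.data if isinstance(clip_data, Clip) else np.asarray(clip_data)
    n_ch, n_samp = data.shape
    if n_samp % n_sub != 0:
        raise ValueError(f"clip length {n_samp} not divisible by n_sub={n_sub}")
    w = n_samp // n_sub
    return data.reshape(n_ch, n_sub, w).transpose(1, 0, 2)


def banded_clip(clip: Clip, bands: BandSet, n_sub: int = N_SUBWINDOWS,
                order: int = FILTER_ORDER) -> np.ndarray:
    """Sub-window then band-decompose one clip.

    Returns (n_sub, n_bands, channels, window_len): with the defaults a
    (5, 4, 62, 200) tensor.  The clip is divided first and each 1-s window is
    filtered on its own, matching the staged preprocessing flow.
    """
    windows = subwindow(clip, n_sub)  # (n_sub, ch, w)
    out = band_decompose(windows, bands, clip.fs, order=order)  # (bands, n_sub, ch, w)
    return out.transpose(1, 0, 2, 3)


# ---------------------------------------------------------------------------
# persistence: .npz array container with a JSON metadata sidecar


def save_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write ``<path>.npz`` (data, fs) and ``<path>.json`` (metadata)."""
    path = Path(path)
    stem = path.with_suffix("")
    np.savez(stem.with_suffix(".npz"), data=rec.data, fs=np.asarray(rec.fs))
    meta = {
        "channel_names": rec.channel_names,
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "trial_id": rec.trial_id,
        "emotion": rec.emotion,
        "fs": rec.fs,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".npz")


def _read_npz(path: Path) -> RawRecording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar {sidecar} missing")
    meta = json.loads(sidecar.read_text())
    with np.load(path) as z:
        data = z["data"]
        fs = float(z["fs"])
    for key in ("channel_names", "subject_id", "session_id", "trial_id", "emotion"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    return RawRecording(
        data=data,
        fs=fs,
        channel_names=list(meta["channel_names"]),
        subject_id=int(meta["subject_id"]),
        session_id=int(meta["session_id"]),
        trial_id=int(meta["trial_id"]),
        emotion=str(meta["emotion"]),
    )


def _read_edf(path: Path) -> RawRecording:
    try:
        import mne
    except ImportError as e:  # pragma: no cover - depends on install extras
        raise FormatError("EDF input requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    missing = [k for k in ("subject_id", "session_id", "trial_id", "emotion")
               if k not in meta]
    if missing:
        raise FormatError(
            f"EDF metadata sidecar {sidecar} missing fields {missing}; "
            "identification protocols need full labels"
        )
    return RawRecording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),  # propagated as-is; resampling is the caller's concern
        channel_names=list(raw.ch_names),
        subject_id=int(meta["subject_id"]),
        session_id=int(meta["session_id"]),
        trial_id=int(meta["trial_id"]),
        emotion=str(meta["emotion"]),
    )


def read_recording(path: str | Path, format: str | None = None) -> RawRecording:
    """Read a recording from the .npz container or an EDF file.

    ``format`` is inferred from the suffix when not given.  Metadata must be
    fully populated (sidecar JSON for both containers) or a FormatError is
    raised — there is no silent defaulting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "npz")
    if fmt == "npz":
        return _read_npz(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {fmt!r} (choose 'npz' or 'edf')")
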