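"""Synthetic multi-subject, multi-session, multi-emotion EEG.

The generator embodies the premise behind EEG biometrics — each person has a
stable, individual distribution of band power over the scalp — without
attempting physiological realism.  Every subject gets a fixed per-channel,
per-band amplitude signature; an emotion condition scales the beta/gamma
bands up or down; each (subject, session) pair carries a scalar gain drift.
A recording is then

    x[ch, t] = sum_b  gain[ch, b] * emotion_gain[b] * drift * n_b[ch, t]
               + sensor_noise_sd * w[ch, t]

with ``n_b`` unit-variance band-limited noise (white noise through the same
zero-phase Butterworth band-pass the preprocessing uses) and ``w`` white
sensor noise.  Everything is reproducible from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import BAND_PRESETS, BandSet, RawRecording, bandpass_filter

__all__ = [
    "CohortSpec",
    "SubjectSignature",
    "ConditionModifiers",
    "make_cohort",
    "bandlimited_noise",
    "simulate_recording",
    "simulate_session",
    "simulate_dataset",
]

EMOTIONS = ("positive", "neutral", "negative")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    The defaults mirror a 15-subject, 62-channel, 200 Hz emotional-video
    protocol: 15 four-minute trials per session, five trials per emotion,
    three sessions recorded weeks apart.
    """

    n_subjects: int = 15
    n_channels: int = 62
    fs: float = 200.0
    trial_seconds: float = 240.0
    n_trials: int = 15
    n_sessions: int = 3
    emotions: tuple[str, ...] = EMOTIONS
    seed: int = 0
    #: log-normal spread (sigma of log amplitude) of subject band gains;
    #: 0 collapses every subject onto the same signature
    signature_spread: float = 0.4
    #: white sensor-noise amplitude relative to unit band-noise amplitude
    sensor_noise_sd: float = 0.3
    band_preset: str = "default"
    #: overrides the preset when given (e.g. a single-band study)
    custom_bands: BandSet | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1 or self.n_trials < 1:
            raise ValueError("counts must be positive")
        if self.n_trials % len(self.emotions) != 0:
            raise ValueError(
                f"n_trials={self.n_trials} not divisible by "
                f"{len(self.emotions)} emotions"
            )
        if self.signature_spread < 0 or self.sensor_noise_sd < 0:
            raise ValueError("spread and noise amplitudes must be >= 0")
        top = max(b.high for b in self.bands)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge ({top} Hz)"
            )

    @property
    def bands(self) -> BandSet:
        return self.custom_bands if self.custom_bands is not None else BAND_PRESETS[self.band_preset]

    @property
    def n_samples_per_trial(self) -> int:
        return int(round(self.trial_seconds * self.fs))

    def trial_emotion(self, trial_id: int) -> str:
        """Emotion label of a trial: conditions cycle through the trial list,
        giving each emotion n_trials/len(emotions) trials per session."""
        return self.emotions[trial_id % len(self.emotions)]


@dataclass(frozen=True)
class SubjectSignature:
    """Per-subject amplitude fingerprint: channels x bands, strictly positive."""

    subject_id: int
    band_gains: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.band_gains <= 0):
            raise ValueError("band gains must be strictly positive")


@dataclass(frozen=True)
class ConditionModifiers:
    """Multiplicative condition effects.

    ``emotion_gain`` maps emotion -> per-band amplitude factors (neutral is
    identity); ``session_drift_sd`` is the log-sd of the scalar gain each
    (subject, session) pair drifts by between visits.
    """

    emotion_gain: dict[str, np.ndarray]
    session_drift_sd: float = 0.1

    def __post_init__(self) -> None:
        for emo, g in self.emotion_gain.items():
            if np.any(np.asarray(g) <= 0):
                raise ValueError(f"non-positive emotion gain for {emo!r}")
        if self.session_drift_sd < 0:
            raise ValueError("session_drift_sd must be >= 0")

    @staticmethod
    def default(bands: BandSet, high_band_factor: float = 1.2,
                session_drift_sd: float = 0.1) -> "ConditionModifiers":
        """Positive emotion boosts beta/gamma amplitude by ``high_band_factor``,
        negative attenuates by its inverse-symmetric factor, neutral is flat —
        the usual direction of valence effects on high-frequency EEG power."""
        nb = len(bands)
        high = np.array([b.name in ("beta", "gamma") for b in bands])
        up, down = np.ones(nb), np.ones(nb)
        up[high] = high_band_factor
        down[high] = 2.0 - high_band_factor  # 1.2 -> 0.8
        return ConditionModifiers(
            emotion_gain={"positive": up, "neutral": np.ones(nb), "negative": down},
            session_drift_sd=session_drift_sd,
        )

    @staticmethod
    def none(bands: BandSet) -> "ConditionModifiers":
        nb = len(bands)
        return ConditionModifiers(
            emotion_gain={e: np.ones(nb) for e in EMOTIONS},
            session_drift_sd=0.0,
        )


# ---------------------------------------------------------------------------
# RNG plumbing: independent, reproducible streams per role


def _rng(spec: CohortSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


# ---------------------------------------------------------------------------
# operations


def make_cohort(spec: CohortSpec) -> list[SubjectSignature]:
    """Draw the per-subject signatures (log-normal i.i.d. per channel x band)."""
    rng = _rng(spec, 0)
    out = []
    for s in range(spec.n_subjects):
        gains = np.exp(spec.signature_spread * rng.standard_normal((spec.n_channels, len(spec.bands))))
        out.append(SubjectSignature(subject_id=s, band_gains=gains))
    return out


def bandlimited_noise(band: tuple[float, float], n: int, fs: float,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Unit-variance zero-mean noise with power confined to ``band``.

    White Gaussian noise is passed through the same zero-phase Butterworth
    band-pass used for preprocessing (one filter code path for generation and
    analysis), then standardized.  Returns an empty array for ``n == 0``.
    """
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={fs / 2})")
    if n == 0:
        return np.empty(0)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = bandpass_filter(rng.standard_normal(n), low, high, fs)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _session_drift(spec: CohortSpec, modifiers: ConditionModifiers,
                   subject: int, session: int) -> float:
    if modifiers.session_drift_sd == 0:
        return 1.0
    rng = _rng(spec, 1, subject, session)
    return float(np.exp(modifiers.session_drift_sd * rng.standard_normal()))


def simulate_recording(signatures: list[SubjectSignature], subject: int,
                       session: int, emotion: str, spec: CohortSpec,
                       modifiers: ConditionModifiers | None = None,
                       trial_id: int = 0) -> RawRecording:
    """Simulate one trial for (subject, session, emotion).

    Each band's noise carpet is drawn independently per channel, scaled by the
    subject's signature, the emotion's band factors and the session's scalar
    drift, summed over bands, and topped with white sensor noise.
    """
    if not 0 <= subject < len(signatures):
        raise ValueError(f"unknown subject {subject}")
    if emotion not in spec.emotions:
        raise ValueError(f"unknown emotion {emotion!r}; expected one of {spec.emotions}")
    if modifiers is None:
        modifiers = ConditionModifiers.default(spec.bands)

    gains = signatures[subject].band_gains  # (ch, bands)
    if gains.shape != (spec.n_channels, len(spec.bands)):
        raise ValueError(
            f"signature shape {gains.shape} does not match spec "
            f"({spec.n_channels}, {len(spec.bands)})"
        )
    egain = modifiers.emotion_gain[emotion]
    drift = _session_drift(spec, modifiers, subject, session)
    n = spec.n_samples_per_trial
    rng = _rng(spec, 2, subject, session, trial_id)

    data = np.zeros((spec.n_channels, n))
    for b, band in enumerate(spec.bands):
        white = rng.standard_normal((spec.n_channels, n))
        carpet = bandpass_filter(white, band.low, band.high, spec.fs)
        carpet -= carpet.mean(axis=1, keepdims=True)
        carpet /= carpet.std(axis=1, keepdims=True)
        data += (gains[:, b] * egain[b] * drift)[:, None] * carpet
    if spec.sensor_noise_sd > 0:
        data += spec.sensor_noise_sd * rng.standard_normal((spec.n_channels, n))

    return RawRecording(
        data=data,
        fs=spec.fs,
        channel_names=default_channel_names(spec.n_channels),
        subject_id=subject,
        session_id=session,
        trial_id=trial_id,
        emotion=emotion,
    )


def simulate_session(signatures: list[SubjectSignature], subject: int,
                     session: int, spec: CohortSpec,
                     modifiers: ConditionModifiers | None = None) -> list[RawRecording]:
    """All trials of one subject-session visit, emotions cycling through the
    trial list (n_trials / n_emotions trials per emotion)."""
    return [
        simulate_recording(signatures, subject, session, spec.trial_emotion(t),
                           spec, modifiers, trial_id=t)
        for t in range(spec.n_trials)
    ]


def simulate_dataset(spec: CohortSpec,
                     modifiers: ConditionModifiers | None = None,
                     sessions: tuple[int, ...] | None = None,
                     signatures: list[SubjectSignature] | None = None) -> list[RawRecording]:
    """Full cohort: every subject x requested session x trial."""
    if signatures is None:
        signatures = make_cohort(spec)
    if sessions is None:
        sessions = tuple(range(spec.n_sessions))
    recs: list[RawRecording] = []
    for subject in range(spec.n_subjects):
        for session in sessions:
            recs.extend(simulate_session(signatures, subject, session, spec, modifiers))
    return recs


def default_channel_names(n_channels: int) -> list[str]:
    """Standard 62-channel montage names when they apply, CH%03d otherwise."""
    if n_channels == 62:
        from .features import ElectrodeMap

        return ElectrodeMap.default().channel_names
    return [f"CH{i:03d}" for i in range(n_channels)]
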