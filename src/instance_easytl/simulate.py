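"""Synthetic multi-subject cohorts with class structure and subject shift.

Two generator modes, sharing a :class:`CohortSpec`:

* **raw mode** — band-limited oscillatory signals: per channel, sinusoids at
  random integer frequencies inside the theta/alpha/beta bands whose
  amplitudes follow a per-class band profile (drowsy = elevated theta/alpha,
  alert = elevated beta), scaled by subject-specific log-normal channel
  gains, plus white noise.  This exercises the full feature pipeline.

* **feature mode** — two Gaussian class clusters with fixed means in
  feature space, pushed through a subject-specific random rotation and
  translation.  This isolates the learning stages from the signal pipeline
  and is the fast default for cohort-level experiments.

In both modes the subject-shift strength dials cross-subject distribution
shift: at 0 all subjects are i.i.d. draws of the same distribution; at the
default strength a classifier trained on other subjects degrades
noticeably — the regime where borrowing labeled target samples pays off.
All randomness flows from ``(spec.seed, subject_id)`` seed sequences, so
cohorts are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .domains import LabeledDomain
from .features import (
    ALPHA_BAND,
    BETA_BAND,
    THETA_BAND,
    RawRecording,
    build_feature_matrix,
    epoch_signal,
)

__all__ = ["CohortSpec", "gen_subject_raw", "gen_subject_features", "gen_cohort"]

_BANDS = (THETA_BAND, ALPHA_BAND, BETA_BAND)

#: (theta, alpha, beta) sinusoid amplitudes per class.  Alert (class 0) has
#: elevated beta; drowsy (class 1) elevated theta/alpha.
DEFAULT_PROFILES = {
    0: (0.6, 0.8, 1.6),
    1: (1.6, 1.3, 0.6),
}


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults describe a small desk-scale cohort (5 subjects, 8 channels,
    100 windows per class); the full-scale mirror of a 15-subject study with
    700 windows per class is one constructor call away.
    """

    n_subjects: int = 5
    n_channels: int = 8
    windows_per_class: int = 100
    fs: float = 200.0
    window_seconds: float = 0.5
    #: per-class (theta, alpha, beta) sinusoid amplitudes (raw mode)
    band_profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    #: sinusoids per band per channel (raw mode)
    tones_per_band: int = 2
    #: sd of per-window log-normal amplitude jitter (raw mode)
    amplitude_jitter: float = 0.3
    #: white-noise sd added to the raw signal
    noise_sd: float = 0.5
    #: feature-space dimension (feature mode)
    n_features: int = 16
    #: distance between the two class means, in units of the class sd
    separation: float = 3.0
    #: feature-mode subject shift: rotation angle in radians plus relative
    #: translation of the subject's feature cloud
    subject_shift: float = 2.0
    #: raw-mode subject shift: sd of the log-normal per-channel gains
    #: (0.5 keeps typical gains within a factor ~2-3, so band power moves
    #: across subjects without burying the oscillations under the noise)
    channel_gain_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.windows_per_class < 1:
            raise ValueError("windows_per_class must be >= 1")
        if self.subject_shift < 0:
            raise ValueError("subject_shift must be >= 0")
        for profile in self.band_profiles.values():
            if not np.all(np.isfinite(profile)):
                raise ValueError("band profiles must be finite")

    def _rng(self, *ids: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *ids]))


def gen_subject_raw(
    spec: CohortSpec, subject_id: int
) -> tuple[dict[int, RawRecording], np.ndarray]:
    """Raw-signal recordings for one subject, one per class, plus window labels.

    Each class recording is ``windows_per_class`` windows long.  Per channel,
    ``tones_per_band`` sinusoids are placed at random integer frequencies in
    each band; amplitudes follow the class band profile times a
    subject-specific log-normal channel gain, with per-window jitter and
    random phases, plus white noise.  The returned labels align with the
    rows of the feature matrix obtained by epoching class 0 then class 1.
    """
    rng = spec._rng(subject_id, 0)
    window_len = int(round(spec.window_seconds * spec.fs))
    n_win = spec.windows_per_class
    t = np.arange(window_len) / spec.fs
    # subject-specific multiplicative channel gains: the cross-subject shift
    gains = np.exp(rng.normal(0.0, spec.channel_gain_sd, size=spec.n_channels))

    recordings: dict[int, RawRecording] = {}
    for cls in (0, 1):
        profile = spec.band_profiles[cls]
        signal = rng.normal(0.0, spec.noise_sd, size=(spec.n_channels, n_win, window_len))
        for ch in range(spec.n_channels):
            for band, amp in zip(_BANDS, profile):
                freqs = rng.integers(band[0], band[1] + 1, size=spec.tones_per_band)
                for f in freqs:
                    jitter = np.exp(
                        rng.normal(0.0, spec.amplitude_jitter, size=(n_win, 1))
                    )
                    phases = rng.uniform(0, 2 * np.pi, size=(n_win, 1))
                    signal[ch] += (
                        amp
                        * gains[ch]
                        * jitter
                        * np.sin(2 * np.pi * f * t[None, :] + phases)
                    )
        recordings[cls] = RawRecording(
            signal=signal.reshape(spec.n_channels, n_win * window_len), fs=spec.fs
        )
    labels = np.repeat([0, 1], n_win)
    return recordings, labels


def _subject_rotation(rng: np.random.Generator, dim: int, angle: float) -> np.ndarray:
    """A random rotation with spectral angle ``angle`` (radians)."""
    G = rng.normal(size=(dim, dim))
    A = G - G.T
    norm = np.linalg.norm(A, 2)
    if norm == 0 or angle == 0:
        return np.eye(dim)
    return expm((angle / norm) * A)


def gen_subject_features(spec: CohortSpec, subject_id: int) -> LabeledDomain:
    """Feature-space samples for one subject: shifted Gaussian class clusters.

    The base distribution has class means ``-+ separation/2`` apart along a
    fixed direction with unit isotropic class covariance.  Each subject's
    samples are rotated by a random rotation of angle ``subject_shift`` and
    translated by a random vector of length
    ``subject_shift * separation / 2``.
    """
    rng = spec._rng(subject_id, 1)
    D = spec.n_features
    direction = np.ones(D) / np.sqrt(D)  # fixed class axis, shared by all subjects
    mu = {0: -0.5 * spec.separation * direction, 1: 0.5 * spec.separation * direction}
    n = spec.windows_per_class
    X = np.vstack(
        [mu[0] + rng.normal(size=(n, D)), mu[1] + rng.normal(size=(n, D))]
    )
    y = np.repeat([0, 1], n)
    R = _subject_rotation(rng, D, spec.subject_shift)
    shift_dir = rng.normal(size=D)
    shift_dir /= np.linalg.norm(shift_dir)
    translation = spec.subject_shift * spec.separation / 2.0 * shift_dir
    return LabeledDomain(X @ R.T + translation, y)


def subject_features_from_raw(spec: CohortSpec, subject_id: int) -> LabeledDomain:
    """Raw-mode subject pushed through the band-power feature pipeline."""
    recordings, labels = gen_subject_raw(spec, subject_id)
    feats = [
        build_feature_matrix(epoch_signal(recordings[cls], spec.window_seconds))
        for cls in (0, 1)
    ]
    return LabeledDomain(np.vstack(feats), labels)


def gen_cohort(spec: CohortSpec, mode: str = "features") -> list[LabeledDomain]:
    """Generate the full cohort, subject ids ``1 .. n_subjects``.

    ``mode="features"`` uses the Gaussian feature-space generator;
    ``mode="raw"`` synthesizes signals and runs the band-power pipeline.
    """
    if mode == "features":
        gen = gen_subject_features
    elif mode == "raw":
        gen = subject_features_from_raw
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [gen(spec, sid) for sid in range(1, spec.n_subjects + 1)]
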