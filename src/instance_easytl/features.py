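"""EEG band-power feature extraction.

Pipeline (per channel): slice the recording into non-overlapping 0.5 s
windows, estimate a one-sided log power spectral density on a 1 Hz grid
(Hamming taper, zero-padded periodogram), then keep the log-power at the
integer frequencies of the theta (4-7 Hz), alpha (8-13 Hz) and beta
(14-30 Hz) bands: 4 + 6 + 17 = 27 values per channel per window.  With 61
channels this yields the 1647-dimensional feature vector used for
drowsiness-vs-alert classification; channel count is free here.

At the default 200 Hz sampling rate a 0.5 s window holds 100 samples; the
tapered segment is zero-padded to ``fs`` points before the FFT, the only
transform length that lands the bins exactly on the integers 0..100 Hz
(101 values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "RawRecording",
    "EpochedEEG",
    "THETA_BAND",
    "ALPHA_BAND",
    "BETA_BAND",
    "N_BAND_FEATURES",
    "PSD_FLOOR",
    "bandpass_filter",
    "epoch_signal",
    "psd_onesided",
    "band_features",
    "build_feature_matrix",
    "band_feature_names",
]

#: Frequency bands in Hz (inclusive integer endpoints).
THETA_BAND = (4, 7)
ALPHA_BAND = (8, 13)
BETA_BAND = (14, 30)

#: Band features per channel: 4 theta + 6 alpha + 17 beta.
N_BAND_FEATURES = 27

#: Added to power before the log so silent bins give a finite floor.
PSD_FLOOR = 1e-12


@dataclass
class RawRecording:
    """A multichannel recording: ``signal`` is (n_channels, n_samples)."""

    signal: np.ndarray
    fs: float = 200.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.ndim != 2 or self.signal.shape[1] < 1:
            raise ValueError(f"signal must be (n_channels, n_samples), got {self.signal.shape}")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochedEEG:
    """Non-overlapping windows: ``windows`` is (n_windows, n_channels, window_len)."""

    windows: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError(f"windows must be 3-D, got shape {self.windows.shape}")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]


def bandpass_filter(
    raw: RawRecording, low_hz: float, high_hz: float, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward (``sosfiltfilt``) filtering keeps window boundaries
    aligned in time.  A 1-30 Hz band is the conventional pre-cleaning step
    before band-power extraction.
    """
    nyq = raw.fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below the Nyquist frequency {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=raw.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.signal, axis=1)
    return RawRecording(signal=filtered, fs=raw.fs)


def epoch_signal(raw: RawRecording, window_seconds: float = 0.5) -> EpochedEEG:
    """Slice into non-overlapping windows of ``round(window_seconds * fs)`` samples.

    Trailing samples that do not fill a window are discarded.  At 200 Hz and
    0.5 s each window has 100 samples, so a 700 s recording gives 1400 windows.
    """
    window_len = int(round(window_seconds * raw.fs))
    if window_len < 1:
        raise ValueError("window_seconds * fs must round to at least one sample")
    n_windows = raw.n_samples // window_len
    if n_windows < 1:
        raise ValueError(
            f"signal of {raw.n_samples} samples is shorter than one "
            f"{window_len}-sample window"
        )
    trimmed = raw.signal[:, : n_windows * window_len]
    # (channels, windows, len) -> (windows, channels, len)
    windows = trimmed.reshape(raw.n_channels, n_windows, window_len).transpose(1, 0, 2)
    return EpochedEEG(windows=windows.copy(), fs=raw.fs)


def _hamming_taper(n: int) -> np.ndarray:
    # Symmetric taper; the periodogram divides by its power (sum of squares).
    return sps.windows.hamming(n, sym=True)


def psd_onesided(window: np.ndarray, fs: float = 200.0) -> np.ndarray:
    """One-sided log10 periodogram of a single window on a 1 Hz grid.

    The window is Hamming-tapered, zero-padded to ``fs`` points and
    transformed; the one-sided density estimate (scaled by the taper power,
    off-DC/Nyquist bins doubled) is floored at :data:`PSD_FLOOR` before the
    log.  Length is ``fs/2 + 1`` (101 at 200 Hz).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1:
        raise ValueError("psd_onesided expects a single 1-D window")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    nfft = int(round(fs))
    if window.size > nfft:
        raise ValueError(
            f"window of {window.size} samples exceeds fs={fs}; 1 Hz bins need "
            "window_len <= fs"
        )
    taper = _hamming_taper(window.size)
    _, pxx = sps.periodogram(window, fs=fs, window=taper, nfft=nfft, detrend=False)
    return np.log10(pxx + PSD_FLOOR)


def band_features(psd: np.ndarray) -> np.ndarray:
    """Select theta/alpha/beta log-power values from a 1 Hz-grid PSD.

    Returns the 27 values at integer frequencies 4..7, 8..13 and 14..30 Hz,
    in ascending frequency order.
    """
    psd = np.asarray(psd, dtype=float)
    if psd.shape[-1] < BETA_BAND[1] + 1:
        raise ValueError(
            f"psd of length {psd.shape[-1]} does not cover {BETA_BAND[1]} Hz"
        )
    idx = _band_indices()
    return psd[..., idx]


def _band_indices() -> np.ndarray:
    return np.concatenate(
        [
            np.arange(THETA_BAND[0], THETA_BAND[1] + 1),
            np.arange(ALPHA_BAND[0], ALPHA_BAND[1] + 1),
            np.arange(BETA_BAND[0], BETA_BAND[1] + 1),
        ]
    )


def build_feature_matrix(epoched: EpochedEEG) -> np.ndarray:
    """Assemble the (n_windows, n_channels * 27) band-power feature matrix.

    Row ``i`` concatenates, channel by channel in recording order, the 27
    band features of window ``i``.  Deterministic; no randomness anywhere in
    the pipeline.
    """
    nfft = int(round(epoched.fs))
    if epoched.window_len > nfft:
        raise ValueError("window_len must not exceed fs for a 1 Hz PSD grid")
    taper = _hamming_taper(epoched.window_len)
    _, pxx = sps.periodogram(
        epoched.windows, fs=epoched.fs, window=taper, nfft=nfft, detrend=False, axis=-1
    )
    logpsd = np.log10(pxx + PSD_FLOOR)
    feats = band_features(logpsd)  # (n_windows, n_channels, 27)
    return feats.reshape(epoched.n_windows, epoched.n_channels * N_BAND_FEATURES)


def band_feature_names(n_channels: int) -> list[str]:
    """Column names ``ch{c}_{band}{f}Hz`` matching the feature-matrix layout."""
    names = []
    bands = (
        [("theta", f) for f in range(THETA_BAND[0], THETA_BAND[1] + 1)]
        + [("alpha", f) for f in range(ALPHA_BAND[0], ALPHA_BAND[1] + 1)]
        + [("beta", f) for f in range(BETA_BAND[0], BETA_BAND[1] + 1)]
    )
    for c in range(n_channels):
        for band, f in bands:
            names.append(f"ch{c}_{band}{f}Hz")
    return names
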