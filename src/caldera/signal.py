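"""Signal representations: magnitude series, sliding windows, spectral features.

Raw tri-axial accelerometer (and optionally gyroscope) recordings are reduced
to a univariate magnitude series — the Euclidean norm of the three axes at
each time index, gravity included.  The classifier then sees one of three
input representations:

* ``time``: overlapping 32-sample windows (0.32 s at 100 Hz), stride 1, so a
  series of length L yields L − 31 windows;
* ``spectral_long``: 32 spectral densities on equal-width frequency intervals
  tiling (0, 50] Hz, estimated over the whole series;
* ``spectral_short``: a 32-bin density vector computed per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
import scipy.signal

#: Sliding-window length in samples; 0.32 s at the 100 Hz device rate.
WINDOW_WIDTH = 32

#: Number of spectral feature bins (matches the classifier's 32 terminals).
N_SPECTRAL_BINS = 32

#: Device sample rate in Hz.
DEFAULT_SAMPLE_RATE = 100.0


class Site(str, Enum):
    """Body location of a sensor module."""

    LEFT_ARM = "left_arm"
    RIGHT_ARM = "right_arm"
    LEFT_LEG = "left_leg"
    RIGHT_LEG = "right_leg"
    TRUNK = "trunk"
    HEAD = "head"


@dataclass
class Recording:
    """A multi-channel inertial time series from one sensor module.

    Parameters
    ----------
    recording_id : str
        Unique identifier for the recording.
    accel : ndarray, shape (n, 3)
        Tri-axial accelerometer samples, raw sensor units (g).
    gyro : ndarray, shape (n, 3), optional
        Tri-axial gyroscope samples (angular rate), same length as ``accel``.
    sample_rate : float
        Samples per second; the device records at 100 Hz.
    t0 : float
        Start time in seconds (epoch offset or 0 for relative time).
    site : Site or str
        Body location the module was worn at.
    """

    recording_id: str
    accel: np.ndarray
    gyro: Optional[np.ndarray] = None
    sample_rate: float = DEFAULT_SAMPLE_RATE
    t0: float = 0.0
    site: Site = Site.LEFT_ARM

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must have shape (n, 3)")
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
            if self.gyro.shape != self.accel.shape:
                raise ValueError("gyro must match accel shape")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.site = Site(self.site)

    def __len__(self) -> int:
        return self.accel.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sample_rate


@dataclass
class MagnitudeSeries:
    """Univariate series of per-sample Euclidean norms of a channel triple."""

    values: np.ndarray
    sample_rate: float
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class WindowSet:
    """Overlapping fixed-width windows of a magnitude series.

    ``windows`` has shape (L − width + 1, width) at stride 1; consecutive
    rows overlap in width − 1 samples.
    """

    windows: np.ndarray
    width: int = WINDOW_WIDTH
    stride: int = 1

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


class SpectralMode(str, Enum):
    LONG = "long"
    SHORT = "short"


@dataclass
class SpectralFeatures:
    """32 non-negative spectral densities on equal-width frequency bins."""

    densities: np.ndarray
    band_edges: np.ndarray
    mode: SpectralMode = SpectralMode.LONG

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.band_edges = np.asarray(self.band_edges, dtype=float)


def magnitude(recording: Recording, channel_group: str = "accel") -> MagnitudeSeries:
    """Per-sample Euclidean norm of a tri-axial channel group.

    No gravity subtraction or filtering is applied: the classifier operates
    on raw acceleration magnitudes, so at rest the series sits near 1 g.

    Parameters
    ----------
    recording : Recording
    channel_group : {"accel", "gyro"}

    Raises
    ------
    ValueError
        ``"channel absent"`` if the group is not recorded;
        ``"invalid sample"`` if any sample is non-finite.
    """
    if channel_group == "accel":
        data = recording.accel
    elif channel_group == "gyro":
        data = recording.gyro
        if data is None:
            raise ValueError(f"channel absent: {channel_group}")
    else:
        raise ValueError(f"channel absent: {channel_group}")
    if not np.all(np.isfinite(data)):
        raise ValueError("invalid sample: non-finite value in channel data")
    values = np.linalg.norm(data, axis=1)
    return MagnitudeSeries(
        values=values,
        sample_rate=recording.sample_rate,
        source=f"{recording.recording_id}/{channel_group}",
    )


def _as_values(series) -> np.ndarray:
    if isinstance(series, MagnitudeSeries):
        return series.values
    return np.asarray(series, dtype=float)


def extract_windows(series, width: int = WINDOW_WIDTH, stride: int = 1) -> WindowSet:
    """Slide a window of ``width`` samples along the series at ``stride`` 1.

    A series of length L yields exactly L − width + 1 windows (L − 31 at the
    default width); row k holds samples [k, k + width).

    Raises
    ------
    ValueError
        ``"series too short"`` when L < width.
    """
    values = _as_values(series)
    if values.shape[0] < width:
        raise ValueError(
            f"series too short: length {values.shape[0]} < window width {width}"
        )
    windows = sliding_window_view(values, width)[::stride]
    return WindowSet(windows=windows, width=width, stride=stride)


def long_term_spectrum(series, sample_rate: float = DEFAULT_SAMPLE_RATE) -> SpectralFeatures:
    """Whole-series spectral densities on 32 equal bins tiling (0, 50] Hz.

    The power spectral density is estimated with Welch's averaged periodogram
    (Hann taper, segments of 256 samples — or the series length if shorter —
    with 50% overlap, mean detrend), then reduced to 32 features by averaging
    the density over each 1.5625 Hz-wide interval.  The DC term is excluded,
    so a constant series has (numerically) zero density everywhere.

    Raises
    ------
    ValueError
        ``"insufficient samples"`` for series shorter than 64 samples, or a
        sample rate other than 100 Hz (the binning assumes a 50 Hz Nyquist).
    """
    values = _as_values(series)
    if values.shape[0] < 64:
        raise ValueError(f"insufficient samples: {values.shape[0]} < 64")
    if abs(sample_rate - DEFAULT_SAMPLE_RATE) > 1e-9:
        raise ValueError(
            f"insufficient samples: sample rate {sample_rate} Hz unsupported; "
            "expected 100 Hz"
        )
    nperseg = min(256, values.shape[0])
    freqs, psd = scipy.signal.welch(
        values,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    nyquist = sample_rate / 2.0
    edges = np.linspace(0.0, nyquist, N_SPECTRAL_BINS + 1)
    densities = np.empty(N_SPECTRAL_BINS)
    for i in range(N_SPECTRAL_BINS):
        mask = (freqs > edges[i]) & (freqs <= edges[i + 1])
        densities[i] = psd[mask].mean() if mask.any() else 0.0
    return SpectralFeatures(densities=densities, band_edges=edges, mode=SpectralMode.LONG)


def short_term_spectra(windows: np.ndarray, sample_rate: float = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Vectorised per-window periodogram densities; returns shape (n, 32).

    Each 32-sample window is zero-padded to 64 samples and a single boxcar
    periodogram is taken; one-sided bins 1..32 (DC dropped) give exactly 32
    features per window.  A 32-sample window natively yields only 17
    one-sided bins, hence the padding.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.shape[1] != WINDOW_WIDTH:
        raise ValueError(f"bad window: width {windows.shape[1]} != {WINDOW_WIDTH}")
    nfft = 2 * WINDOW_WIDTH
    spec = np.fft.rfft(windows, n=nfft, axis=1)
    # one-sided PSD scaling over the unpadded sample count
    psd = (np.abs(spec) ** 2) / (sample_rate * WINDOW_WIDTH)
    psd[:, 1:-1] *= 2.0
    return psd[:, 1 : N_SPECTRAL_BINS + 1]


def short_term_spectrum(window, sample_rate: float = DEFAULT_SAMPLE_RATE) -> SpectralFeatures:
    """Spectral densities of a single 32-sample window (see `short_term_spectra`)."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.shape[0] != WINDOW_WIDTH:
        raise ValueError(f"bad window: expected {WINDOW_WIDTH} samples")
    densities = short_term_spectra(window[None, :], sample_rate)[0]
    nyquist = sample_rate / 2.0
    edges = np.linspace(0.0, nyquist, N_SPECTRAL_BINS + 1)
    return SpectralFeatures(densities=densities, band_edges=edges, mode=SpectralMode.SHORT)
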