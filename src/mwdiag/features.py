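"""The 30-descriptor feature bank computed per backscattered signal.

Four sub-groups, all computed independently per signal (no statistic is ever
pooled across observations, so feature extraction cannot leak information
between training and test sets):

* #1–#19  time-domain peak/area statistics of the (windowed) signal;
* #20–#24 peak statistics of the normalised autocorrelation sequence;
* #25     mean of the Welch power-spectral-density estimate;
* #26–#30 peak statistics of the periodogram.

Peaks are local extrema with prominence at least 5% of the maximum absolute
amplitude; FWHM is measured by linear interpolation at half the
prominence-referenced height.  Feature definitions are length-agnostic: they
apply to 60-sample tumour signatures (30 GHz) and to raw full-length records
(600 GHz) alike — pass the matching ``fs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError

__all__ = [
    "PeakSet",
    "FeatureVector",
    "FEATURE_NAMES",
    "detect_peaks",
    "time_features",
    "autocorr_features",
    "psd_features",
    "extract_features",
    "feature_matrix",
]

FEATURE_NAMES: tuple[str, ...] = (
    "max_pos_peak_amp",        # 1
    "max_pos_peak_loc",        # 2
    "max_neg_peak_amp",        # 3
    "max_neg_peak_loc",        # 4
    "variance",                # 5
    "rms",                     # 6
    "n_pos_peaks",             # 7
    "n_neg_peaks",             # 8
    "mean_pos_peak_amp",       # 9
    "mean_neg_peak_amp",       # 10
    "mean_pos_peak_fwhm",      # 11
    "mean_neg_peak_fwhm",      # 12
    "mean_pos_peak_sep",       # 13
    "mean_neg_peak_sep",       # 14
    "n_zero_crossings",        # 15
    "integral",                # 16
    "integral_abs",            # 17
    "pos_area_pct",            # 18
    "neg_area_pct",            # 19
    "acf_mean",                # 20
    "acf_n_peaks",             # 21
    "acf_mean_peak_amp",       # 22
    "acf_mean_peak_fwhm",      # 23
    "acf_mean_peak_sep",       # 24
    "welch_mean",              # 25
    "pgram_mean",              # 26
    "pgram_n_peaks",           # 27
    "pgram_mean_peak_amp",     # 28
    "pgram_mean_peak_fwhm",    # 29
    "pgram_mean_peak_sep",     # 30
)

#: default peak prominence threshold, as a fraction of max |amplitude|
MIN_PROMINENCE_FRAC = 0.05


@dataclass
class PeakSet:
    """Detected peaks of one polarity: locations, signed amplitudes, FWHMs."""

    locations: np.ndarray
    amplitudes: np.ndarray
    fwhms: np.ndarray
    polarity: str

    def __len__(self) -> int:
        return len(self.locations)


@dataclass
class FeatureVector:
    """The 30 descriptors in fixed order #1..#30."""

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (30,):
            raise DataError(f"feature vector must have 30 entries, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature vector contains non-finite values")


def detect_peaks(signal, polarity: str = "positive", min_prominence: float | None = None) -> PeakSet:
    """Local maxima of the signal (positive) or of its negation (negative).

    Only peaks whose signed amplitude has the requested polarity are kept, so
    a PeakSet's amplitudes are all > 0 (positive) or all < 0 (negative).
    FWHM per peak comes from linear interpolation at half the
    prominence-referenced peak height, clipped at the window edges.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise DataError("peak detection needs at least 3 samples")
    if polarity not in ("positive", "negative"):
        raise DataError(f"polarity must be positive/negative, got {polarity!r}")
    amax = float(np.max(np.abs(x))) if x.size else 0.0
    if amax == 0.0:
        return PeakSet(np.array([], int), np.array([]), np.array([]), polarity)
    if min_prominence is None:
        min_prominence = MIN_PROMINENCE_FRAC * amax
    y = x if polarity == "positive" else -x
    locs, props = sps.find_peaks(y, prominence=min_prominence)
    if len(locs):
        widths = sps.peak_widths(y, locs, rel_height=0.5)[0]
    else:
        widths = np.array([])
    keep = y[locs] > 0  # enforce signed-amplitude polarity
    locs, widths = locs[keep], widths[keep]
    amps = x[locs]
    return PeakSet(locations=locs, amplitudes=amps, fwhms=widths, polarity=polarity)


def _mean_or_zero(v) -> float:
    v = np.asarray(v, dtype=float)
    return float(v.mean()) if v.size else 0.0


def _mean_sep(locations) -> float:
    locations = np.asarray(locations, dtype=float)
    return float(np.diff(locations).mean()) if locations.size >= 2 else 0.0


def time_features(signature, fs: float = 30.0, min_prominence: float | None = None) -> np.ndarray:
    """Features #1..#19 from the time-domain waveform (sample period 1/fs ns)."""
    x = np.asarray(signature, dtype=float)
    dt = 1.0 / fs
    pos = detect_peaks(x, "positive", min_prominence)
    neg = detect_peaks(x, "negative", min_prominence)

    if len(pos):
        i = int(np.argmax(pos.amplitudes))
        f1, f2 = float(pos.amplitudes[i]), float(pos.locations[i])
    else:
        f1 = f2 = 0.0
    if len(neg):
        i = int(np.argmin(neg.amplitudes))  # most negative
        f3, f4 = float(neg.amplitudes[i]), float(neg.locations[i])
    else:
        f3 = f4 = 0.0

    pos_area = float(np.sum(x[x > 0])) * dt
    neg_area = float(-np.sum(x[x < 0])) * dt
    total_abs = float(np.sum(np.abs(x))) * dt

    return np.array([
        f1, f2, f3, f4,
        float(np.var(x)),                       # 5 variance
        float(np.sqrt(np.mean(x * x))),         # 6 RMS value
        float(len(pos)), float(len(neg)),       # 7, 8
        _mean_or_zero(pos.amplitudes), _mean_or_zero(neg.amplitudes),   # 9, 10
        _mean_or_zero(pos.fwhms), _mean_or_zero(neg.fwhms),             # 11, 12
        _mean_sep(pos.locations), _mean_sep(neg.locations),             # 13, 14
        float(np.sum(x[:-1] * x[1:] < 0)),      # 15 zero crossings
        float(np.sum(x)) * dt,                  # 16 integral
        total_abs,                              # 17 integral of |x|
        100.0 * pos_area / total_abs if total_abs > 0 else 0.0,         # 18
        100.0 * neg_area / total_abs if total_abs > 0 else 0.0,         # 19
    ])


def autocorrelation(signature) -> np.ndarray:
    """Autocorrelation over non-negative lags, normalised so lag 0 equals 1."""
    x = np.asarray(signature, dtype=float)
    r = sps.correlate(x, x, mode="full", method="auto")[x.size - 1:]
    return r / r[0]


def autocorr_features(signature) -> np.ndarray:
    """Features #20..#24 from the normalised autocorrelation sequence."""
    x = np.asarray(signature, dtype=float)
    if not np.any(x):
        return np.zeros(5)
    r = autocorrelation(x)
    peaks = detect_peaks(r, "positive")  # lag-0 endpoint is never a local max
    return np.array([
        float(r.mean()),                 # 20
        float(len(peaks)),               # 21
        _mean_or_zero(peaks.amplitudes), # 22
        _mean_or_zero(peaks.fwhms),      # 23
        _mean_sep(peaks.locations),      # 24
    ])


def psd_features(signature, fs: float = 30.0) -> np.ndarray:
    """Features #25..#30 from Welch and periodogram PSD estimates.

    Welch: Hann window, segment length 30 (or the signal length if shorter),
    50% overlap.  Periodogram: rectangular window over the full record.  Peak
    widths/separations are measured in frequency bins.
    """
    x = np.asarray(signature, dtype=float)
    if not np.any(x):
        return np.zeros(6)
    nperseg = min(30, x.size)
    _, welch_psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, detrend=False
    )
    _, pgram = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    peaks = detect_peaks(pgram, "positive")
    return np.array([
        float(welch_psd.mean()),         # 25
        float(pgram.mean()),             # 26
        float(len(peaks)),               # 27
        _mean_or_zero(peaks.amplitudes), # 28
        _mean_or_zero(peaks.fwhms),      # 29
        _mean_sep(peaks.locations),      # 30
    ])


def extract_features(signature, fs: float = 30.0) -> FeatureVector:
    """Concatenate #1..#30 for one signal; depends only on that signal."""
    x = np.asarray(signature, dtype=float)
    values = np.concatenate([time_features(x, fs=fs), autocorr_features(x), psd_features(x, fs=fs)])
    return FeatureVector(values=values)


def feature_matrix(signals: np.ndarray, fs: float = 30.0) -> np.ndarray:
    """Stack extract_features over the rows of a (n_signals, n_samples) array."""
    signals = np.asarray(signals, dtype=float)
    return np.stack([extract_features(row, fs=fs).values for row in signals])
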