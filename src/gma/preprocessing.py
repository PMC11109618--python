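"""Signal cleaning, filtering, segmentation, vital-sign extraction, and
spectral pre-analysis statistics.

The processing chain mirrors standard wearable-IMU practice: linear
interpolation over missing ("NULL") samples, zero-phase Butterworth
filtering, fixed-length overlapping sliding windows, prominence-based peak
detection for the gyroscope-derived vital signs, and one-sided periodogram
spectra compared between label groups via a mean +/- SD error band and an
interval overlap-rate statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session import Frame, FrameSet, ImuSession, PLACEMENTS

__all__ = [
    "FilterSpec",
    "PeakList",
    "Spectrum",
    "GroupBand",
    "clean_missing",
    "clean_session",
    "apply_filter",
    "filter_session",
    "segment_frames",
    "segment_cohort",
    "detect_peaks",
    "estimate_respiration_rate",
    "estimate_pulse_rate",
    "estimate_heart_rate",
    "pearson_r",
    "power_spectrum",
    "group_band",
    "overlap_rate",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter specification.

    ``kind`` is ``"lowpass"`` (uses ``f_high`` only) or ``"bandpass"``
    (``f_low`` .. ``f_high``).  ``zero_phase`` selects forward-backward
    filtering, which preserves peak timing.
    """

    kind: str
    f_high: float
    f_low: float | None = None
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if not (0.0 < self.f_high < nyq):
            raise ValueError(
                f"f_high={self.f_high} must lie in (0, Nyquist={nyq}) Hz")
        if self.kind == "bandpass":
            if self.f_low is None or not (0.0 < self.f_low < self.f_high):
                raise ValueError(
                    f"bandpass needs 0 < f_low < f_high, got "
                    f"f_low={self.f_low}, f_high={self.f_high}")


#: 14 Hz movement-retaining low-pass applied before segmentation.
MOVEMENT_LOWPASS = FilterSpec(kind="lowpass", f_high=14.0)
#: Respiration band of the abdomen gyroscope chain.
RESPIRATION_BAND = FilterSpec(kind="bandpass", f_low=0.08, f_high=0.9)
#: Pulse-wave band of the wrist gyroscope chain.
PULSE_BAND = FilterSpec(kind="bandpass", f_low=1.0, f_high=5.0)
#: Heart-waveform band (covers 42-220 bpm fundamentals at fs=30).
HEART_BAND = FilterSpec(kind="bandpass", f_low=0.7, f_high=8.0)


def clean_missing(channel: np.ndarray) -> np.ndarray:
    """Replace NaN sentinels by linear interpolation between neighbors.

    Present samples are returned unchanged.  Leading/trailing sentinels (not
    produced by the cohort generator, but possible in external data) are
    filled with the nearest present value.
    """
    x = np.asarray(channel, dtype=float)
    missing = np.isnan(x)
    if not missing.any():
        return x.copy()
    if missing.all():
        raise ValueError("channel is entirely missing; nothing to interpolate")
    idx = np.arange(x.size)
    out = x.copy()
    out[missing] = np.interp(idx[missing], idx[~missing], x[~missing])
    return out


def clean_session(session: ImuSession) -> ImuSession:
    """Interpolate missing samples on every channel of a session."""
    out = session.copy()
    for node in PLACEMENTS:
        arr = out.nodes[node]
        for ci in range(arr.shape[0]):
            arr[ci] = clean_missing(arr[ci])
    return out


def apply_filter(channel: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply a Butterworth filter; output length equals input length."""
    spec.validate(fs)
    x = np.asarray(channel, dtype=float)
    if spec.kind == "lowpass":
        sos = sps.butter(spec.order, spec.f_high, btype="low", fs=fs,
                         output="sos")
    else:
        sos = sps.butter(spec.order, [spec.f_low, spec.f_high],
                         btype="bandpass", fs=fs, output="sos")
    if spec.zero_phase:
        # pad by a few periods of the lowest corner frequency so that
        # forward-backward edge transients die out inside the padding
        f_lowest = spec.f_low if spec.kind == "bandpass" else spec.f_high
        padlen = int(min(x.size - 1, max(3 * spec.order, 10.0 * fs / f_lowest)))
        return sps.sosfiltfilt(sos, x, padlen=padlen)
    return sps.sosfilt(sos, x)


def filter_session(session: ImuSession,
                   spec: FilterSpec = MOVEMENT_LOWPASS) -> ImuSession:
    """Filter every channel of a session (default: 14 Hz low-pass)."""
    out = session.copy()
    for node in PLACEMENTS:
        arr = out.nodes[node]
        for ci in range(arr.shape[0]):
            arr[ci] = apply_filter(arr[ci], spec, session.fs)
    return out


def frame_count(n_samples: int, window: int, overlap: int) -> int:
    """Closed-form count of full overlapping windows.

    ``floor((L - W) / (W - V)) + 1`` for L >= W, else 0; partial tail
    windows are dropped.
    """
    if n_samples < window:
        return 0
    return (n_samples - window) // (window - overlap) + 1


def segment_frames(session: ImuSession, window_s: float = 120.0,
                   overlap_s: float = 10.0) -> FrameSet:
    """Cut a session into fixed-length overlapping frames.

    Consecutive frames share exactly ``overlap_s`` seconds; a session
    shorter than one window yields an empty frame set (with a warning).
    """
    if not (window_s > overlap_s >= 0):
        raise ValueError(
            f"need window_s > overlap_s >= 0, got {window_s}, {overlap_s}")
    fs = session.fs
    W = int(round(window_s * fs))
    V = int(round(overlap_s * fs))
    L = session.n_samples
    n_frames = frame_count(L, W, V)
    if n_frames == 0:
        warnings.warn(
            f"session {session.subject_id} ({session.duration_s:.0f} s) is "
            f"shorter than one {window_s:.0f} s window; no frames produced",
            stacklevel=2)
    frames = []
    step = W - V
    for k in range(n_frames):
        start = k * step
        nodes = {node: arr[:, start:start + W].copy()
                 for node, arr in session.nodes.items()}
        frames.append(Frame(subject_id=session.subject_id, label=session.label,
                            index=k, start_sample=start, fs=fs, nodes=nodes))
    return FrameSet(frames=frames, window_s=window_s, overlap_s=overlap_s, fs=fs)


def segment_cohort(sessions: list[ImuSession], window_s: float = 120.0,
                   overlap_s: float = 10.0) -> FrameSet:
    """Segment every session and pool the frames in cohort order."""
    if not sessions:
        raise ValueError("no sessions to segment")
    out: FrameSet | None = None
    for sess in sessions:
        fset = segment_frames(sess, window_s=window_s, overlap_s=overlap_s)
        if out is None:
            out = fset
        else:
            out.extend(fset)
    assert out is not None
    return out


@dataclass
class PeakList:
    """Detected peak sample indices of one trace."""

    indices: np.ndarray
    duration_s: float

    def __len__(self) -> int:
        return len(self.indices)

    def times_s(self, fs: float) -> np.ndarray:
        return self.indices / fs


def detect_peaks(channel: np.ndarray, fs: float,
                 min_prominence_sd: float = 0.5,
                 min_distance_s: float = 0.3) -> PeakList:
    """Prominence-thresholded local maxima with a minimum separation.

    The prominence threshold is ``min_prominence_sd`` times the channel SD;
    when two candidates violate the separation the larger is kept.
    A constant channel has SD 0 and yields no peaks.
    """
    if min_distance_s <= 0:
        raise ValueError("min_distance_s must be positive")
    x = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("channel contains non-finite samples")
    sd = float(np.std(x))
    duration_s = x.size / fs
    if sd == 0.0:
        return PeakList(indices=np.array([], dtype=int), duration_s=duration_s)
    distance = max(int(round(min_distance_s * fs)), 1)
    idx, _ = sps.find_peaks(x, prominence=min_prominence_sd * sd,
                            distance=distance)
    return PeakList(indices=idx, duration_s=duration_s)


def _rate_from_count(peaks: PeakList) -> float:
    if len(peaks) == 0:
        return math.nan
    return 60.0 * len(peaks) / peaks.duration_s


#: Minimum in-band power fraction for a rate to be considered defined.
_INBAND_POWER_FLOOR = 1e-4


def _band_filtered(channel: np.ndarray, band: FilterSpec, fs: float) -> np.ndarray:
    """Band-pass the trace; zeros (hence an undefined rate) when the
    passband holds essentially none of the signal power."""
    x = np.asarray(channel, dtype=float)
    if np.var(x) == 0:
        return np.zeros_like(x)
    freqs, pxx = sps.periodogram(x - x.mean(), fs=fs, window="boxcar",
                                 detrend=False)
    inband = (freqs >= band.f_low) & (freqs <= band.f_high)
    if pxx[inband].sum() < _INBAND_POWER_FLOOR * pxx.sum():
        return np.zeros_like(x)
    return apply_filter(x, band, fs)


def estimate_respiration_rate(channel: np.ndarray, fs: float) -> float:
    """Breaths/min from the abdomen x-axis angular velocity.

    Band-pass 0.08-0.9 Hz, peak detection, then ``count * 60 / duration``.
    Returns NaN when no breath peaks are found or the passband is empty.
    """
    filtered = _band_filtered(channel, RESPIRATION_BAND, fs)
    peaks = detect_peaks(filtered, fs, min_prominence_sd=0.5,
                         min_distance_s=60.0 / 90.0)
    return _rate_from_count(peaks)


def estimate_pulse_rate(channel: np.ndarray, fs: float) -> float:
    """Beats/min from the wrist x-axis angular velocity (band 1-5 Hz)."""
    filtered = _band_filtered(channel, PULSE_BAND, fs)
    peaks = detect_peaks(filtered, fs, min_prominence_sd=0.5,
                         min_distance_s=60.0 / 220.0)
    return _rate_from_count(peaks)


def estimate_heart_rate(av_xyz: np.ndarray, fs: float) -> float:
    """Beats/min from the 3-axis angular velocity measured near the heart.

    Each axis is z-scored, the axes are summed into a heart waveform, the
    waveform is band-passed and R peaks detected; the rate is taken from the
    median inter-peak interval (robust to a missed R peak).
    """
    arr = np.atleast_2d(np.asarray(av_xyz, dtype=float))
    if arr.shape[0] != 3:
        raise ValueError(f"expected 3 equal-length axes, got shape {arr.shape}")
    fused = np.zeros(arr.shape[1])
    for axis in arr:
        sd = axis.std()
        if sd > 0:
            fused += (axis - axis.mean()) / sd
    filtered = _band_filtered(fused, HEART_BAND, fs)
    peaks = detect_peaks(filtered, fs, min_prominence_sd=0.5,
                         min_distance_s=60.0 / 220.0)
    if len(peaks) < 2:
        return math.nan
    # parabolic sub-sample refinement: the sample grid (33 ms at 30 Hz)
    # would otherwise quantize the median interval by several bpm
    refined = []
    for i in peaks.indices:
        if 0 < i < filtered.size - 1:
            denom = filtered[i - 1] - 2 * filtered[i] + filtered[i + 1]
            shift = (0.5 * (filtered[i - 1] - filtered[i + 1]) / denom
                     if denom != 0 else 0.0)
            refined.append(i + float(np.clip(shift, -0.5, 0.5)))
        else:
            refined.append(float(i))
    intervals = np.diff(refined) / fs
    return 60.0 / float(np.median(intervals))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length arrays.

    r = sum((x - xbar)(y - ybar)) / sqrt(sum((x - xbar)^2) sum((y - ybar)^2))

    Returns NaN (with a warning) when either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson_r needs two equal-length 1-D arrays, n >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    den = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if den == 0.0:
        warnings.warn("pearson_r undefined for zero-variance input",
                      stacklevel=2)
        return math.nan
    r = float(dx @ dy) / den
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class Spectrum:
    """One-sided power spectrum of a single channel.

    ``power`` is the linear periodogram density; ``power_db`` its dB view.
    """

    freqs: np.ndarray
    power: np.ndarray
    node: str = ""
    channel: str = ""

    _DB_FLOOR = 1e-300

    @property
    def power_db(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.power, self._DB_FLOOR))


def power_spectrum(channel: np.ndarray, fs: float, window: str = "hann",
                   node: str = "", channel_name: str = "") -> Spectrum:
    """One-sided periodogram of a demeaned channel on the FFT grid.

    With ``window="boxcar"`` the estimate is Parseval-consistent:
    ``sum(power) * df`` equals the signal variance exactly.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 2:
        raise ValueError("power_spectrum needs at least 2 samples")
    freqs, pxx = sps.periodogram(x - x.mean(), fs=fs, window=window,
                                 detrend=False, scaling="density")
    return Spectrum(freqs=freqs, power=pxx, node=node, channel=channel_name)


@dataclass
class GroupBand:
    """Per-frequency mean +/- SD power band of one label group (in dB)."""

    freqs: np.ndarray
    mean_db: np.ndarray
    sd_db: np.ndarray
    group: str = ""


def group_band(spectra: list[Spectrum], group: str = "") -> GroupBand:
    """Mean and sample SD of dB power across subjects, per frequency bin."""
    if len(spectra) < 2:
        raise ValueError("group_band needs at least 2 spectra")
    grid = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != grid.shape or not np.allclose(s.freqs, grid):
            raise ValueError("spectra are not on a common frequency grid")
    stack = np.vstack([s.power_db for s in spectra])
    return GroupBand(freqs=grid.copy(), mean_db=stack.mean(axis=0),
                     sd_db=stack.std(axis=0, ddof=1), group=group)


def overlap_rate(band_a: GroupBand, band_b: GroupBand) -> float:
    """Percent overlap of two mean +/- 1 SD bands, averaged over frequency.

    At each bin the two bands define intervals; the per-bin ratio is the
    length of their intersection over the length of their union (0 when
    disjoint, and 1 when both intervals are identical, including the
    degenerate zero-width case).  Returns 100 x the mean ratio; symmetric
    in its arguments and bounded in [0, 100].
    """
    if band_a.freqs.shape != band_b.freqs.shape or not np.allclose(
            band_a.freqs, band_b.freqs):
        raise ValueError("group bands are not on a common frequency grid")
    lo_a, hi_a = band_a.mean_db - band_a.sd_db, band_a.mean_db + band_a.sd_db
    lo_b, hi_b = band_b.mean_db - band_b.sd_db, band_b.mean_db + band_b.sd_db
    inter = np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b)
    union = np.maximum(hi_a, hi_b) - np.minimum(lo_a, lo_b)
    ratio = np.where(
        union > 0,
        np.clip(inter, 0.0, None) / np.where(union > 0, union, 1.0),
        # both intervals degenerate: identical points overlap fully
        (np.abs(band_a.mean_db - band_b.mean_db) == 0).astype(float),
    )
    return float(100.0 * ratio.mean())
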