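"""Data fusion and feature engineering for segmented IMU frames.

Each 120 s frame of a node's 6 raw channels is first expanded to 8 channels
by appending per-sample root-mean-square composites of the acceleration and
angular-velocity triads (data fusion).  From every fused channel a fixed,
versioned catalog of 29 time/frequency features and 7 entropy features is
extracted, yielding per-node ``N x (29*8)`` position matrices and one pooled
``N x (7*8*5)`` entropy matrix (N = number of frames).

Feature order is part of the package contract: column indices are stable
across versions as long as the catalog version string is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba as nb
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .session import FUSED_CHANNELS, PLACEMENTS, Frame, FrameSet, Label, NodePlacement

__all__ = [
    "CATALOG_VERSION",
    "TIME_FREQ_FEATURES",
    "ENTROPY_FEATURES",
    "FeatureDescriptor",
    "FeatureMatrix",
    "FusedFrame",
    "fuse_channels",
    "extract_time_freq_features",
    "extract_entropy_features",
    "build_position_matrices",
    "build_entropy_matrix",
    "build_all_matrices",
]

CATALOG_VERSION = "1.0"

#: The 29 time/frequency features, in contract order.
TIME_FREQ_FEATURES: tuple[str, ...] = (
    "mean", "sd", "variance", "rms", "min", "max", "p2", "median", "iqr",
    "skewness", "kurtosis", "mad", "zcr", "sma", "energy", "crest_factor",
    "impulse_factor", "shape_factor", "waveform_length", "autocorr_lag1",
    "dominant_freq", "dominant_power", "spectral_centroid", "spectral_spread",
    "spectral_entropy", "band_power_0_2", "band_power_2_6", "band_power_6_14",
    "median_freq",
)
#: Domain tag per time/frequency feature ("time" or "frequency").
_TF_DOMAIN = dict.fromkeys(TIME_FREQ_FEATURES[:20], "time") | dict.fromkeys(
    TIME_FREQ_FEATURES[20:], "frequency")

#: The 7 entropy (movement-complexity) features, in contract order.
ENTROPY_FEATURES: tuple[str, ...] = (
    "approximate_entropy", "sample_entropy", "permutation_entropy",
    "spectral_entropy", "shannon_entropy", "fuzzy_entropy", "svd_entropy",
)

#: Entropy estimates use at most this many leading samples of a frame;
#: O(n^2) template matching beyond ~1000 samples adds cost, not precision.
ENTROPY_MAX_SAMPLES = 1024


# ---------------------------------------------------------------------------
# data fusion


@dataclass
class FusedFrame:
    """One frame with 8 channels per node (6 raw + 2 RMS composites)."""

    subject_id: str
    label: Label
    index: int
    fs: float
    nodes: dict[NodePlacement, np.ndarray] = field(repr=False)


def fuse_channels(frame: Frame) -> FusedFrame:
    """Expand each node's 6 channels to 8 by appending RMS composites.

    ``acc_rms[t] = sqrt((acc_x^2 + acc_y^2 + acc_z^2) / 3)`` and likewise
    ``av_rms``; the original channels are passed through untouched.
    """
    fused: dict[NodePlacement, np.ndarray] = {}
    for node, arr in frame.nodes.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(
                f"frame {frame.index} of {frame.subject_id}, node {node}: "
                "non-finite samples; clean the session first")
        acc, av = arr[:3], arr[3:]
        acc_rms = np.sqrt((acc ** 2).sum(axis=0) / 3.0)
        av_rms = np.sqrt((av ** 2).sum(axis=0) / 3.0)
        fused[node] = np.vstack([acc, acc_rms, av, av_rms])
    return FusedFrame(subject_id=frame.subject_id, label=frame.label,
                      index=frame.index, fs=frame.fs, nodes=fused)


# ---------------------------------------------------------------------------
# 29 time/frequency features


def _band_power(freqs: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    sel = (freqs >= lo) & (freqs < hi)
    return float(pxx[sel].sum() * df)


def extract_time_freq_features(channel: np.ndarray, fs: float) -> np.ndarray:
    """The 29 catalog features of one channel, in catalog order.

    Degenerate (zero-variance) inputs follow explicit conventions: moment
    shapes (skewness, kurtosis), ratio features with zero denominators and
    all spectral features are 0 rather than NaN.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 8:
        raise ValueError("feature extraction needs at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("channel contains non-finite samples")

    n = x.size
    mean = float(x.mean())
    dx = x - mean
    var = float(dx @ dx) / (n - 1)
    sd = np.sqrt(var)
    rms = float(np.sqrt((x @ x) / n))
    xmin, xmax = float(x.min()), float(x.max())
    absx = np.abs(x)
    sma = float(absx.mean())
    peak = float(absx.max())
    q25, q75 = np.percentile(x, [25, 75])

    if sd > 0:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x))
        zcr = float(np.count_nonzero(np.diff(np.signbit(dx))) / (n - 1))
        ac1 = float((dx[:-1] @ dx[1:]) / (dx @ dx))
    else:
        skew = kurt = zcr = ac1 = 0.0

    crest = peak / rms if rms > 0 else 0.0
    impulse = peak / sma if sma > 0 else 0.0
    shape = rms / sma if sma > 0 else 0.0

    freqs, pxx = sps.periodogram(dx, fs=fs, window="boxcar", detrend=False,
                                 scaling="density")
    total = float(pxx.sum())
    if total > 0:
        q = pxx / total
        dom_i = int(np.argmax(pxx))
        dom_freq = float(freqs[dom_i])
        dom_power = float(pxx[dom_i])
        centroid = float(freqs @ q)
        spread = float(np.sqrt(((freqs - centroid) ** 2) @ q))
        nz = q[q > 0]
        spec_ent = float(-(nz @ np.log(nz)) / np.log(q.size))
        cum = np.cumsum(q)
        med_freq = float(freqs[np.searchsorted(cum, 0.5)])
    else:
        dom_freq = dom_power = centroid = spread = spec_ent = med_freq = 0.0

    return np.array([
        mean, sd, var, rms, xmin, xmax, xmax - xmin, float(np.median(x)),
        float(q75 - q25), skew, kurt, float(np.abs(dx).mean()), zcr, sma,
        float((x @ x) / n), crest, impulse, shape,
        float(np.abs(np.diff(x)).sum()), ac1,
        dom_freq, dom_power, centroid, spread, spec_ent,
        _band_power(freqs, pxx, 0.0, 2.0), _band_power(freqs, pxx, 2.0, 6.0),
        _band_power(freqs, pxx, 6.0, 14.0), med_freq,
    ])


# ---------------------------------------------------------------------------
# 7 entropy features


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = x.size - (m - 1) * delay
    idx = np.arange(m) * delay + np.arange(n)[:, None]
    return x[idx]


@nb.njit(cache=True)
def _apen_phi(x: np.ndarray, m: int, r: float) -> float:
    """mean_i ln(C_i) with C_i the fraction of templates (self included)
    within Chebyshev distance r of template i."""
    n = x.size
    nt = n - m + 1
    acc = 0.0
    for i in range(nt):
        count = 0
        for j in range(nt):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                count += 1
        acc += np.log(count / nt)
    return acc / nt


@nb.njit(cache=True)
def _sampen_pairs(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """(A, B): matched template pairs of length m+1 and m (self excluded);
    both lengths use the same N - m starting points."""
    n = x.size
    nt = n - m
    a = 0
    b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                b += 1
                dk = abs(x[i + m] - x[j + m])
                if dk > d:
                    d = dk
                if d <= r:
                    a += 1
    return a, b


@nb.njit(cache=True)
def _fuzzy_phi(x: np.ndarray, m: int, w: int, r: float) -> float:
    """Mean Gaussian membership exp(-(d/r)^2) over template pairs, with
    templates of length w demeaned individually; N - m starting points."""
    n = x.size
    nt = n - m
    acc = 0.0
    for i in range(nt):
        mi = 0.0
        for k in range(w):
            mi += x[i + k]
        mi /= w
        for j in range(i + 1, nt):
            mj = 0.0
            for k in range(w):
                mj += x[j + k]
            mj /= w
            d = 0.0
            for k in range(w):
                dk = abs((x[i + k] - mi) - (x[j + k] - mj))
                if dk > d:
                    d = dk
            acc += np.exp(-((d / r) ** 2))
    return acc / (nt * (nt - 1) / 2.0)


def approximate_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r = r_frac * SD); self-matches included."""
    x = np.ascontiguousarray(x, dtype=float)
    r = r_frac * x.std()
    return float(_apen_phi(x, m, r) - _apen_phi(x, m + 1, r))


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy SampEn(m, r = r_frac * SD); self-matches excluded.

    Both template lengths use the same N - m starting points.  When no
    (m+1)-matches exist the maximal finite value ``-ln(2 / ((N-m)(N-m-1)))``
    is returned so that the feature stays finite.
    """
    x = np.ascontiguousarray(x, dtype=float)
    r = r_frac * x.std()
    a, b = _sampen_pairs(x, m, r)
    if b == 0:
        return 0.0
    if a == 0:
        nm = x.size - m
        return float(-np.log(2.0 / (nm * (nm - 1))))
    return float(-np.log(a / b))


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Shannon entropy (nats) of ordinal patterns; ties broken by position.

    The maximum is ``ln(order!)``; a constant signal maps to one pattern
    and scores 0.
    """
    x = np.asarray(x, dtype=float)
    emb = _embed(x, order, delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    base = order ** np.arange(order)
    codes = patterns @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p @ np.log(p)))


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Normalized Shannon entropy of the periodogram (0 = pure tone-ish)."""
    x = np.asarray(x, dtype=float)
    _, pxx = sps.periodogram(x - x.mean(), fs=fs, window="boxcar",
                             detrend=False)
    total = pxx.sum()
    if total <= 0:
        return 0.0
    q = pxx / total
    nz = q[q > 0]
    return float(-(nz @ np.log(nz)) / np.log(q.size))


def shannon_entropy(x: np.ndarray, bins: int = 16) -> float:
    """Shannon entropy (nats) of a 16-bin amplitude histogram."""
    x = np.asarray(x, dtype=float)
    if x.max() == x.min():
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p @ np.log(p)))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Fuzzy entropy with Gaussian membership exp(-(d/r)^2) on demeaned
    templates; 0 for a zero-variance signal."""
    x = np.ascontiguousarray(x, dtype=float)
    r = r_frac * x.std()
    if r == 0.0:
        return 0.0
    p_m = _fuzzy_phi(x, m, m, r)
    p_m1 = _fuzzy_phi(x, m, m + 1, r)
    if p_m <= 0 or p_m1 <= 0:
        return 0.0
    return float(np.log(p_m) - np.log(p_m1))


def svd_entropy(x: np.ndarray, order: int = 10, delay: int = 1) -> float:
    """Shannon entropy (nats) of normalized singular values of the
    delay-embedding matrix; 0 for rank-one (constant/linear) signals."""
    x = np.asarray(x, dtype=float)
    emb = _embed(x, order, delay)
    s = np.linalg.svd(emb, compute_uv=False)
    total = s.sum()
    if total <= 0:
        return 0.0
    p = s / total
    p = p[p > 1e-12]
    return float(-(p @ np.log(p)))


def extract_entropy_features(channel: np.ndarray, fs: float,
                             max_samples: int = ENTROPY_MAX_SAMPLES) -> np.ndarray:
    """The 7 catalog entropy features of one channel, in catalog order.

    Template-matching entropies are evaluated on the first ``max_samples``
    samples of the frame.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 32:
        raise ValueError("entropy extraction needs at least 32 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("channel contains non-finite samples")
    xs = x[:max_samples]
    return np.array([
        approximate_entropy(xs),
        sample_entropy(xs),
        permutation_entropy(xs),
        spectral_entropy(x, fs),
        shannon_entropy(x),
        fuzzy_entropy(xs),
        svd_entropy(xs),
    ])


# ---------------------------------------------------------------------------
# feature matrices


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one feature-matrix column."""

    node: str
    channel: str
    feature: str
    domain: str  # time | frequency | entropy

    @property
    def name(self) -> str:
        return f"{self.node}.{self.channel}.{self.feature}"


@dataclass
class FeatureMatrix:
    """An ``N samples x F features`` table with per-column provenance."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    labels: list[Label]
    subject_ids: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, f = self.values.shape
        if len(self.descriptors) != f:
            raise ValueError("descriptor count must equal feature count")
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids must match sample count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def binary_labels(self) -> np.ndarray:
        """Two-class view: 'Normal' vs 'Risky'."""
        return np.array([lab.binary for lab in self.labels])

    @property
    def multiclass_labels(self) -> np.ndarray:
        return np.array([lab.value for lab in self.labels])

    def column_index(self, node: str, channel: str, feature: str) -> int:
        """Map a descriptor to its unique column index."""
        hits = [i for i, d in enumerate(self.descriptors)
                if (d.node, d.channel, d.feature) == (node, channel, feature)]
        if len(hits) != 1:
            raise KeyError(f"descriptor ({node}, {channel}, {feature}) maps "
                           f"to {len(hits)} columns")
        return hits[0]

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[idx],
            descriptors=self.descriptors,
            labels=[self.labels[i] for i in np.atleast_1d(idx)],
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(idx)],
            name=self.name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[d.name for d in self.descriptors])
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", [lab.value for lab in self.labels])
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path)
        subject_ids = df.pop("subject_id").tolist()
        labels = [Label(v) for v in df.pop("label")]
        descriptors = []
        for col in df.columns:
            node, channel, feature = col.split(".", 2)
            domain = ("entropy" if feature in ENTROPY_FEATURES
                      else _TF_DOMAIN.get(feature, "time"))
            descriptors.append(FeatureDescriptor(node, channel, feature, domain))
        return cls(values=df.to_numpy(dtype=float), descriptors=descriptors,
                   labels=labels, subject_ids=subject_ids, name=name)


def _require_frames(frame_set: FrameSet) -> None:
    if len(frame_set) == 0:
        raise ValueError("empty frame set: nothing to extract features from")


def build_position_matrices(
        frame_set: FrameSet,
) -> dict[NodePlacement, FeatureMatrix]:
    """One ``N x (29*8)`` time/frequency matrix per sensing node.

    Columns are channel-major: for each of the 8 fused channels, the 29
    catalog features in order.
    """
    _require_frames(frame_set)
    fs = frame_set.fs
    per_node: dict[NodePlacement, list[np.ndarray]] = {n: [] for n in PLACEMENTS}
    for frame in frame_set:
        fused = fuse_channels(frame)
        for node in PLACEMENTS:
            arr = fused.nodes[node]
            row = np.concatenate([
                extract_time_freq_features(arr[ci], fs)
                for ci in range(len(FUSED_CHANNELS))
            ])
            per_node[node].append(row)

    out: dict[NodePlacement, FeatureMatrix] = {}
    labels = frame_set.labels
    subjects = frame_set.subject_ids
    for node in PLACEMENTS:
        descriptors = [
            FeatureDescriptor(node.value, ch, feat, _TF_DOMAIN[feat])
            for ch in FUSED_CHANNELS for feat in TIME_FREQ_FEATURES
        ]
        out[node] = FeatureMatrix(
            values=np.vstack(per_node[node]), descriptors=descriptors,
            labels=list(labels), subject_ids=list(subjects),
            name=f"position_{node.value}")
    return out


def build_entropy_matrix(
        frame_set: FrameSet,
        entropy_max_samples: int = ENTROPY_MAX_SAMPLES,
) -> FeatureMatrix:
    """The pooled ``N x (7*8*5)`` entropy matrix.

    Node blocks follow the canonical placement order; within each node the
    8 fused channels are laid out channel-major over the 7 entropy features.
    """
    _require_frames(frame_set)
    fs = frame_set.fs
    rows = []
    for frame in frame_set:
        fused = fuse_channels(frame)
        rows.append(np.concatenate([
            extract_entropy_features(fused.nodes[node][ci], fs,
                                     max_samples=entropy_max_samples)
            for node in PLACEMENTS for ci in range(len(FUSED_CHANNELS))
        ]))
    descriptors = [
        FeatureDescriptor(node.value, ch, feat, "entropy")
        for node in PLACEMENTS for ch in FUSED_CHANNELS
        for feat in ENTROPY_FEATURES
    ]
    return FeatureMatrix(values=np.vstack(rows), descriptors=descriptors,
                         labels=list(frame_set.labels),
                         subject_ids=list(frame_set.subject_ids),
                         name="entropy")


def build_all_matrices(
        frame_set: FrameSet,
        entropy_max_samples: int = ENTROPY_MAX_SAMPLES,
) -> list[FeatureMatrix]:
    """The six feature matrices (5 position + 1 entropy), in fixed order."""
    position = build_position_matrices(frame_set)
    matrices = [position[node] for node in PLACEMENTS]
    matrices.append(build_entropy_matrix(frame_set,
                                         entropy_max_samples=entropy_max_samples))
    return matrices
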