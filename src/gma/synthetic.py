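"""Synthetic labeled IMU cohorts and vital-sign traces.

The real clinical recordings behind the general-movements assessment study
are not publicly deposited, so this module generates cohorts that carry the
statistical structure the downstream analysis exploits:

* ~6-minute sessions at 30 Hz from five body sites;
* Normal subjects move with wider amplitude ranges (and therefore uniformly
  higher 0-14 Hz spectral power) than Risky subjects, with the contrast set
  by ``effect_scale`` (amplitude-range ratio Normal:Risky);
* Risky subjects show occasional isolated 1-2 s high-amplitude bulges;
* sporadic missing samples (NaN sentinels) and high-frequency (>14 Hz)
  sensor noise.

The movement model is band-limited (~0-10 Hz) Gaussian burst noise riding on
a constant per-node gravity orientation.  It reproduces the qualitative
class contrasts without claiming physiological fidelity.

Controlled quasi-periodic vital-sign traces (respiration, pulse, heartbeat)
with known event times are also generated here so that the rate-extraction
chains can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .session import CHANNELS, MISSING, PLACEMENTS, ImuSession, Label, coerce_label

__all__ = [
    "CohortSpec",
    "VitalTrace",
    "generate_session",
    "generate_cohort",
    "generate_vital_trace",
    "inject_missing",
    "VITAL_RATE_BOUNDS",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_scale`` is the Normal:Risky amplitude-range ratio (>= 0; may be
    ``inf`` for a degenerate motionless Risky class).  ``bulge_rate`` is the
    expected number of isolated Risky bulges per minute.
    """

    n_normal: int = 12
    n_low_risk: int = 3
    n_high_risk: int = 3
    duration_s: float = 360.0
    fs: float = 30.0
    effect_scale: float = 2.0
    bulge_rate: float = 0.5
    missing_rate: float = 0.002
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_low_risk, self.n_high_risk) < 0:
            raise ValueError("cohort counts must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")

    @property
    def n_total(self) -> int:
        return self.n_normal + self.n_low_risk + self.n_high_risk


# Per-node movement amplitudes (acceleration in g, angular velocity in deg/s)
# for a Normal subject.  Limbs move more than the head, matching the general
# pattern of supine infant movement.
_NODE_ACC_AMPL = {
    "head": 0.08,
    "left_wrist": 0.30,
    "right_wrist": 0.30,
    "left_ankle": 0.35,
    "right_ankle": 0.35,
}
_NODE_AV_AMPL = {
    "head": 10.0,
    "left_wrist": 45.0,
    "right_wrist": 45.0,
    "left_ankle": 55.0,
    "right_ankle": 55.0,
}
# Constant gravity orientation per node (unit vector, in g) for the
# acceleration channels of a supine infant.
_NODE_GRAVITY = {
    "head": (0.0, 0.10, 0.99),
    "left_wrist": (0.20, -0.10, 0.97),
    "right_wrist": (-0.20, -0.10, 0.97),
    "left_ankle": (0.15, 0.20, 0.97),
    "right_ankle": (-0.15, 0.20, 0.97),
}

_MOVEMENT_BAND_HZ = 10.0  # soft low-pass corner of the movement process
_ENVELOPE_HZ = 0.4        # burst-envelope bandwidth
_NOISE_HP_HZ = 14.0       # sensor-noise high-pass corner


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        cutoff: float, order: int = 2) -> np.ndarray:
    """Unit-variance-ish Gaussian noise low-passed at ``cutoff`` Hz."""
    white = rng.standard_normal(n)
    if cutoff >= fs / 2:
        return white
    # single-pass: keeps a soft roll-off so movement power stays above the
    # sensor-noise floor throughout the 0-14 Hz analysis band
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfilt(sos, white)


def _burst_envelope(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Non-negative slowly varying envelope producing movement bursts."""
    slow = _band_limited_noise(rng, n, fs, _ENVELOPE_HZ, order=2)
    env = np.clip(slow, 0.0, None) ** 2
    peak = env.max()
    if peak > 0:
        env /= peak
    return 0.15 + env  # small tonic floor so channels are never dead


def generate_session(label: Label | str, spec: CohortSpec, seed: int,
                     subject_id: str | None = None) -> ImuSession:
    """Generate one labeled session; a pure function of (label, spec, seed).

    Normal subjects receive the full movement amplitude; Risky subjects the
    same process divided by ``spec.effect_scale``, plus sparse 1-2 s
    high-amplitude bulges (Poisson ``bulge_rate`` per minute).
    """
    label = coerce_label(label)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6D0]))
    n = int(round(spec.fs * spec.duration_s))
    risky = label.is_risky
    # effect_scale -> inf yields a motionless Risky class
    scale = 1.0 if not risky else (
        0.0 if np.isinf(spec.effect_scale) else 1.0 / max(spec.effect_scale, 1e-12)
    )

    nodes: dict = {}
    for node in PLACEMENTS:
        arr = np.empty((len(CHANNELS), n))
        env = _burst_envelope(rng, n, spec.fs)
        gravity = _NODE_GRAVITY[node.value]
        for ci, ch in enumerate(CHANNELS):
            base = _NODE_ACC_AMPL[node.value] if ch.startswith("acc") else _NODE_AV_AMPL[node.value]
            movement = base * scale * env * _band_limited_noise(
                rng, n, spec.fs, _MOVEMENT_BAND_HZ, order=2)
            offset = gravity["xyz".index(ch[-1])] if ch.startswith("acc") else 0.0
            arr[ci] = offset + movement
        nodes[node] = arr

    if risky:
        _add_bulges(rng, nodes, spec)

    if spec.noise_sd > 0:
        # steep zero-phase high-pass confines sensor noise above 14 Hz
        sos = sps.butter(6, _NOISE_HP_HZ * 1.04, btype="high", fs=spec.fs,
                         output="sos")
        for node in PLACEMENTS:
            arr = nodes[node]
            for ci, ch in enumerate(CHANNELS):
                unit = 1.0 if ch.startswith("acc") else 100.0  # deg/s noise scale
                arr[ci] += spec.noise_sd * unit * sps.sosfiltfilt(
                    sos, rng.standard_normal(n))

    return ImuSession(
        subject_id=subject_id or f"synthetic-{label.value}-{seed}",
        label=label,
        fs=spec.fs,
        duration_s=spec.duration_s,
        nodes=nodes,
    )


def _add_bulges(rng: np.random.Generator, nodes: dict, spec: CohortSpec) -> None:
    """Superimpose isolated 1-2 s high-amplitude bulges on a Risky session."""
    n = int(round(spec.fs * spec.duration_s))
    minutes = spec.duration_s / 60.0
    n_bulges = rng.poisson(spec.bulge_rate * minutes)
    for _ in range(n_bulges):
        node = PLACEMENTS[rng.integers(len(PLACEMENTS))]
        width_s = rng.uniform(1.0, 2.0)
        half = int(round(width_s * spec.fs / 2))
        center = rng.integers(half, max(n - half, half + 1))
        t = np.arange(n)
        pulse = np.exp(-0.5 * ((t - center) / (half / 2.5)) ** 2)
        arr = nodes[node]
        for ci, ch in enumerate(CHANNELS):
            base = _NODE_ACC_AMPL[node.value] if ch.startswith("acc") else _NODE_AV_AMPL[node.value]
            arr[ci] += rng.choice([-1.0, 1.0]) * 2.0 * base * pulse


def generate_cohort(spec: CohortSpec) -> list[ImuSession]:
    """Generate the full labeled cohort described by ``spec``.

    Per-session seeds are derived from ``(spec.seed, subject index)`` so that
    enlarging the cohort never perturbs earlier subjects.
    """
    if spec.n_total == 0:
        raise ValueError("cohort must contain at least one subject")
    labels = (
        [Label.normal] * spec.n_normal
        + [Label.low_risk] * spec.n_low_risk
        + [Label.high_risk] * spec.n_high_risk
    )
    sessions = []
    for i, label in enumerate(labels):
        sub_seed = int(
            np.random.SeedSequence([int(spec.seed), i]).generate_state(1)[0]
            % (2**31)
        )
        sess = generate_session(
            label, spec, seed=sub_seed, subject_id=f"S{i + 1:03d}")
        if spec.missing_rate > 0:
            sess = inject_missing(sess, spec.missing_rate, seed=sub_seed + 1)
        sessions.append(sess)
    return sessions


#: Physiological rate bounds (events/min) per vital kind.
VITAL_RATE_BOUNDS = {
    "respiration": (5.0, 90.0),
    "pulse": (30.0, 220.0),
    "cardiac": (30.0, 220.0),
}


@dataclass
class VitalTrace:
    """A synthetic vital-sign channel with its ground-truth event times."""

    kind: str
    fs: float
    duration_s: float
    values: np.ndarray
    event_times_s: np.ndarray

    @property
    def true_rate_per_min(self) -> float:
        return 60.0 * len(self.event_times_s) / self.duration_s


def generate_vital_trace(kind: str, rate_per_min: float, duration_s: float,
                         fs: float, noise_sd: float, seed: int,
                         jitter_frac: float = 0.02) -> VitalTrace:
    """Quasi-periodic vital-sign waveform plus true event times.

    Respiration is a smooth bump train (sinusoid-like); pulse and cardiac
    are trains of sharp transients.  Event intervals carry small
    multiplicative jitter (``jitter_frac`` of the period).
    """
    if kind not in VITAL_RATE_BOUNDS:
        raise ValueError(f"unknown vital kind {kind!r}; expected one of "
                         f"{sorted(VITAL_RATE_BOUNDS)}")
    lo, hi = VITAL_RATE_BOUNDS[kind]
    if not (lo <= rate_per_min <= hi):
        raise ValueError(
            f"{kind} rate {rate_per_min}/min outside physiological bounds "
            f"[{lo}, {hi}]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE0]))
    period = 60.0 / rate_per_min
    # event times: half-period offset, jittered intervals
    times = []
    t = period / 2.0
    while t < duration_s:
        times.append(t)
        t += period * (1.0 + jitter_frac * rng.standard_normal())
    events = np.asarray(times)

    n = int(round(fs * duration_s))
    tgrid = np.arange(n) / fs
    width = 0.30 * period if kind == "respiration" else 0.10
    values = np.zeros(n)
    for ev in events:
        values += np.exp(-0.5 * ((tgrid - ev) / width) ** 2)
    values /= max(values.max(), 1e-12)
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(n)
    return VitalTrace(kind=kind, fs=fs, duration_s=duration_s,
                      values=values, event_times_s=events)


def inject_missing(session: ImuSession, missing_rate: float,
                   seed: int) -> ImuSession:
    """Replace samples with the NaN sentinel i.i.d. at ``missing_rate``.

    The first and last sample of every channel are always kept so that
    linear interpolation is total.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    out = session.copy()
    if missing_rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    for node in PLACEMENTS:
        arr = out.nodes[node]
        mask = rng.random(arr.shape) < missing_rate
        mask[:, 0] = False
        mask[:, -1] = False
        arr[mask] = MISSING
    return out
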