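"""Core containers for five-node infant IMU recordings.

A recording session holds synchronized 3-axis acceleration (g) and 3-axis
angular velocity (deg/s) streams from five body placements (head, both
wrists, both ankles) sampled at a common rate.  Missing samples are encoded
as NaN and are never silently dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Channel order used throughout the package for raw (6-channel) node data.
CHANNELS: tuple[str, ...] = ("acc_x", "acc_y", "acc_z", "av_x", "av_y", "av_z")

#: Channel order after RMS data fusion (6 -> 8 dimensions).
FUSED_CHANNELS: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z", "acc_rms", "av_x", "av_y", "av_z", "av_rms",
)

#: Sentinel for missing ("NULL") samples.
MISSING = np.nan


class NodePlacement(str, enum.Enum):
    """The five sensor-node body sites."""

    head = "head"
    left_wrist = "left_wrist"
    right_wrist = "right_wrist"
    left_ankle = "left_ankle"
    right_ankle = "right_ankle"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical placement order (defines block order in the entropy matrix).
PLACEMENTS: tuple[NodePlacement, ...] = (
    NodePlacement.head,
    NodePlacement.left_wrist,
    NodePlacement.right_wrist,
    NodePlacement.left_ankle,
    NodePlacement.right_ankle,
)


class Label(str, enum.Enum):
    """Clinical general-movements label of a subject."""

    normal = "Normal"
    low_risk = "LowRisk"
    high_risk = "HighRisk"

    @property
    def is_risky(self) -> bool:
        return self is not Label.normal

    @property
    def binary(self) -> str:
        """Two-class view: 'Normal' vs 'Risky'."""
        return "Risky" if self.is_risky else "Normal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def coerce_label(label: "Label | str") -> Label:
    if isinstance(label, Label):
        return label
    try:
        return Label(label)
    except ValueError:
        pass
    try:
        return Label[str(label)]
    except KeyError:
        raise ValueError(
            f"unknown label {label!r}; expected one of "
            f"{[lab.value for lab in Label]}"
        ) from None


@dataclass
class ImuSession:
    """One subject's labeled five-node, six-channel recording.

    ``nodes`` maps each :class:`NodePlacement` to a ``(6, n)`` float array in
    the :data:`CHANNELS` order, with ``n = round(fs * duration_s)``.
    """

    subject_id: str
    label: Label
    fs: float
    duration_s: float
    nodes: dict[NodePlacement, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.label = coerce_label(self.label)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")
        expected = self.n_samples
        missing_nodes = set(PLACEMENTS) - set(self.nodes)
        if missing_nodes:
            raise ValueError(f"session lacks nodes: {sorted(n.value for n in missing_nodes)}")
        for node, arr in self.nodes.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(CHANNELS), expected):
                raise ValueError(
                    f"node {node}: expected shape {(len(CHANNELS), expected)}, "
                    f"got {arr.shape}"
                )
            self.nodes[node] = arr

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def channel(self, node: NodePlacement, name: str) -> np.ndarray:
        """Return one channel array (a view) by node and channel name."""
        return self.nodes[node][CHANNELS.index(name)]

    def copy(self) -> "ImuSession":
        return ImuSession(
            subject_id=self.subject_id,
            label=self.label,
            fs=self.fs,
            duration_s=self.duration_s,
            nodes={k: v.copy() for k, v in self.nodes.items()},
        )


@dataclass
class Frame:
    """A fixed-length window cut from one session (all 5 nodes)."""

    subject_id: str
    label: Label
    index: int
    start_sample: int
    fs: float
    nodes: dict[NodePlacement, np.ndarray] = field(repr=False)

    @property
    def n_samples(self) -> int:
        return next(iter(self.nodes.values())).shape[1]


@dataclass
class FrameSet:
    """Ordered fixed-length overlapping windows from one or more sessions."""

    frames: list[Frame]
    window_s: float
    overlap_s: float
    fs: float

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def labels(self) -> list[Label]:
        return [f.label for f in self.frames]

    @property
    def subject_ids(self) -> list[str]:
        return [f.subject_id for f in self.frames]

    def extend(self, other: "FrameSet") -> None:
        if (other.window_s, other.overlap_s, other.fs) != (
            self.window_s, self.overlap_s, self.fs,
        ):
            raise ValueError("cannot merge frame sets with different windowing")
        self.frames.extend(other.frames)
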