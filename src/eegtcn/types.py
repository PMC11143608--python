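"""Core data containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

HEALTHY = "healthy"
EP = "EP"
GROUPS = (HEALTHY, EP)

#: Recording electrodes of the international 10-20 montage, in acquisition order.
CHANNELS_1020: Tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)


def label_to_int(group: str) -> int:
    """Map a group label to the binary class index (EP is the positive class)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group label: {group!r}")
    return int(group == EP)


@dataclass
class RawRecording:
    """One subject's continuous multichannel EEG.

    ``signal`` is a (n_channels, n_samples) float array in microvolts.
    """

    subject_id: str
    group: str
    rate: float
    channels: List[str]
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label: {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def copy(self, **changes) -> "RawRecording":
        out = replace(self, **changes)
        if "signal" not in changes:
            out.signal = self.signal.copy()
        return out


@dataclass
class Segment:
    """A fixed-length window cut from one recording."""

    values: np.ndarray  # (channels, window_samples)
    subject_id: str
    label: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("segment values must be 2-D")
        if self.label not in GROUPS:
            raise ValueError(f"unknown label: {self.label!r}")


@dataclass
class SegmentSet:
    """An ordered collection of segments with a subject lookup index."""

    segments: List[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __getitem__(self, i: int) -> Segment:
        return self.segments[i]

    @property
    def subject_index(self) -> Dict[str, List[int]]:
        idx: Dict[str, List[int]] = {}
        for i, seg in enumerate(self.segments):
            idx.setdefault(seg.subject_id, []).append(i)
        return idx

    @property
    def subjects(self) -> List[str]:
        seen: Dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.subject_id)
        return list(seen)

    def subset(self, subject_ids: Sequence[str]) -> "SegmentSet":
        wanted = set(subject_ids)
        return SegmentSet([s for s in self.segments if s.subject_id in wanted])

    def extend(self, other: "SegmentSet") -> None:
        self.segments.extend(other.segments)

    def to_arrays(self) -> Tuple[np.ndarray, np.ndarray, List[str]]:
        """Stack into (X, y, subject_ids) with X of shape (n, channels, samples)."""
        if not self.segments:
            raise ValueError("empty segment set")
        X = np.stack([s.values for s in self.segments])
        y = np.array([label_to_int(s.label) for s in self.segments], dtype=np.int64)
        subs = [s.subject_id for s in self.segments]
        return X, y, subs
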