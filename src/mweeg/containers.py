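"""Core in-memory containers for probe-based lecture EEG.

The pipeline operates on three objects: a :class:`RawRecording` (continuous
multichannel signal), a list of :class:`ProbeEvent` (thought-probe onsets with
the participant's self-reported attentional state), and an :class:`EpochSet`
(fixed-length windows cut from the recording, optionally labelled by probe
response). Everything downstream — conditioning, ICA, band power, CSP,
classification — consumes and returns these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

# Probe response labels. MW (mind wandering) is the positive class throughout.
MW = "MW"
NOT_MW = "NOT_MW"
UNSURE = "UNSURE"
RESPONSES = (MW, NOT_MW, UNSURE)

#: 16-channel 10-20 montage used for simultaneous audience recordings.
DEFAULT_LABELS = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "F4", "F8",
    "T7", "C3", "C4", "T8",
    "P7", "P8",
    "O1", "Oz", "O2",
)

# Approximate 2-D scalp projections (head radius 1, nose up) for topography
# plots; x is right-positive, y is front-positive.
_POSITIONS_2D = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.41, 0.53), "F4": (0.41, 0.53),
    "F8": (0.81, 0.59),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "P7": (-0.81, -0.59), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with 2-D scalp positions."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: Sequence[str]) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])


def default_montage(labels: Iterable[str] = DEFAULT_LABELS) -> Montage:
    labels = tuple(labels)
    pos = np.array([_POSITIONS_2D[l] for l in labels])
    return Montage(labels, pos)


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    data : (n_channels, n_samples) array
    fs : sampling rate in Hz
    montage : channel labels/positions, row-aligned with ``data``
    start_time : seconds; probe onsets are expressed on the same clock
    """

    data: np.ndarray
    fs: float
    montage: Montage
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{len(self.montage)} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "RawRecording":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray) -> "RawRecording":
        return replace(self, data=np.asarray(data, dtype=float))

    def drop_channels(self, labels: Sequence[str]) -> "RawRecording":
        """Return a recording without the named channels."""
        drop = set(labels)
        unknown = drop - set(self.montage.labels)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        keep = [l for l in self.montage.labels if l not in drop]
        if not keep:
            raise ValueError("cannot drop every channel")
        idx = [self.montage.index(l) for l in keep]
        return RawRecording(
            self.data[idx], self.fs, self.montage.subset(keep), self.start_time
        )


@dataclass(frozen=True)
class ProbeEvent:
    """A thought probe: onset (s from recording start) and the response."""

    onset: float
    response: str
    probe_id: int

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")


def validate_probes(probes: Sequence[ProbeEvent]) -> None:
    onsets = [p.onset for p in probes]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("probe onsets must be strictly increasing")


@dataclass
class EpochSet:
    """Epochs x channels x samples with optional labels and probe grouping.

    ``labels`` is None for unlabeled sets (e.g. the 1 s artifact-scan epochs);
    labelled sets carry one {MW, NOT_MW} label per epoch and a ``probe_ids``
    vector grouping the epochs cut from the same pre-probe window.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    labels: np.ndarray | None = None
    probe_ids: np.ndarray | None = None
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel axis inconsistent with montage")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != self.n_epochs:
                raise ValueError("one label per epoch required")
        if self.probe_ids is not None:
            self.probe_ids = np.asarray(self.probe_ids, dtype=int)
            if self.probe_ids.shape[0] != self.n_epochs:
                raise ValueError("one probe_id per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_length(self) -> float:
        return self.n_samples / self.fs

    def select(self, index: np.ndarray) -> "EpochSet":
        """Subset epochs by boolean mask or integer index array."""
        index = np.asarray(index)
        return EpochSet(
            self.data[index],
            self.fs,
            self.montage,
            None if self.labels is None else self.labels[index],
            None if self.probe_ids is None else self.probe_ids[index],
            self.subject_id,
        )

    def class_counts(self) -> dict[str, int]:
        if self.labels is None:
            raise ValueError("epoch set is unlabeled")
        return {
            MW: int(np.sum(self.labels == MW)),
            NOT_MW: int(np.sum(self.labels == NOT_MW)),
        }

    def observed_mw_rate(self) -> float:
        counts = self.class_counts()
        total = counts[MW] + counts[NOT_MW]
        if total == 0:
            raise ValueError("no labelled epochs")
        return counts[MW] / total

    def with_data(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=np.asarray(data, dtype=float))


def concatenate_epochs(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack epoch sets recorded on identical montages (used by LOSO)."""
    if not sets:
        raise ValueError("nothing to concatenate")
    labels0 = sets[0].montage.labels
    if any(s.montage.labels != labels0 for s in sets):
        raise ValueError("montages differ; intersect channels first")
    has_labels = all(s.labels is not None for s in sets)
    has_probes = all(s.probe_ids is not None for s in sets)
    # offset probe ids so groups stay distinct across subjects
    probe_ids = None
    if has_probes:
        parts, offset = [], 0
        for s in sets:
            parts.append(s.probe_ids + offset)
            offset += int(s.probe_ids.max()) + 1 if len(s.probe_ids) else 0
        probe_ids = np.concatenate(parts)
    return EpochSet(
        np.concatenate([s.data for s in sets]),
        sets[0].fs,
        sets[0].montage,
        np.concatenate([s.labels for s in sets]) if has_labels else None,
        probe_ids,
        "+".join(s.subject_id for s in sets),
    )
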