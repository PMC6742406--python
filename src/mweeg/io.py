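"""File I/O: EDF reading, events CSV, and the simulator's on-disk format.

Recordings can be loaded from EDF (via mne) or from the package's own NPZ
container. Probe events travel as a two-column CSV ``onset_s,response``
with responses coded A (paying attention), B (mind wandering), C (unsure),
mirroring the on-screen probe choices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    MW,
    NOT_MW,
    UNSURE,
    Montage,
    ProbeEvent,
    RawRecording,
    default_montage,
)
from .synth import GroundTruth

_CODE_TO_RESPONSE = {"A": NOT_MW, "B": MW, "C": UNSURE}
_RESPONSE_TO_CODE = {v: k for k, v in _CODE_TO_RESPONSE.items()}


def read_edf(path: str | Path) -> RawRecording:
    """Load a continuous recording from EDF, in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    try:
        montage = default_montage(labels)
    except KeyError:
        # unknown labels: place channels on a circle so plotting still works
        theta = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
        montage = Montage(labels, np.column_stack([np.sin(theta), np.cos(theta)]))
    return RawRecording(raw.get_data() * 1e6, raw.info["sfreq"], montage)


def write_events_csv(path: str | Path, probes: Sequence[ProbeEvent]) -> None:
    pd.DataFrame(
        {
            "onset_s": [p.onset for p in probes],
            "response": [_RESPONSE_TO_CODE[p.response] for p in probes],
        }
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[ProbeEvent]:
    df = pd.read_csv(path)
    if not {"onset_s", "response"} <= set(df.columns):
        raise ValueError("events CSV needs columns onset_s,response")
    return [
        ProbeEvent(float(row.onset_s), _CODE_TO_RESPONSE[str(row.response)], i)
        for i, row in enumerate(df.itertuples())
    ]


def write_recording_npz(path: str | Path, raw: RawRecording) -> None:
    np.savez_compressed(
        path,
        data=raw.data,
        fs=raw.fs,
        labels=np.array(raw.montage.labels),
        positions=raw.montage.positions,
        start_time=raw.start_time,
    )


def read_recording_npz(path: str | Path) -> RawRecording:
    with np.load(path, allow_pickle=False) as z:
        montage = Montage(tuple(str(l) for l in z["labels"]), z["positions"])
        return RawRecording(z["data"], float(z["fs"]), montage, float(z["start_time"]))


def write_ground_truth_json(path: str | Path, truth: GroundTruth) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "probe_onsets": truth.probe_onsets.tolist(),
                "probe_responses": list(truth.probe_responses),
                "mixing_used": truth.mixing_used.tolist(),
                "effect_sources": truth.effect_sources.tolist(),
            },
            indent=2,
        )
    )


def load_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    if path.suffix.lower() == ".npz":
        return read_recording_npz(path)
    raise ValueError(f"unsupported recording format: {path.suffix}")
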