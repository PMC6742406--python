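"""Canonical frequency bands and per-epoch band power.

Band powers feed two paths: the repeated-measures ANOVAs (per channel and
per participant) and the per-band CSP machine-learning analysis. Powers are
Welch estimates (1 s Hann segments, 50% overlap) integrated over the band;
integration uses the closed-open convention [lo, hi+1) on the frequency
grid so adjacent canonical bands never double-count a bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import filtfilt, firwin, welch

from .containers import EpochSet, RawRecording
from .conditioning import bandpass


class FrequencyBand(NamedTuple):
    name: str
    lo: float
    hi: float


THETA = FrequencyBand("theta", 4.0, 7.0)
ALPHA = FrequencyBand("alpha", 8.0, 12.0)
BETA1 = FrequencyBand("beta1", 13.0, 18.0)
BETA2 = FrequencyBand("beta2", 19.0, 30.0)
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (THETA, ALPHA, BETA1, BETA2)


def band_by_name(name: str) -> FrequencyBand:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


@dataclass
class BandPowerTable:
    """Per-epoch, per-channel, per-band power in uV^2 with epoch metadata."""

    values: np.ndarray  # (n_epochs, n_channels, n_bands)
    bands: tuple[FrequencyBand, ...]
    labels: np.ndarray | None
    probe_ids: np.ndarray | None
    channel_labels: tuple[str, ...]
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("band powers must be non-negative")

    def band_index(self, band: FrequencyBand | str) -> int:
        name = band if isinstance(band, str) else band.name
        return [b.name for b in self.bands].index(name)


def band_power(
    epochs: EpochSet,
    bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
    method: str = "welch",
    seg_seconds: float = 1.0,
) -> BandPowerTable:
    """Integrate the per-epoch PSD over each band.

    welch: Hann segments of ``seg_seconds`` with 50% overlap (falls back to
    the epoch length when epochs are shorter); periodogram: single
    rectangular segment.
    """
    nyq = epochs.fs / 2.0
    for band in bands:
        if band.hi >= nyq:
            raise ValueError(f"band {band.name} exceeds Nyquist ({nyq} Hz)")
        if epochs.epoch_length < 2.0 / band.lo:
            warnings.warn(
                f"epoch length {epochs.epoch_length:.1f} s is short for the "
                f"{band.name} band; power estimates will be coarse"
            )
    if method == "welch":
        nperseg = min(int(round(seg_seconds * epochs.fs)), epochs.n_samples)
        freqs, psd = welch(
            epochs.data, fs=epochs.fs, nperseg=nperseg, noverlap=nperseg // 2,
            window="hann", axis=2,
        )
    elif method == "periodogram":
        freqs, psd = welch(
            epochs.data, fs=epochs.fs, nperseg=epochs.n_samples,
            noverlap=0, window="boxcar", axis=2,
        )
    else:
        raise ValueError("method must be 'welch' or 'periodogram'")
    df = freqs[1] - freqs[0]
    values = np.empty((epochs.n_epochs, epochs.n_channels, len(bands)))
    for bi, band in enumerate(bands):
        mask = (freqs >= band.lo) & (freqs < band.hi + 1.0)
        values[:, :, bi] = psd[:, :, mask].sum(axis=2) * df
    return BandPowerTable(
        values, tuple(bands), epochs.labels, epochs.probe_ids,
        epochs.montage.labels, epochs.subject_id,
    )


def _band_cutoffs(band: FrequencyBand) -> tuple[float, float, float]:
    """-6 dB cutoffs widened by half a transition width on each side, so the
    integrated range [lo, hi+1) sits in the flat passband rather than on the
    filter edge."""
    trans = min(2.0, band.lo)
    lo = max(band.lo - trans / 2, 0.25)
    hi = band.hi + 1.0 + trans / 2
    return lo, hi, trans


def bandpass_raw_band(raw: RawRecording, band: FrequencyBand) -> RawRecording:
    """Filter the continuous recording to a single canonical band.

    Preferred route for CSP: filtering before epoch extraction avoids the
    edge effects of filtering short epochs.
    """
    lo, hi, trans = _band_cutoffs(band)
    return bandpass(raw, lo, hi, trans_lo=trans, trans_hi=trans)


def bandpass_per_band(epochs: EpochSet, band: FrequencyBand) -> EpochSet:
    """Filter already-cut epochs to a single band (zero-phase FIR).

    The filter order is capped so forward-backward padding fits inside one
    epoch; for 2 s epochs this costs transition sharpness, which is why the
    pipeline filters the continuous record instead whenever it is available.
    """
    lo, hi, trans = _band_cutoffs(band)
    if hi >= epochs.fs / 2:
        raise ValueError("band exceeds Nyquist")
    numtaps = int(np.ceil(3.3 * epochs.fs / trans))
    max_taps = max((epochs.n_samples - 1) // 3, 9)
    if numtaps > max_taps:
        warnings.warn(
            f"filter shortened from {numtaps} to {max_taps} taps to fit the "
            f"epoch; transition bands widen accordingly"
        )
        numtaps = max_taps
    if numtaps % 2:
        numtaps += 1
    taps = firwin(numtaps, [lo, hi], pass_zero=False,
                  fs=epochs.fs, window="hamming")
    padlen = min(3 * len(taps), epochs.n_samples - 1)
    out = filtfilt(taps, [1.0], epochs.data, axis=2, padlen=padlen)
    return epochs.with_data(out)


def per_band_epochs(
    raw: RawRecording,
    probes,
    bands: Sequence[FrequencyBand] = CANONICAL_BANDS,
    window: float = 10.0,
    sub: float = 2.0,
) -> dict[str, EpochSet]:
    """Band-filter the continuous record, then cut pre-probe epochs per band."""
    from .epoching import extract_preprobe_epochs

    return {
        band.name: extract_preprobe_epochs(
            bandpass_raw_band(raw, band), probes, window=window, sub=sub
        )
        for band in bands
    }
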