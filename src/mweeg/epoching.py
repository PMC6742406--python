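"""Epoching and artifact handling.

Two-stage artifact strategy: (1) the conditioned recording is cut into
non-overlapping 1 s epochs and epochs with extreme peak-to-peak amplitude
are dropped using a cross-validated global threshold; (2) an extended-
infomax ICA is fitted on the surviving epochs, components with extreme
skewness (|skew| > 2.50) or excess kurtosis (|kurt| > 3.00) are marked as
artifactual, and the continuous signal is re-mixed without them. Stage (2)
is bypassed in the "artifacts present" analysis variant.

Finally, the 10 s before each usable probe is cut into five 2 s epochs
labelled with that probe's response; "unsure" probes are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from mne.preprocessing import infomax
from scipy import stats as sps

from .containers import UNSURE, EpochSet, ProbeEvent, RawRecording


def epoch_fixed(raw: RawRecording, length: float = 1.0) -> EpochSet:
    """Cut the recording into floor(duration/length) non-overlapping epochs.

    Epoch k covers the half-open sample interval [k*L, (k+1)*L).
    """
    n_per = int(round(length * raw.fs))
    if n_per < 1 or n_per > raw.n_samples:
        raise ValueError("recording shorter than one epoch")
    n_ep = raw.n_samples // n_per
    data = raw.data[:, : n_ep * n_per].reshape(raw.n_channels, n_ep, n_per)
    return EpochSet(np.swapaxes(data, 0, 1).copy(), raw.fs, raw.montage)


class RejectionResult(NamedTuple):
    epochs: EpochSet
    threshold: float
    kept: np.ndarray  # integer indices into the input set


def _epoch_ptp(epochs: EpochSet) -> np.ndarray:
    """Max over channels of the within-epoch peak-to-peak amplitude."""
    return np.ptp(epochs.data, axis=2).max(axis=1)


def reject_epochs_ptp(
    epochs: EpochSet,
    threshold_grid: Sequence[float] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> RejectionResult:
    """Drop epochs whose peak-to-peak amplitude exceeds a learned threshold.

    The global threshold is chosen by cross-validated reconstruction error:
    for each candidate, the mean of the retained training epochs is compared
    (RMSE) against the pointwise median of the held-out epochs; the
    candidate minimizing the average error wins, ties going to the largest
    (most permissive) threshold.
    """
    if epochs.n_epochs < 10:
        raise ValueError("need at least 10 epochs to calibrate a threshold")
    ptp = _epoch_ptp(epochs)
    if threshold_grid is None:
        threshold_grid = np.quantile(ptp, np.linspace(0.5, 1.0, 21))
    grid = np.sort(np.asarray(threshold_grid, dtype=float))

    rng = np.random.default_rng(seed)
    order = rng.permutation(epochs.n_epochs)
    folds = np.array_split(order, cv_folds)
    scores = np.zeros(len(grid))
    for test_idx in folds:
        test_median = np.median(epochs.data[test_idx], axis=0)
        train_mask = np.ones(epochs.n_epochs, bool)
        train_mask[test_idx] = False
        for gi, thr in enumerate(grid):
            keep = train_mask & (ptp <= thr)
            if not keep.any():
                scores[gi] += np.inf
                continue
            train_mean = epochs.data[keep].mean(axis=0)
            scores[gi] += np.sqrt(np.mean((train_mean - test_median) ** 2))
    # argmin with ties broken toward the largest threshold
    best = len(grid) - 1 - int(np.argmin(scores[::-1]))
    threshold = float(grid[best])
    kept = np.flatnonzero(ptp <= threshold)
    if kept.size == 0:
        raise ValueError(f"all epochs rejected at threshold {threshold:.1f} uV")
    return RejectionResult(epochs.select(kept), threshold, kept)


def apply_ptp_threshold(epochs: EpochSet, threshold: float) -> RejectionResult:
    """Apply an already-chosen peak-to-peak threshold (no re-calibration)."""
    kept = np.flatnonzero(_epoch_ptp(epochs) <= threshold)
    if kept.size == 0:
        raise ValueError(f"all epochs rejected at threshold {threshold:.1f} uV")
    return RejectionResult(epochs.select(kept), float(threshold), kept)


@dataclass
class IcaDecomposition:
    """Linear ICA decomposition with artifact bookkeeping.

    unmixing : (k, channels) — maps centred channel data to sources
    mixing : (channels, k) — pseudo-inverse dual; columns are component maps
    sources : (k, samples) source time courses on the fit data
    rejected : indices of components marked artifactual
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    channel_mean: np.ndarray
    n_channels: int
    rejected: frozenset[int] = frozenset()
    skew_threshold: float = 2.50
    kurt_threshold: float = 3.00

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def get_sources(self, raw: RawRecording) -> np.ndarray:
        if raw.n_channels != self.n_channels:
            raise ValueError("montage mismatch: channel count differs from fit")
        return self.unmixing @ (raw.data - self.channel_mean[:, None])


def fit_ica(
    clean_epochs: EpochSet,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 200,
    max_samples: int = 50_000,
) -> IcaDecomposition:
    """Fit extended-infomax ICA on artifact-screened epochs.

    The concatenated epochs are centred and PCA-whitened; rank deficiency
    (one dimension is lost to the average reference) caps the component
    count. Components are ordered by explained channel-space variance and
    signs are fixed so each component map's largest-|weight| entry is
    positive. Long recordings are subsampled (whole epochs, seeded) to at
    most ``max_samples`` time points before fitting; for 16 channels this
    is far beyond the sample count infomax needs to converge.
    """
    epochs_data = clean_epochs.data
    n_fit = epochs_data.shape[0] * epochs_data.shape[2]
    if max_samples and n_fit > max_samples:
        n_keep = max(max_samples // epochs_data.shape[2], 2)
        idx = np.sort(
            np.random.default_rng(seed).choice(
                epochs_data.shape[0], n_keep, replace=False
            )
        )
        epochs_data = epochs_data[idx]
    x = np.hstack(epochs_data)  # (channels, epochs*samples)
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    cov = (xc @ xc.T) / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-10))
    k = min(n_components or x.shape[0], rank)
    if k < (n_components or x.shape[0]):
        warnings.warn(
            f"data rank {rank} < requested components; fitting {k} components"
        )
    whitener = (evecs[:, :k] / np.sqrt(evals[:k])).T  # (k, channels)
    xw = whitener @ xc

    w = infomax(xw.T, extended=True, rng=seed, max_iter=max_iter)
    unmixing = w @ whitener  # (k, channels)
    mixing = np.linalg.pinv(unmixing)  # (channels, k)
    sources = unmixing @ xc

    # order by reconstructed channel-space variance, fix sign convention
    expl = np.sum(mixing**2, axis=0) * np.var(sources, axis=1)
    order = np.argsort(expl)[::-1]
    unmixing, mixing, sources = unmixing[order], mixing[:, order], sources[order]
    for i in range(k):
        j = int(np.argmax(np.abs(mixing[:, i])))
        if mixing[j, i] < 0:
            mixing[:, i] *= -1
            unmixing[i] *= -1
            sources[i] *= -1

    return IcaDecomposition(
        unmixing=unmixing,
        mixing=mixing,
        sources=sources,
        channel_mean=mean,
        n_channels=x.shape[0],
    )


def reject_components_stats(ica: IcaDecomposition) -> IcaDecomposition:
    """Mark components with extreme source statistics as artifactual.

    A component is rejected when |skewness| strictly exceeds the skewness
    threshold (2.50) or |excess kurtosis| strictly exceeds the kurtosis
    threshold (3.00). Excess (Fisher) kurtosis is used: a Gaussian source
    scores 0, making the symmetric threshold meaningful.
    """
    skew = sps.skew(ica.sources, axis=1)
    kurt = sps.kurtosis(ica.sources, axis=1, fisher=True)
    rejected = frozenset(
        int(i)
        for i in range(ica.n_components)
        if abs(skew[i]) > ica.skew_threshold or abs(kurt[i]) > ica.kurt_threshold
    )
    return replace(ica, rejected=rejected)


def remix_without_rejected(raw: RawRecording, ica: IcaDecomposition) -> RawRecording:
    """Reconstruct channel space from the retained components only."""
    if raw.n_channels != ica.n_channels:
        raise ValueError("montage mismatch: channel count differs from ICA fit")
    sources = ica.get_sources(raw)
    keep = np.array(
        [i for i in range(ica.n_components) if i not in ica.rejected], dtype=int
    )
    recon = ica.mixing[:, keep] @ sources[keep] + ica.channel_mean[:, None]
    return raw.with_data(recon)


def extract_preprobe_epochs(
    raw: RawRecording,
    probes: Sequence[ProbeEvent],
    window: float = 10.0,
    sub: float = 2.0,
) -> EpochSet:
    """Cut the ``window`` seconds before each usable probe into ``window/sub``
    consecutive labelled epochs.

    The window is (onset - window, onset], half-open at the left; "unsure"
    probes are ignored and probes with insufficient history are skipped with
    a warning. All epochs from one probe share its probe_id and label.
    """
    n_sub = int(round(window / sub))
    n_per = int(round(sub * raw.fs))
    data, labels, probe_ids = [], [], []
    for probe in probes:
        if probe.response == UNSURE:
            continue
        if probe.onset - raw.start_time < window:
            warnings.warn(
                f"probe {probe.probe_id} at {probe.onset:.1f} s has less than "
                f"{window:.0f} s of history; skipped"
            )
            continue
        end = int(np.floor((probe.onset - raw.start_time) * raw.fs))
        start = end - n_sub * n_per
        if start < 0 or end > raw.n_samples:
            warnings.warn(f"probe {probe.probe_id} outside recording; skipped")
            continue
        seg = raw.data[:, start:end].reshape(raw.n_channels, n_sub, n_per)
        data.append(np.swapaxes(seg, 0, 1))
        labels.extend([probe.response] * n_sub)
        probe_ids.extend([probe.probe_id] * n_sub)
    if not data:
        raise ValueError("no usable MW/NOT_MW probes with sufficient history")
    return EpochSet(
        np.concatenate(data),
        raw.fs,
        raw.montage,
        np.array(labels, dtype=object),
        np.array(probe_ids, dtype=int),
    )
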