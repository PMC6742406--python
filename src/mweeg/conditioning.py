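"""Continuous-signal conditioning.

Order used by the pipeline: bad-channel removal (extreme variance), common
average re-reference, exponential running mean/variance standardization
(smoothness alpha = 0.001), then a 1-30 Hz linear-phase FIR bandpass applied
zero-phase. The standardization tames slow drifts and high-voltage excursions
before filtering; the bandpass restricts analysis to the theta-beta range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin, lfilter

from .containers import RawRecording


def detect_bad_channels(raw: RawRecording, z_threshold: float = 5.0) -> list[str]:
    """Flag channels with extreme variance.

    A channel is flagged when the robust z-score (median/MAD across channels)
    of its log-variance exceeds ``z_threshold`` in absolute value.
    """
    if raw.n_channels < 4:
        raise ValueError("need at least 4 channels for robust statistics")
    logvar = np.log(np.var(raw.data, axis=1) + np.finfo(float).tiny)
    med = np.median(logvar)
    mad = np.median(np.abs(logvar - med))
    scale = 1.4826 * mad
    if scale == 0:
        return []
    z = (logvar - med) / scale
    flagged = [
        raw.montage.labels[i] for i in range(raw.n_channels)
        if abs(z[i]) > z_threshold
    ]
    if len(flagged) == raw.n_channels:
        raise ValueError("all channels flagged as bad; montage unusable")
    return flagged


def rereference_average(raw: RawRecording) -> RawRecording:
    """Subtract the instantaneous mean across channels (common average)."""
    if raw.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return raw.with_data(raw.data - raw.data.mean(axis=0, keepdims=True))


@dataclass
class EwmState:
    """State of the exponential running mean/variance standardizer.

    alpha is the smoothness factor: small alpha means long memory. The
    recursion (mean updated *before* the output is formed) is
        mu_t = (1 - alpha) * mu_{t-1} + alpha * x_t
        v_t  = (1 - alpha) * v_{t-1} + alpha * (x_t - mu_t)^2
        y_t  = (x_t - mu_t) / sqrt(max(v_t, var_floor))
    """

    alpha: float = 0.001
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None
    var_floor: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.var_floor <= 0:
            raise ValueError("var_floor must be positive")


def ewm_standardize(raw: RawRecording, state: EwmState | None = None) -> RawRecording:
    """Standardize each channel by its exponential running mean and variance.

    Initialization: mu_0 = first sample; v_0 = sample variance of the first
    10 s (fallback 1.0 if degenerate). The recursions are first-order IIR
    filters and are evaluated with ``scipy.signal.lfilter``.
    """
    state = state or EwmState()
    a = state.alpha
    x = raw.data
    n_burn = min(x.shape[1], int(round(10 * raw.fs)))
    mu0 = (
        state.running_mean
        if state.running_mean is not None
        else x[:, 0].copy()
    )
    if state.running_var is not None:
        v0 = state.running_var
    else:
        v0 = np.var(x[:, :n_burn], axis=1)
        v0 = np.where(v0 > 0, v0, 1.0)

    # mu_t = a*x_t + (1-a)*mu_{t-1}  ->  IIR b=[a], a=[1, -(1-a)]
    b, acoef = np.array([a]), np.array([1.0, -(1.0 - a)])
    zi_mu = ((1.0 - a) * mu0)[:, None]
    mu, zf = lfilter(b, acoef, x, axis=1, zi=zi_mu)
    dev2 = (x - mu) ** 2
    zi_v = ((1.0 - a) * v0)[:, None]
    v, _ = lfilter(b, acoef, dev2, axis=1, zi=zi_v)
    out = (x - mu) / np.sqrt(np.maximum(v, state.var_floor))
    state.running_mean = mu[:, -1]
    state.running_var = v[:, -1]
    return raw.with_data(out)


def design_fir_bandpass(
    fs: float,
    lo: float = 1.0,
    hi: float = 30.0,
    trans_lo: float = 1.0,
    trans_hi: float = 5.0,
) -> np.ndarray:
    """Design an even-length (Type II) linear-phase FIR bandpass.

    The tap count is auto-selected from the narrower transition width using
    the Hamming-window rule (~3.3 * fs / transition), rounded up to an even
    number. An even-symmetric filter has a structural zero at Nyquist, which
    is in the stopband for any bandpass below fs/2.
    """
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {nyq} Hz")
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    trans = min(trans_lo, trans_hi)
    numtaps = int(np.ceil(3.3 * fs / trans))
    if numtaps % 2:
        numtaps += 1
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def bandpass(
    raw: RawRecording,
    lo: float = 1.0,
    hi: float = 30.0,
    trans_lo: float = 1.0,
    trans_hi: float = 5.0,
) -> RawRecording:
    """Zero-phase FIR bandpass of the continuous recording.

    The filter is applied forward-backward (``filtfilt``) so epoch timing is
    not delayed relative to probe onsets; the effective magnitude response is
    the squared one-pass response.
    """
    taps = design_fir_bandpass(raw.fs, lo, hi, trans_lo, trans_hi)
    padlen = min(3 * len(taps), raw.n_samples - 1)
    if padlen < len(taps):
        warnings.warn("recording short relative to filter; edge effects likely")
    out = filtfilt(taps, [1.0], raw.data, axis=1, padlen=padlen)
    return raw.with_data(out)


def condition(
    raw: RawRecording,
    bad_z: float = 5.0,
    alpha: float = 0.001,
    band: tuple[float, float] = (1.0, 30.0),
) -> tuple[RawRecording, list[str]]:
    """Full conditioning chain; returns the cleaned recording and the
    labels of removed channels."""
    bad = detect_bad_channels(raw, bad_z)
    if bad:
        raw = raw.drop_channels(bad)
    raw = rereference_average(raw)
    raw = ewm_standardize(raw, EwmState(alpha=alpha))
    raw = bandpass(raw, band[0], band[1])
    return raw, bad
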