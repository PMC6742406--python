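"""Synthetic probe-based lecture EEG with known ground truth.

The generator is a forward source-mixing model: band-limited Gaussian
sources are projected to 16 scalp channels through smooth topographies,
blink-like transients are added with a frontal-dominant weighting, and white
sensor noise completes the signal. During the 10 s preceding a probe whose
(simulated) response is "mind wandering", designated sources have their
power multiplied by a class effect factor — so every downstream stage has a
parameter-recovery target: the effect band, the effect topography, and the
probe labels are all known exactly.

Defaults emulate a ~52 min lecture session: 13 probes at 240 s spacing,
P(MW) = 0.35, P(unsure) = 0.04, one alpha-band source carrying a 2x power
effect, blinks at 10/min and 120 uV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import firwin, lfilter

from .containers import (
    MW,
    NOT_MW,
    UNSURE,
    DEFAULT_LABELS,
    Montage,
    ProbeEvent,
    RawRecording,
    default_montage,
)

#: source band layout: two sources per canonical band (theta, alpha, beta1, beta2)
_DEFAULT_SOURCE_BANDS = (
    (4.0, 7.0), (8.0, 12.0), (13.0, 18.0), (19.0, 30.0),
    (4.0, 7.0), (8.0, 12.0), (13.0, 18.0), (19.0, 30.0),
)


def _default_class_effect() -> np.ndarray:
    # one alpha-band source (index 1) carries a 2x power effect during MW
    eff = np.ones(len(_DEFAULT_SOURCE_BANDS))
    eff[1] = 2.0
    return eff


def _default_blink_topography(montage: Montage) -> np.ndarray:
    # frontal-dominant weights decaying with distance from a point above Fpz
    pos = montage.positions
    d2 = (pos[:, 0] ** 2 + (pos[:, 1] - 1.15) ** 2)
    return np.exp(-d2 / 0.5)


@dataclass
class SyntheticConfig:
    """Parameters of the forward model. Seed + config fully determine output."""

    n_channels: int = 16
    fs: float = 250.0
    montage_labels: tuple[str, ...] = DEFAULT_LABELS
    n_sources: int = 8
    mixing: np.ndarray | None = None  # (channels, sources); random if None
    source_bands: tuple[tuple[float, float], ...] = _DEFAULT_SOURCE_BANDS
    class_effect: np.ndarray = field(default_factory=_default_class_effect)
    source_amplitude: float = 20.0  # uV RMS per source at the scalp
    n_probes: int = 13
    probe_spacing: float = 240.0  # s
    duration: float | None = None  # s; n_probes * spacing + 10 if None
    p_mw: float = 0.35
    p_unsure: float = 0.04
    blink_rate: float = 10.0  # events/min
    blink_amplitude: float = 120.0  # uV
    blink_topography: np.ndarray | None = None  # frontal-dominant if None
    noise_sd: float = 5.0  # uV white sensor noise
    effect_window: float = 10.0  # s before each probe where the effect acts
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_effect = np.asarray(self.class_effect, dtype=float)
        if len(self.source_bands) != self.n_sources:
            raise ValueError("source_bands length must equal n_sources")
        if self.class_effect.shape != (self.n_sources,):
            raise ValueError("class_effect must have one factor per source")
        if np.any(self.class_effect <= 0):
            raise ValueError("class_effect factors must be strictly positive")
        if not 0 <= self.p_mw <= 1 or not 0 <= self.p_unsure <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.p_mw + self.p_unsure > 1:
            raise ValueError("p_mw + p_unsure must not exceed 1")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.shape != (self.n_channels, self.n_sources):
                raise ValueError("mixing must be (n_channels, n_sources)")
            if np.linalg.matrix_rank(self.mixing) < self.n_sources:
                raise ValueError("mixing must have full column rank")
        for lo, hi in self.source_bands:
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(f"band ({lo}, {hi}) invalid for fs={self.fs}")

    @property
    def session_duration(self) -> float:
        return (
            self.duration
            if self.duration is not None
            else self.n_probes * self.probe_spacing + self.effect_window
        )

    @property
    def effect_sources(self) -> np.ndarray:
        return np.flatnonzero(self.class_effect != 1.0)

    def montage(self) -> Montage:
        return default_montage(self.montage_labels)


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    probe_onsets: np.ndarray  # s
    probe_responses: list[str]  # MW / NOT_MW / UNSURE per probe
    mixing_used: np.ndarray  # (channels, sources)
    effect_sources: np.ndarray  # indices of sources carrying class effects
    blink_timecourse: np.ndarray | None = None  # (n_samples,) scalar artifact
    blink_topography: np.ndarray | None = None  # (n_channels,)

    def probes(self) -> list[ProbeEvent]:
        return [
            ProbeEvent(float(t), r, i)
            for i, (t, r) in enumerate(zip(self.probe_onsets, self.probe_responses))
        ]


def _random_topography(rng: np.random.Generator, montage: Montage) -> np.ndarray:
    """Smooth signed scalp map: Gaussian bump at a random site, unit norm."""
    pos = montage.positions
    center = rng.uniform(-1.0, 1.0, size=2)
    width = rng.uniform(0.3, 0.6)
    w = np.exp(-np.sum((pos - center) ** 2, axis=1) / (2 * width**2))
    w *= rng.choice([-1.0, 1.0])
    return w / np.linalg.norm(w)


def _make_mixing(
    rng: np.random.Generator, montage: Montage, n_sources: int
) -> np.ndarray:
    for _ in range(50):
        cols = [_random_topography(rng, montage) for _ in range(n_sources)]
        mixing = np.column_stack(cols)
        # reject near-collinear draws so the forward model is identifiable
        if np.linalg.matrix_rank(mixing, tol=1e-6) == n_sources and (
            np.linalg.cond(mixing) < 1e3
        ):
            return mixing
    raise RuntimeError("could not draw a well-conditioned mixing matrix")


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi] Hz."""
    trans = max(min(lo, 2.0), 0.5)
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # odd Type I taps
    taps = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")
    x = lfilter(taps, [1.0], rng.standard_normal(n + numtaps))[numtaps:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _effect_gain(
    n_samples: int,
    fs: float,
    onsets: np.ndarray,
    responses: list[str],
    window: float,
    factor: float,
    ramp: float = 0.2,
) -> np.ndarray:
    """Amplitude gain profile: sqrt(factor) inside MW pre-probe windows,
    with short cosine ramps to avoid broadband switching transients."""
    gain = np.ones(n_samples)
    amp = np.sqrt(factor)
    n_ramp = max(int(round(ramp * fs)), 1)
    half = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n_ramp)))
    for t, resp in zip(onsets, responses):
        if resp != MW:
            continue
        i0 = max(int(np.floor((t - window) * fs)), 0)
        i1 = min(int(np.floor(t * fs)), n_samples)
        if i1 <= i0:
            continue
        gain[i0:i1] = amp
        up0 = max(i0 - n_ramp, 0)
        if i0 > up0:
            gain[up0:i0] = 1 + (amp - 1) * half[-(i0 - up0):]
        dn1 = min(i1 + n_ramp, n_samples)
        if dn1 > i1:
            gain[i1:dn1] = amp + (1 - amp) * half[: dn1 - i1]
    return gain


def inject_blinks(
    raw: RawRecording,
    rate: float,
    amplitude: float,
    topography: np.ndarray,
    seed: int,
) -> tuple[RawRecording, np.ndarray]:
    """Add blink-like transients (half-sine bursts, 200-400 ms).

    Returns the contaminated recording and the scalar artifact time course
    s(t); the injected channel-space artifact is ``outer(topography, s)``,
    so the original signal is recoverable by subtraction.
    """
    if rate < 0 or amplitude < 0:
        raise ValueError("rate and amplitude must be non-negative")
    topography = np.asarray(topography, dtype=float)
    if topography.shape != (raw.n_channels,):
        raise ValueError("topography length must equal channel count")
    s = np.zeros(raw.n_samples)
    if rate > 0 and amplitude > 0:
        rng = np.random.default_rng(seed)
        n_events = rng.poisson(rate * raw.duration / 60.0)
        for _ in range(n_events):
            width = rng.uniform(0.2, 0.4)
            t0 = rng.uniform(0, raw.duration - width)
            i0 = int(t0 * raw.fs)
            n = int(width * raw.fs)
            s[i0 : i0 + n] += (
                amplitude * rng.uniform(0.8, 1.2) * np.sin(np.pi * np.arange(n) / n)
            )
    return raw.with_data(raw.data + np.outer(topography, s)), s


def generate_session(config: SyntheticConfig) -> tuple[RawRecording, GroundTruth]:
    """Simulate one probe-based lecture session.

    Signal model: x(t) = A s(t) + b(t) + n(t), with A the mixing matrix,
    s band-limited Gaussian sources (effect sources amplitude-modulated in
    MW pre-probe windows), b the blink artifact, n white sensor noise.
    """
    montage = config.montage()
    duration = config.session_duration
    if config.n_probes * config.probe_spacing > duration:
        raise ValueError(
            f"session of {duration:.0f} s too short for {config.n_probes} "
            f"probes every {config.probe_spacing:.0f} s"
        )
    n_samples = int(round(duration * config.fs))

    ss = np.random.SeedSequence(config.seed)
    rng_mix, rng_src, rng_lab, rng_noise, seed_blink = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ] + [int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)]

    mixing = (
        config.mixing
        if config.mixing is not None
        else _make_mixing(rng_mix, montage, config.n_sources)
    )

    onsets = config.probe_spacing * np.arange(1, config.n_probes + 1)
    responses = [
        str(
            rng_lab.choice(
                [MW, UNSURE, NOT_MW],
                p=[config.p_mw, config.p_unsure, 1 - config.p_mw - config.p_unsure],
            )
        )
        for _ in range(config.n_probes)
    ]

    sources = np.empty((config.n_sources, n_samples))
    for i, (lo, hi) in enumerate(config.source_bands):
        src = _band_limited_noise(rng_src, n_samples, config.fs, lo, hi)
        if config.class_effect[i] != 1.0:
            src = src * _effect_gain(
                n_samples,
                config.fs,
                onsets,
                responses,
                config.effect_window,
                config.class_effect[i],
            )
        sources[i] = src

    data = config.source_amplitude * (mixing @ sources)
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng_noise.standard_normal(data.shape)
    raw = RawRecording(data, config.fs, montage)

    topo = (
        np.asarray(config.blink_topography, dtype=float)
        if config.blink_topography is not None
        else _default_blink_topography(montage)
    )
    raw, blink_tc = inject_blinks(
        raw, config.blink_rate, config.blink_amplitude, topo, seed_blink
    )

    truth = GroundTruth(
        probe_onsets=onsets,
        probe_responses=responses,
        mixing_used=mixing,
        effect_sources=config.effect_sources,
        blink_timecourse=blink_tc if config.blink_rate > 0 else None,
        blink_topography=topo if config.blink_rate > 0 else None,
    )
    return raw, truth


def generate_cohort(
    base: SyntheticConfig,
    n_subjects: int,
    individualize: bool = True,
    seed: int = 0,
) -> list[tuple[RawRecording, GroundTruth]]:
    """Simulate a cohort sharing session structure.

    individualize=True gives each subject an independently drawn effect
    topography and effect band (the regime where patterns do not transfer
    across subjects); individualize=False plants the same effect topography
    in every subject (the regime where a leave-one-subject-out model works).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_subjects == 1:
        return [generate_session(base)]  # degenerate cohort
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    montage = default_montage(base.montage_labels)

    shared_mixing = base.mixing
    if not individualize and shared_mixing is None:
        shared_mixing = _make_mixing(
            np.random.default_rng(np.random.SeedSequence(base.seed)),
            montage,
            base.n_sources,
        )

    effect_magnitude = (
        float(base.class_effect[base.effect_sources[0]])
        if len(base.effect_sources)
        else 1.0
    )
    band_cycle = list(dict.fromkeys(base.source_bands))  # unique bands, in order

    out = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % 2**31)
        cfg = dataclasses.replace(base, seed=sub_seed)
        if individualize and len(base.effect_sources):
            rng = np.random.default_rng(child.spawn(1)[0])
            band = band_cycle[rng.integers(len(band_cycle))]
            src_idx = next(
                i for i, b in enumerate(base.source_bands) if b == band
            )
            effect = np.ones(base.n_sources)
            effect[src_idx] = effect_magnitude
            mixing = _make_mixing(rng, montage, base.n_sources)
            cfg = dataclasses.replace(cfg, class_effect=effect, mixing=mixing)
        elif not individualize:
            cfg = dataclasses.replace(cfg, mixing=shared_mixing)
        raw, truth = generate_session(cfg)
        out.append((raw, truth))
    return out
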