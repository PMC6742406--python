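"""End-to-end orchestration of the per-subject and cohort analyses.

Stage order is fixed and asserted: conditioning -> 1 s epoching ->
peak-to-peak epoch rejection -> (artifacts-suppressed variant only:
ICA fit on the surviving epochs, statistical component rejection, remix)
-> per-band filtering of the continuous record -> pre-probe epoch
extraction and labelling -> per-band CSP+SVM cross-validation ->
best-band selection -> permutation chance calibration -> comparison to
chance -> band-power repeated-measures ANOVA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .conditioning import condition
from .containers import ProbeEvent, RawRecording
from .detection import (
    DetectionResult,
    NullDistribution,
    compare_to_chance,
    intra_subject_cv,
    inter_subject_loso,
    permutation_null,
    rate_agreement,
    select_best_band,
)
from .epoching import (
    apply_ptp_threshold,
    epoch_fixed,
    extract_preprobe_epochs,
    fit_ica,
    reject_components_stats,
    reject_epochs_ptp,
    remix_without_rejected,
)
from .spectral import CANONICAL_BANDS, band_power, per_band_epochs
from .stats import AnovaTable, aggregate_cell_means, rm_anova_2x4

VARIANTS = ("suppressed", "present")

_KNOWN_KEYS = {
    "variant", "bands", "ewm_alpha", "bad_channel_z", "skew_threshold",
    "kurt_threshold", "csp_components", "csp_shrinkage", "svm_c",
    "cv_folds", "n_permutations", "preprobe_window", "preprobe_sub",
    "scan_epoch_length", "seed",
}


@dataclass
class RunConfig:
    """All analysis knobs; serialized verbatim into every report."""

    variant: str = "suppressed"
    bands: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
    ewm_alpha: float = 0.001
    bad_channel_z: float = 5.0
    skew_threshold: float = 2.50
    kurt_threshold: float = 3.00
    csp_components: int = 6
    csp_shrinkage: float = 0.0
    svm_c: float = 1.0
    cv_folds: int = 5
    n_permutations: int = 100
    preprobe_window: float = 10.0
    preprobe_sub: float = 2.0
    scan_epoch_length: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in d:
            d = {**d, "bands": tuple(d["bands"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = list(d["bands"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SubjectReport:
    """Everything one subject's run produces."""

    subject_id: str
    per_band: dict[str, DetectionResult]
    best: DetectionResult
    null: NullDistribution
    t_vs_chance: float
    p_vs_chance: float
    anova: AnovaTable
    bad_channels: list[str]
    ptp_threshold: float
    n_rejected_components: int
    provenance: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        b = self.best
        return {
            "subject": self.subject_id,
            "best_band": b.band,
            "accuracy": b.mean("accuracy"),
            "accuracy_se": b.se("accuracy"),
            "f1": b.mean("f1"),
            "f1_se": b.se("f1"),
            "recall": b.mean("recall"),
            "precision": b.mean("precision"),
            "observed_mw_rate": b.observed_mw_rate,
            "predicted_mw_rate": b.predicted_mw_rate,
            "n_epochs": b.n_epochs,
            "chance_ci_low": self.null.ci95[0],
            "chance_ci_high": self.null.ci95[1],
            "p_vs_chance": self.p_vs_chance,
        }


def _subject_seeds(seed: int, n: int) -> list[int]:
    """Fan a master seed out into per-use seeds (all below 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def preprocess_subject(
    config: RunConfig, raw: RawRecording
) -> tuple[RawRecording, list[str], float, int]:
    """Conditioning plus the two-stage artifact handling.

    Returns the cleaned continuous recording, removed channel labels, the
    learned peak-to-peak threshold, and the number of rejected ICA
    components (0 in the artifacts-present variant).
    """
    seeds = _subject_seeds(config.seed, 2)
    cleaned, bad = condition(
        raw, bad_z=config.bad_channel_z, alpha=config.ewm_alpha
    )
    scan = epoch_fixed(cleaned, config.scan_epoch_length)
    rejection = reject_epochs_ptp(scan, seed=seeds[0])
    n_rejected_components = 0
    if config.variant == "suppressed":
        # pipeline-order invariant: epoch rejection precedes ICA fitting
        ica = fit_ica(rejection.epochs, seed=seeds[1])
        ica = reject_components_stats(ica)
        n_rejected_components = len(ica.rejected)
        cleaned = remix_without_rejected(cleaned, ica)
    return cleaned, bad, rejection.threshold, n_rejected_components


def run_subject(
    config: RunConfig,
    raw: RawRecording,
    probes: Sequence[ProbeEvent],
    subject_id: str = "S0",
) -> SubjectReport:
    """Full per-subject analysis; deterministic under config.seed."""
    seeds = _subject_seeds(config.seed + 1, 3)
    cleaned, bad, ptp_thr, n_rej = preprocess_subject(config, raw)

    bands = [b for b in CANONICAL_BANDS if b.name in config.bands]
    band_eps = per_band_epochs(
        cleaned, probes, bands,
        window=config.preprobe_window, sub=config.preprobe_sub,
    )
    broadband = extract_preprobe_epochs(
        cleaned, probes, window=config.preprobe_window, sub=config.preprobe_sub
    )
    # apply the learned amplitude threshold to the pre-probe epochs too
    kept = apply_ptp_threshold(broadband, ptp_thr).kept
    broadband = broadband.select(kept)
    band_eps = {name: ep.select(kept) for name, ep in band_eps.items()}
    for ep in band_eps.values():
        ep.subject_id = subject_id
    broadband.subject_id = subject_id

    per_band = intra_subject_cv(
        band_eps,
        k=config.cv_folds,
        seed=seeds[0],
        n_components=config.csp_components,
        shrinkage=config.csp_shrinkage,
        svm_c=config.svm_c,
        variant=config.variant,
    )
    best = select_best_band(per_band)
    null = permutation_null(
        band_eps[best.band],
        band=next(b for b in bands if b.name == best.band),
        n=config.n_permutations,
        k=config.cv_folds,
        seed=seeds[1],
        n_components=config.csp_components,
        shrinkage=config.csp_shrinkage,
        svm_c=config.svm_c,
    )
    t, p = compare_to_chance([f["f1"] for f in best.per_fold], null)

    powers = band_power(broadband, bands)
    powers.subject_id = subject_id
    cells = aggregate_cell_means(powers, "channel")
    anova = rm_anova_2x4(cells, model_name=subject_id)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "subject": subject_id,
        "ica": {
            "applied": config.variant == "suppressed",
            "n_rejected_components": n_rej,
        },
    }
    return SubjectReport(
        subject_id=subject_id,
        per_band=per_band,
        best=best,
        null=null,
        t_vs_chance=t,
        p_vs_chance=p,
        anova=anova,
        bad_channels=bad,
        ptp_threshold=ptp_thr,
        n_rejected_components=n_rej,
        provenance=provenance,
    )


@dataclass
class CohortReport:
    subjects: list[SubjectReport]
    table: pd.DataFrame  # per-subject rows + average row
    loso: list[DetectionResult]
    loso_mean_f1: float
    pearson_r_obs_pred: float
    spearman_rho_epochs_f1: float
    provenance: dict


def run_cohort(
    config: RunConfig,
    sessions: Sequence[tuple[RawRecording, Sequence[ProbeEvent]]],
    loso_band: str = "alpha",
) -> CohortReport:
    """Per-subject runs plus leave-one-subject-out transfer and the
    cross-subject agreement summaries."""
    if len(sessions) < 2:
        raise ValueError("need at least 2 subjects")
    reports = []
    loso_inputs = []
    for i, (raw, probes) in enumerate(sessions):
        sid = f"P{i + 1}"
        cfg = dataclasses.replace(config, seed=config.seed + i)
        rep = run_subject(cfg, raw, probes, subject_id=sid)
        reports.append(rep)

        cleaned, _, ptp_thr, _ = preprocess_subject(cfg, raw)
        eps = per_band_epochs(
            cleaned, probes,
            [b for b in CANONICAL_BANDS if b.name == loso_band],
            window=config.preprobe_window, sub=config.preprobe_sub,
        )[loso_band]
        eps = eps.select(apply_ptp_threshold(eps, ptp_thr).kept)
        eps.subject_id = sid
        loso_inputs.append(eps)

    rows = [r.to_row() for r in reports]
    df = pd.DataFrame(rows)
    avg = df.drop(columns=["subject", "best_band"]).mean(numeric_only=True)
    avg_row = {"subject": "Average", "best_band": "", **avg.to_dict()}
    table = pd.concat([df, pd.DataFrame([avg_row])], ignore_index=True)

    loso = (
        inter_subject_loso(
            loso_inputs, band=loso_band,
            n_components=config.csp_components,
            shrinkage=config.csp_shrinkage, svm_c=config.svm_c,
            variant=config.variant,
        )
        if len(loso_inputs) >= 3
        else []
    )
    loso_mean = float(np.mean([r.mean_f1 for r in loso])) if loso else float("nan")

    try:
        r, rho = rate_agreement([rep.best for rep in reports])
    except ValueError as err:
        warnings.warn(f"rate agreement undefined: {err}")
        r, rho = float("nan"), float("nan")

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_subjects": len(sessions),
        "loso_band": loso_band,
    }
    return CohortReport(
        subjects=reports,
        table=table,
        loso=loso,
        loso_mean_f1=loso_mean,
        pearson_r_obs_pred=r,
        spearman_rho_epochs_f1=rho,
        provenance=provenance,
    )
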