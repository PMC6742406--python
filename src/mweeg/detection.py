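"""Classification and chance calibration.

Per band: CSP features -> RBF support vector machine, evaluated with
probe-grouped 5-fold cross-validation (all five epochs of a probe stay in
one fold, so the classifier is never tested on epochs adjacent to its
training data). Inter-subject transfer uses leave-one-subject-out CV.
Chance level is calibrated per subject by re-running the full CSP+SVM CV
on label permutations (shuffled at the probe level) and taking the
empirical 95% interval of the resulting F1 scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import pairwise_distances
from sklearn.svm import SVC

from .containers import MW, NOT_MW, EpochSet, concatenate_epochs
from .csp import csp_features, fit_csp
from .spectral import CANONICAL_BANDS, FrequencyBand

#: canonical order used for best-band tie-breaks
BAND_ORDER = tuple(b.name for b in CANONICAL_BANDS)


@dataclass(frozen=True)
class FoldAssignment:
    """Probe-level fold assignment: every epoch of a probe shares its fold."""

    fold_of_probe: dict[int, int]
    k: int
    seed: int

    def fold_of_epochs(self, probe_ids: np.ndarray) -> np.ndarray:
        return np.array([self.fold_of_probe[int(p)] for p in probe_ids])


@dataclass
class DetectionResult:
    """One row of the per-subject performance table.

    accuracy is in percent; precision/recall/F1 are for the MW (positive)
    class; means and standard errors are taken across CV folds.
    """

    band: str
    per_fold: list[dict[str, float]]
    predicted_mw_rate: float
    observed_mw_rate: float
    n_epochs: int
    subject_id: str = "S0"
    variant: str = "present"

    def _vals(self, key: str) -> np.ndarray:
        return np.array([f[key] for f in self.per_fold])

    def mean(self, key: str) -> float:
        return float(self._vals(key).mean())

    def se(self, key: str) -> float:
        v = self._vals(key)
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return self.mean("f1")


@dataclass
class NullDistribution:
    """Permutation F1 samples defining the chance band."""

    f1_samples: np.ndarray
    ci95: tuple[float, float]
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        self.f1_samples = np.asarray(self.f1_samples, dtype=float)
        if self.f1_samples.shape != (self.n_iterations,):
            raise ValueError("sample count must equal n_iterations")
        lo, hi = self.ci95
        if not (0 <= lo <= hi <= 1):
            raise ValueError("ci95 must be ordered and within [0, 1]")

    def contains(self, f1: float) -> bool:
        return self.ci95[0] <= f1 <= self.ci95[1]


def compute_metrics(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> dict[str, float]:
    """Accuracy (percent), precision, recall and F1 with MW positive.

    Zero-denominator precision/recall/F1 are defined as 0.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = float(np.sum((y_true == MW) & (y_pred == MW)))
    fp = float(np.sum((y_true == NOT_MW) & (y_pred == MW)))
    fn = float(np.sum((y_true == MW) & (y_pred == NOT_MW)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    accuracy = 100.0 * float(np.mean(y_true == y_pred))
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def make_grouped_folds(
    probe_ids: Sequence[int],
    probe_labels: Mapping[int, str],
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Assign probes to k folds, label-stratified where counts permit."""
    unique = sorted(set(int(p) for p in probe_ids))
    if len(unique) < k:
        raise ValueError(f"need at least {k} probes for {k} folds")
    rng = np.random.default_rng(seed)
    fold_of_probe: dict[int, int] = {}
    offset = 0
    for cls in (MW, NOT_MW):
        members = [p for p in unique if probe_labels[p] == cls]
        if 0 < len(members) < k:
            warnings.warn(
                f"only {len(members)} {cls} probes for {k} folds; "
                "stratification is best-effort"
            )
        rng.shuffle(members)
        # round-robin deal, rotating the starting fold between classes so
        # leftovers do not pile into fold 0
        for i, p in enumerate(members):
            fold_of_probe[p] = (i + offset) % k
        offset += len(members)
    return FoldAssignment(fold_of_probe, k, seed)


def _median_heuristic_gamma(features: np.ndarray) -> float:
    d = pairwise_distances(features)
    med = np.median(d[np.triu_indices_from(d, k=1)]) if len(features) > 1 else 0.0
    return 1.0 / (2 * med**2) if med > 0 else 1.0 / features.shape[1]


def train_eval_fold(
    train: EpochSet,
    test: EpochSet,
    band: FrequencyBand | None = None,
    n_components: int = 6,
    shrinkage: float = 0.0,
    svm_c: float = 1.0,
) -> tuple[dict[str, float], np.ndarray]:
    """Fit CSP+SVM on the training fold only; evaluate on the test fold.

    The CSP model never sees test epochs (the leakage guard of the whole
    evaluation); the RBF width is the median heuristic on training features.
    """
    classes = set(train.labels.tolist())
    if len(classes) < 2:
        raise ValueError("single-class training fold")
    model = fit_csp(train, n_components=min(n_components, train.n_channels),
                    shrinkage=shrinkage, band=band)
    f_train = csp_features(model, train)
    f_test = csp_features(model, test)
    gamma = _median_heuristic_gamma(f_train)
    clf = SVC(kernel="rbf", C=svm_c, gamma=gamma)
    clf.fit(f_train, train.labels.astype(str))
    y_pred = clf.predict(f_test).astype(object)
    return compute_metrics(test.labels, y_pred), y_pred


def _probe_label_map(epochs: EpochSet) -> dict[int, str]:
    out: dict[int, str] = {}
    for pid, lab in zip(epochs.probe_ids, epochs.labels):
        prev = out.setdefault(int(pid), str(lab))
        if prev != lab:
            raise ValueError(f"probe {pid} carries conflicting labels")
    return out


def _run_cv(
    epochs: EpochSet,
    folds: FoldAssignment,
    band: FrequencyBand | None,
    n_components: int,
    shrinkage: float,
    svm_c: float,
) -> tuple[list[dict[str, float]], float]:
    """All folds of one CV; returns per-fold metrics and the pooled
    predicted MW rate."""
    fold_idx = folds.fold_of_epochs(epochs.probe_ids)
    per_fold, n_mw_pred, n_pred = [], 0, 0
    for f in range(folds.k):
        test_mask = fold_idx == f
        if not test_mask.any():
            continue
        train = epochs.select(~test_mask)
        test = epochs.select(test_mask)
        if len(set(train.labels.tolist())) < 2:
            warnings.warn(f"fold {f} skipped: single-class training data")
            continue
        metrics, y_pred = train_eval_fold(
            train, test, band, n_components, shrinkage, svm_c
        )
        per_fold.append(metrics)
        n_mw_pred += int(np.sum(y_pred == MW))
        n_pred += len(y_pred)
    if not per_fold:
        raise ValueError("no evaluable folds")
    return per_fold, n_mw_pred / n_pred


def intra_subject_cv(
    band_epochs: Mapping[str, EpochSet],
    k: int = 5,
    seed: int = 0,
    n_components: int = 6,
    shrinkage: float = 0.0,
    svm_c: float = 1.0,
    variant: str = "present",
) -> dict[str, DetectionResult]:
    """Probe-grouped k-fold CV for one subject, per frequency band.

    ``band_epochs`` maps band name to that band's filtered epochs (same
    probes in each). One fold assignment, drawn once from ``seed``, is
    shared across bands so band comparisons see identical partitions.
    """
    first = next(iter(band_epochs.values()))
    folds = make_grouped_folds(first.probe_ids, _probe_label_map(first), k, seed)
    results = {}
    for name, epochs in band_epochs.items():
        band = next((b for b in CANONICAL_BANDS if b.name == name), None)
        per_fold, pred_rate = _run_cv(
            epochs, folds, band, n_components, shrinkage, svm_c
        )
        results[name] = DetectionResult(
            band=name,
            per_fold=per_fold,
            predicted_mw_rate=pred_rate,
            observed_mw_rate=epochs.observed_mw_rate(),
            n_epochs=epochs.n_epochs,
            subject_id=epochs.subject_id,
            variant=variant,
        )
    return results


def inter_subject_loso(
    cohort: Sequence[EpochSet],
    band: FrequencyBand | str | None = None,
    n_components: int = 6,
    shrinkage: float = 0.0,
    svm_c: float = 1.0,
    variant: str = "present",
) -> list[DetectionResult]:
    """Leave-one-subject-out evaluation on band-filtered epoch sets."""
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects for leave-one-subject-out")
    band_obj = (
        next((b for b in CANONICAL_BANDS if b.name == band), None)
        if isinstance(band, str)
        else band
    )
    name = band if isinstance(band, str) else (band.name if band else "broadband")
    results = []
    for i, held_out in enumerate(cohort):
        # sort training subjects so results are invariant to cohort order
        train = concatenate_epochs(
            sorted(
                (s for j, s in enumerate(cohort) if j != i),
                key=lambda s: s.subject_id,
            )
        )
        metrics, y_pred = train_eval_fold(
            train, held_out, band_obj, n_components, shrinkage, svm_c
        )
        results.append(
            DetectionResult(
                band=name,
                per_fold=[metrics],
                predicted_mw_rate=float(np.mean(y_pred == MW)),
                observed_mw_rate=held_out.observed_mw_rate(),
                n_epochs=held_out.n_epochs,
                subject_id=held_out.subject_id,
                variant=variant,
            )
        )
    return results


def permutation_null(
    epochs: EpochSet,
    band: FrequencyBand | None = None,
    n: int = 500,
    k: int = 5,
    seed: int = 0,
    n_components: int = 6,
    shrinkage: float = 0.0,
    svm_c: float = 1.0,
) -> NullDistribution:
    """Chance-level F1 distribution from probe-level label permutations.

    Each iteration permutes the per-probe label vector (all five epochs of
    a probe keep a common shuffled label, respecting within-probe
    dependence), redraws the fold partition, runs the full CSP+SVM CV, and
    records the mean F1 across folds.
    """
    if n < 1:
        raise ValueError("need at least one permutation iteration")
    label_map = _probe_label_map(epochs)
    probes = sorted(label_map)
    probe_labels = np.array([label_map[p] for p in probes], dtype=object)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    f1s = np.empty(n)
    for it in range(n):
        shuffled = dict(zip(probes, rng.permutation(probe_labels)))
        new_labels = np.array(
            [shuffled[int(p)] for p in epochs.probe_ids], dtype=object
        )
        perm = EpochSet(
            epochs.data, epochs.fs, epochs.montage, new_labels,
            epochs.probe_ids, epochs.subject_id,
        )
        folds = make_grouped_folds(
            perm.probe_ids, shuffled, k,
            seed=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                per_fold, _ = _run_cv(
                    perm, folds, band, n_components, shrinkage, svm_c
                )
                f1s[it] = float(np.mean([m["f1"] for m in per_fold]))
            except ValueError:
                f1s[it] = 0.0  # degenerate shuffle (single-class folds)
    lo, hi = np.percentile(f1s, [2.5, 97.5])
    return NullDistribution(f1s, (float(lo), float(hi)), n, seed)


def compare_to_chance(
    cv_f1: Sequence[float], null: NullDistribution
) -> tuple[float, float]:
    """Welch two-sample t-test of the CV F1 values against the null samples."""
    cv_f1 = np.asarray(cv_f1, dtype=float)
    if cv_f1.size < 2:
        raise ValueError("need at least 2 cross-validation values")
    if cv_f1.std(ddof=1) == 0 and null.f1_samples.std(ddof=1) == 0:
        # degenerate: exact comparison of two constants
        equal = np.isclose(cv_f1.mean(), null.f1_samples.mean())
        return (0.0, 1.0) if equal else (np.inf, 0.0)
    t, p = sps.ttest_ind(cv_f1, null.f1_samples, equal_var=False)
    return float(t), float(p)


def select_best_band(
    results: Mapping[str, DetectionResult]
) -> DetectionResult:
    """Return the band with the highest mean F1; ties go to the earlier
    band in canonical order (theta < alpha < beta1 < beta2)."""
    if not results:
        raise ValueError("no band results")
    ordered = sorted(
        results.values(),
        key=lambda r: BAND_ORDER.index(r.band) if r.band in BAND_ORDER else 99,
    )
    best = ordered[0]
    for r in ordered[1:]:
        if r.mean_f1 > best.mean_f1:
            best = r
    return best


def rate_agreement(
    results: Sequence[DetectionResult],
) -> tuple[float, float]:
    """Cross-subject agreement summaries.

    Returns (Pearson r between observed and predicted MW rates, Spearman
    rho between per-subject epoch counts and mean F1).
    """
    if len(results) < 3:
        raise ValueError("need at least 3 subjects")
    obs = np.array([r.observed_mw_rate for r in results])
    pred = np.array([r.predicted_mw_rate for r in results])
    n_ep = np.array([r.n_epochs for r in results])
    f1 = np.array([r.mean_f1 for r in results])
    if obs.std() == 0 or pred.std() == 0 or n_ep.std() == 0 or f1.std() == 0:
        raise ValueError("correlation undefined for constant vectors")
    r, _ = sps.pearsonr(obs, pred)
    rho, _ = sps.spearmanr(n_ep, f1)
    return float(r), float(rho)
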