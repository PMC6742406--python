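"""Classifier evaluation: grouped folds, metrics, CV, permutation null,
chance comparison, best-band selection, rate agreement."""

import numpy as np
import pytest
from scipy import stats as sps

from mweeg.containers import MW, NOT_MW
from mweeg.conditioning import rereference_average
from mweeg.detection import (
    DetectionResult,
    NullDistribution,
    compare_to_chance,
    compute_metrics,
    inter_subject_loso,
    intra_subject_cv,
    make_grouped_folds,
    permutation_null,
    rate_agreement,
    select_best_band,
    train_eval_fold,
)
from mweeg.epoching import extract_preprobe_epochs
from mweeg.spectral import ALPHA, bandpass_raw_band, per_band_epochs
from mweeg.synth import SyntheticConfig, generate_cohort, generate_session

from conftest import alpha_effect, make_two_class_epochs


def _planted_epochs(effect, seed=0, n_probes=24, p_mw=0.5):
    cfg = SyntheticConfig(
        seed=seed, class_effect=alpha_effect(effect), noise_sd=2.0,
        blink_rate=0.0, n_probes=n_probes, probe_spacing=15.0,
        p_mw=p_mw, p_unsure=0.0,
    )
    raw, truth = generate_session(cfg)
    filtered = bandpass_raw_band(rereference_average(raw), ALPHA)
    return extract_preprobe_epochs(filtered, truth.probes())


class TestGroupedFolds:
    def test_balanced_division_two_probes_per_fold(self):
        labels = {i: MW if i < 5 else NOT_MW for i in range(10)}
        folds = make_grouped_folds(list(range(10)), labels, k=5, seed=0)
        counts = np.bincount(list(folds.fold_of_probe.values()), minlength=5)
        assert counts.tolist() == [2] * 5

    def test_stratified_one_of_each_class_per_fold(self):
        labels = {i: MW if i < 5 else NOT_MW for i in range(10)}
        folds = make_grouped_folds(list(range(10)), labels, k=5, seed=3)
        for f in range(5):
            members = [p for p, ff in folds.fold_of_probe.items() if ff == f]
            assert sorted(labels[p] for p in members) == [MW, NOT_MW]

    def test_epochs_of_one_probe_share_fold(self):
        labels = {i: MW if i % 2 else NOT_MW for i in range(10)}
        folds = make_grouped_folds(list(range(10)), labels, k=5, seed=1)
        probe_ids = np.repeat(np.arange(10), 5)
        fold_idx = folds.fold_of_epochs(probe_ids)
        for p in range(10):
            assert len(set(fold_idx[probe_ids == p])) == 1

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            make_grouped_folds([0, 1, 2], {0: MW, 1: MW, 2: NOT_MW}, k=5)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([MW, NOT_MW], [MW, NOT_MW])
        assert m == {
            "accuracy": 100.0, "precision": 1.0, "recall": 1.0, "f1": 1.0
        }

    def test_hand_counted_confusion_table(self):
        y_true = [MW, MW, NOT_MW, NOT_MW]
        y_pred = [MW, NOT_MW, NOT_MW, NOT_MW]
        m = compute_metrics(y_true, y_pred)
        assert m["precision"] == 1.0
        assert m["recall"] == 0.5
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == 75.0

    def test_harmonic_mean_fixed_point(self):
        # precision = recall = 0.5 -> F1 = 0.5 (one TP, one FP, one FN)
        y_true = [MW, MW, NOT_MW, NOT_MW]
        y_pred = [MW, NOT_MW, MW, NOT_MW]
        m = compute_metrics(y_true, y_pred)
        assert m["precision"] == 0.5 and m["recall"] == 0.5
        assert m["f1"] == 0.5

    def test_zero_denominators_are_zero(self):
        m = compute_metrics([NOT_MW, NOT_MW], [NOT_MW, NOT_MW])
        assert m["precision"] == m["recall"] == m["f1"] == 0.0
        assert m["accuracy"] == 100.0

    def test_label_swap_symmetry(self):
        """Relabelling both vectors swaps the roles of the confusion-table
        cells consistently: new recall equals old specificity-side recall."""
        rng = np.random.default_rng(0)
        y_true = rng.choice([MW, NOT_MW], 50)
        y_pred = rng.choice([MW, NOT_MW], 50)
        m = compute_metrics(y_true, y_pred)
        swap = {MW: NOT_MW, NOT_MW: MW}
        y_true_s = np.array([swap[y] for y in y_true], dtype=object)
        y_pred_s = np.array([swap[y] for y in y_pred], dtype=object)
        m_s = compute_metrics(y_true_s, y_pred_s)
        assert m_s["accuracy"] == m["accuracy"]
        tp_s = np.sum((y_true == NOT_MW) & (y_pred == NOT_MW))
        assert m_s["recall"] == pytest.approx(
            tp_s / max(np.sum(y_true == NOT_MW), 1)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestTrainEvalFold:
    def test_resubstitution_on_separable_data_scores_high(self):
        """Strong planted effect, test = train: accuracy >= 90%."""
        eps = _planted_epochs(6.0, seed=1)
        metrics, _ = train_eval_fold(eps, eps, band=ALPHA)
        assert metrics["accuracy"] >= 90.0

    def test_single_class_training_fold_rejected(self):
        eps = _planted_epochs(2.0, seed=2)
        only_mw = eps.select(eps.labels == MW)
        with pytest.raises(ValueError, match="single-class"):
            train_eval_fold(only_mw, eps, band=ALPHA)


class TestIntraSubjectCv:
    def test_alpha_best_band_under_planted_alpha_effect(self):
        cfg = SyntheticConfig(
            seed=4, class_effect=alpha_effect(4.0), n_probes=20,
            probe_spacing=20.0, p_mw=0.5, p_unsure=0.0,
        )
        raw, truth = generate_session(cfg)
        bands = per_band_epochs(rereference_average(raw), truth.probes())
        results = intra_subject_cv(bands, seed=0)
        best = select_best_band(results)
        assert best.band == "alpha"
        assert best.mean_f1 > 0.8

    def test_observed_rate_is_epoch_fraction(self):
        eps = _planted_epochs(2.0, seed=5)
        results = intra_subject_cv({"alpha": eps}, seed=0)
        expected = np.mean(eps.labels == MW)
        assert results["alpha"].observed_mw_rate == pytest.approx(expected)


class TestPermutationNull:
    def test_zero_iterations_rejected(self):
        eps = _planted_epochs(1.0, seed=6, n_probes=10)
        with pytest.raises(ValueError):
            permutation_null(eps, n=0)

    def test_null_centred_near_class_ratio_f1(self):
        """Balanced labels, no effect: the null F1 distribution centres in
        the analytic chance range for a 50/50 class ratio — between the
        coin-flip F1 (0.5) and the always-positive-classifier F1
        2p/(1+p) = 2/3, the degenerate solutions an SVM drifts to on
        uninformative features."""
        eps = _planted_epochs(1.0, seed=7, n_probes=20, p_mw=0.5)
        null = permutation_null(eps, band=ALPHA, n=40, seed=0)
        assert 0.40 < null.f1_samples.mean() < 0.75
        assert null.ci95[0] <= null.f1_samples.mean() <= null.ci95[1]

    def test_true_labels_beat_null_under_strong_effect(self):
        eps = _planted_epochs(6.0, seed=8, n_probes=20)
        results = intra_subject_cv({"alpha": eps}, seed=0)
        null = permutation_null(eps, band=ALPHA, n=40, seed=1)
        assert results["alpha"].mean_f1 > null.ci95[1]


class TestCompareToChance:
    def _null(self, samples):
        samples = np.asarray(samples, dtype=float)
        lo, hi = np.percentile(samples, [2.5, 97.5])
        return NullDistribution(samples, (float(lo), float(hi)),
                                len(samples), 0)

    def test_no_effect_gives_t_zero_p_one(self):
        null = self._null(np.full(100, 0.5))
        t, p = compare_to_chance([0.5, 0.5, 0.5], null)
        assert t == 0.0 and p == 1.0

    def test_large_shift_gives_tiny_p(self, rng):
        samples = 0.5 + 0.02 * rng.standard_normal(200)
        null = self._null(samples)
        shifted = samples[:20] + 5 * samples.std()
        t, p = compare_to_chance(shifted, null)
        assert p < 1e-4 and t > 0

    def test_swapping_samples_negates_t(self, rng):
        a = 0.6 + 0.05 * rng.standard_normal(30)
        b = 0.4 + 0.05 * rng.standard_normal(100)
        t1, p1 = compare_to_chance(a, self._null(b))
        t2, p2 = sps.ttest_ind(b, a, equal_var=False)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestSelectBestBand:
    def _result(self, band, f1):
        return DetectionResult(
            band=band, per_fold=[{"accuracy": 50.0, "precision": f1,
                                  "recall": f1, "f1": f1}],
            predicted_mw_rate=0.5, observed_mw_rate=0.5, n_epochs=10,
        )

    def test_single_band_returned(self):
        r = self._result("theta", 0.7)
        assert select_best_band({"theta": r}) is r

    def test_argmax_by_f1(self):
        results = {
            "theta": self._result("theta", 0.5),
            "alpha": self._result("alpha", 0.9),
            "beta1": self._result("beta1", 0.7),
            "beta2": self._result("beta2", 0.7),
        }
        assert select_best_band(results).band == "alpha"

    def test_exact_tie_broken_by_canonical_order(self):
        results = {
            "beta2": self._result("beta2", 0.8),
            "theta": self._result("theta", 0.8),
        }
        assert select_best_band(results).band == "theta"


class TestRateAgreement:
    def _result(self, band, f1, obs, pred, n):
        return DetectionResult(
            band=band, per_fold=[{"accuracy": 50.0, "precision": f1,
                                  "recall": f1, "f1": f1}],
            predicted_mw_rate=pred, observed_mw_rate=obs, n_epochs=n,
        )

    def test_identical_rates_give_r_one(self):
        rs = [self._result("alpha", 0.5 + 0.1 * i, 0.2 + 0.1 * i,
                           0.2 + 0.1 * i, 30 + i) for i in range(4)]
        r, _ = rate_agreement(rs)
        assert r == pytest.approx(1.0)

    def test_rank_reversal_gives_rho_minus_one(self):
        rs = [self._result("alpha", 0.9 - 0.1 * i, 0.2 + 0.05 * i,
                           0.3 + 0.05 * i, 30 + 5 * i) for i in range(5)]
        _, rho = rate_agreement(rs)
        assert rho == pytest.approx(-1.0)

    def test_constant_vectors_rejected(self):
        rs = [self._result("alpha", 0.5, 0.3, 0.3, 30) for _ in range(3)]
        with pytest.raises(ValueError):
            rate_agreement(rs)


class TestInterSubjectLoso:
    def _band_epochs_for(self, cohort):
        out = []
        for i, (raw, truth) in enumerate(cohort):
            filtered = bandpass_raw_band(rereference_average(raw), ALPHA)
            eps = extract_preprobe_epochs(filtered, truth.probes())
            eps.subject_id = f"P{i + 1}"
            out.append(eps)
        return out

    @pytest.fixture(scope="class")
    def shared_cohort_results(self):
        base = SyntheticConfig(
            seed=20, class_effect=alpha_effect(6.0), n_probes=16,
            probe_spacing=15.0, p_mw=0.5, p_unsure=0.0, blink_rate=0.0,
            noise_sd=2.0,
        )
        cohort = generate_cohort(base, 4, individualize=False, seed=2)
        eps = self._band_epochs_for(cohort)
        return inter_subject_loso(eps, band="alpha")

    def test_shared_topography_transfers_above_chance(
        self, shared_cohort_results
    ):
        mean_f1 = np.mean([r.mean_f1 for r in shared_cohort_results])
        assert mean_f1 > 0.7  # well above the ~0.5 chance F1 at 50% MW

    def test_subject_order_does_not_change_held_out_result(self):
        base = SyntheticConfig(
            seed=21, class_effect=alpha_effect(4.0), n_probes=10,
            probe_spacing=15.0, p_mw=0.5, p_unsure=0.0, blink_rate=0.0,
        )
        cohort = generate_cohort(base, 3, individualize=False, seed=3)
        eps = self._band_epochs_for(cohort)
        res1 = inter_subject_loso(eps, band="alpha")
        res2 = inter_subject_loso(eps[::-1], band="alpha")
        f1_by_subject_1 = {r.subject_id: r.mean_f1 for r in res1}
        f1_by_subject_2 = {r.subject_id: r.mean_f1 for r in res2}
        assert f1_by_subject_1 == f1_by_subject_2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            inter_subject_loso([], band="alpha")


def test_shuffled_labels_fall_inside_chance_ci():
    """Training on shuffled labels yields F1 inside the permutation CI in
    most repetitions (chance behaviour of the whole pipeline)."""
    eps = _planted_epochs(1.0, seed=30, n_probes=13, p_mw=0.35)
    null = permutation_null(eps, band=ALPHA, n=60, seed=5)
    rng = np.random.default_rng(6)
    inside = 0
    n_rep = 10
    for rep in range(n_rep):
        probes = np.unique(eps.probe_ids)
        labels = {int(p): str(eps.labels[eps.probe_ids == p][0]) for p in probes}
        vals = rng.permutation(np.array(list(labels.values()), dtype=object))
        shuffled = dict(zip(labels, vals))
        new_labels = np.array(
            [shuffled[int(p)] for p in eps.probe_ids], dtype=object
        )
        shuffled_eps = eps.select(np.arange(eps.n_epochs))
        shuffled_eps.labels = new_labels
        res = intra_subject_cv({"alpha": shuffled_eps}, seed=rep)
        if null.contains(res["alpha"].mean_f1):
            inside += 1
    assert inside >= 0.9 * n_rep - 1
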