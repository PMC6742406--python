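"""Repeated-measures ANOVA against a brute-force oracle, effect sizes,
Holm correction, post-hoc paired tests."""

import numpy as np
import pytest
from scipy import stats as sps

from mweeg.containers import MW, NOT_MW, Montage, EpochSet
from mweeg.spectral import CANONICAL_BANDS, BandPowerTable
from mweeg.stats import (
    AnovaTable,
    CellMeans,
    aggregate_cell_means,
    eta_p2_from_f,
    holm_bonferroni,
    partial_eta_squared,
    posthoc_paired_t,
    rm_anova_2x4,
)


def brute_force_ss(y):
    """Oracle: explicit-loop sums of squares for the (n, a, b)
    within-subject decomposition."""
    n, a, b = y.shape
    m = y.mean()
    ss = dict.fromkeys(["A", "AxS", "B", "BxS", "AB", "ABxS", "S"], 0.0)
    for j in range(a):
        ss["A"] += n * b * (y[:, j, :].mean() - m) ** 2
    for i in range(n):
        ss["S"] += a * b * (y[i].mean() - m) ** 2
    for k in range(b):
        ss["B"] += n * a * (y[:, :, k].mean() - m) ** 2
    for i in range(n):
        for j in range(a):
            ss["AxS"] += b * (
                y[i, j, :].mean() - y[i].mean() - y[:, j, :].mean() + m
            ) ** 2
    for i in range(n):
        for k in range(b):
            ss["BxS"] += a * (
                y[i, :, k].mean() - y[i].mean() - y[:, :, k].mean() + m
            ) ** 2
    for j in range(a):
        for k in range(b):
            ss["AB"] += n * (
                y[:, j, k].mean() - y[:, j, :].mean() - y[:, :, k].mean() + m
            ) ** 2
    for i in range(n):
        for j in range(a):
            for k in range(b):
                ss["ABxS"] += (
                    y[i, j, k]
                    - y[i, j, :].mean() - y[i, :, k].mean() - y[:, j, k].mean()
                    + y[i].mean() + y[:, j, :].mean() + y[:, :, k].mean()
                    - m
                ) ** 2
    return ss


def _cells(y, kind="participant"):
    names = tuple(f"u{i}" for i in range(y.shape[0]))
    return CellMeans(y, kind, names)


class TestRmAnova:
    def test_sums_of_squares_match_brute_force_oracle(self, rng):
        """Random 6-unit 2x4 designs: every SS component matches the
        explicit-loop oracle to 1e-10."""
        for _ in range(5):
            y = rng.standard_normal((6, 2, 4))
            table = rm_anova_2x4(_cells(y))
            oracle = brute_force_ss(y)
            for key, val in oracle.items():
                assert table.ss[key] == pytest.approx(val, abs=1e-10)
            total = sum(oracle.values())
            assert table.ss["total"] == pytest.approx(total, abs=1e-10)

    def test_df_structure_exact(self, rng):
        y = rng.standard_normal((15, 2, 4))
        table = rm_anova_2x4(_cells(y))
        assert (table["MW"].df1, table["MW"].df2) == (1, 14)
        assert (table["MWxFreq"].df1, table["MWxFreq"].df2) == (3, 42)
        y16 = rng.standard_normal((16, 2, 4))
        table16 = rm_anova_2x4(_cells(y16, "channel"))
        assert (table16["MW"].df1, table16["MW"].df2) == (1, 15)
        assert (table16["MWxFreq"].df1, table16["MWxFreq"].df2) == (3, 45)

    def test_null_f_distribution_behaviour(self, rng):
        """Pure unit + band effects, no MW effect: the MW factor's F is
        central-F distributed. With df2 = 5 the exact null mean is
        df2/(df2-2) = 5/3, and the 5% type-I rate holds."""
        n_sim = 400
        fs, rejections = [], 0
        for _ in range(n_sim):
            unit = rng.standard_normal((6, 1, 1))
            band = rng.standard_normal((1, 1, 4))
            noise = rng.standard_normal((6, 2, 4))
            table = rm_anova_2x4(_cells(unit + band + noise))
            fs.append(table["MW"].F)
            rejections += table["MW"].p_uncorrected < 0.05
        expected_mean = 5 / (5 - 2)
        assert np.mean(fs) == pytest.approx(expected_mean, rel=0.25)
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_planted_mw_shift_grows_mw_factor_only(self, rng):
        f_mw, f_int = [], []
        for delta in (0.0, 1.0, 3.0):
            y = rng.standard_normal((10, 2, 4))
            y[:, 0, :] += delta  # uniform MW shift in all bands
            table = rm_anova_2x4(_cells(y))
            f_mw.append(table["MW"].F)
            f_int.append(table["MWxFreq"].F)
        assert f_mw[0] < f_mw[1] < f_mw[2]
        assert all(f < 5 for f in f_int)  # interaction stays null-like

    def test_matches_pingouin_two_way_rm_anova(self, rng):
        """Independent oracle: pingouin's repeated-measures ANOVA on the
        same long-format data gives the same F statistics."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        y = rng.standard_normal((8, 2, 4))
        table = rm_anova_2x4(_cells(y))
        rows = [
            {"unit": i, "mw": j, "band": k, "y": y[i, j, k]}
            for i in range(8) for j in range(2) for k in range(4)
        ]
        res = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["mw", "band"],
            subject="unit", detailed=True,
        )
        f_mw = float(res.loc[res["Source"] == "mw", "F"].iloc[0])
        f_int = float(res.loc[res["Source"] == "mw * band", "F"].iloc[0])
        assert table["MW"].F == pytest.approx(f_mw, rel=1e-6)
        assert table["MWxFreq"].F == pytest.approx(f_int, rel=1e-6)

    def test_too_few_units_rejected(self, rng):
        with pytest.raises(ValueError):
            rm_anova_2x4(_cells(rng.standard_normal((2, 2, 4))))


class TestPartialEtaSquared:
    def test_printed_effect_sizes_recovered_from_f(self):
        """Spot checks against published repeated-measures results: the
        effect size from F and dfs reproduces the printed values at 2 dp."""
        assert round(eta_p2_from_f(400.95, 1, 15), 2) == 0.96
        assert round(eta_p2_from_f(95.49, 1, 14), 2) == 0.87
        assert round(eta_p2_from_f(22.51, 1, 15), 2) == 0.60
        assert round(eta_p2_from_f(2.99, 1, 13), 2) == 0.19

    def test_ss_form_equals_f_form(self, rng):
        y = rng.standard_normal((10, 2, 4))
        table = rm_anova_2x4(_cells(y))
        row = table["MW"]
        from_f = eta_p2_from_f(row.F, row.df1, row.df2)
        assert row.eta_p2 == pytest.approx(from_f, abs=1e-12)

    def test_zero_error_gives_one_and_double_zero_rejected(self):
        assert partial_eta_squared(5.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            partial_eta_squared(0.0, 0.0)


class TestHolmBonferroni:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_bonferroni([0.03]), [0.03])

    def test_hand_applied_step_down(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.04]), [0.02, 0.04]
        )

    def test_conservative_and_permutation_invariant(self, rng):
        p = rng.uniform(size=12)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p)
        perm = rng.permutation(12)
        adj_perm = holm_bonferroni(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestPosthocPairedT:
    def test_identical_pairs_give_t_zero_p_one(self):
        y = np.random.default_rng(0).standard_normal((6, 1, 4))
        cells = CellMeans(np.repeat(y, 2, axis=1), "participant",
                          tuple("abcdef"))
        for row in posthoc_paired_t(cells):
            assert row["t"] == 0.0 and row["p"] == 1.0

    def test_constant_shift_zero_noise_guarded(self):
        y = np.random.default_rng(1).standard_normal((6, 1, 4))
        shifted = np.concatenate([y + 2.0, y], axis=1)
        cells = CellMeans(shifted, "participant", tuple("abcdef"))
        for row in posthoc_paired_t(cells):
            assert row["t"] == np.inf and row["p"] == 0.0

    def test_power_matches_noncentral_t_oracle(self, rng):
        """Empirical rejection rate at alpha = 0.05 for paired data with a
        known shift matches the closed-form noncentral-t power."""
        n, delta, sigma = 12, 0.8, 1.0
        n_sim = 1500
        rejections = 0
        for _ in range(n_sim):
            d = delta + sigma * rng.standard_normal(n)
            _, p = sps.ttest_rel(d, np.zeros(n))
            rejections += p < 0.05
        nc = delta / (sigma / np.sqrt(n))
        tcrit = sps.t.ppf(0.975, n - 1)
        power = 1 - sps.nct.cdf(tcrit, n - 1, nc) + sps.nct.cdf(-tcrit, n - 1, nc)
        assert rejections / n_sim == pytest.approx(power, abs=0.04)


class TestAggregation:
    def _table(self, rng, subject="S0", n_probes=6):
        labels = np.array(
            [MW if i % 2 else NOT_MW for i in range(n_probes) for _ in range(5)],
            dtype=object,
        )
        probe_ids = np.repeat(np.arange(n_probes), 5)
        values = rng.uniform(0.5, 2.0, size=(n_probes * 5, 16, 4))
        ch = tuple(f"ch{i}" for i in range(16))
        return BandPowerTable(values, CANONICAL_BANDS, labels, probe_ids, ch,
                              subject)

    def test_channel_units_shape(self, rng):
        cells = aggregate_cell_means(self._table(rng), "channel")
        assert cells.values.shape == (16, 2, 4)

    def test_participant_units_shape(self, rng):
        tables = [self._table(rng, f"S{i}") for i in range(15)]
        cells = aggregate_cell_means(tables, "participant", channel="ch3")
        assert cells.values.shape == (15, 2, 4)
        assert cells.unit_names == tuple(f"S{i}" for i in range(15))

    def test_single_epoch_cell_mean_is_that_value(self, rng):
        values = rng.uniform(1.0, 2.0, size=(2, 3, 4))
        labels = np.array([MW, NOT_MW], dtype=object)
        table = BandPowerTable(values, CANONICAL_BANDS, labels,
                               np.array([0, 1]), ("a", "b", "c"), "S0")
        cells = aggregate_cell_means(table, "channel", log=False)
        np.testing.assert_allclose(cells.values[:, 0, :], values[0])
        np.testing.assert_allclose(cells.values[:, 1, :], values[1])
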