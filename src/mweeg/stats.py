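"""Band-power statistics: two-factor repeated-measures ANOVA with partial
eta squared, Holm-Bonferroni correction, and post-hoc paired t-tests.

Two families of models are fitted on (log) band power:
  * channel-wise models — for each channel, units are the participants and
    the factors are attentional state (2 levels) x band (4 levels);
  * participant-wise models — for each participant, units are the channels.
The response entering a model is the cell mean: one value per unit x
state x band. The univariate within-subject decomposition with a separate
error term per effect gives dfs (1, n-1) for the state factor and
(3, 3(n-1)) for the interaction in the 2 x 4 design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import MW, NOT_MW
from .spectral import BandPowerTable


@dataclass
class CellMeans:
    """Mean (log-)band power per unit x condition x band.

    values has shape (n_units, 2, n_bands) with condition order (MW, NOT_MW).
    unit_kind records whether units are participants or channels.
    """

    values: np.ndarray
    unit_kind: str
    unit_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("values must be (n_units, 2, n_bands)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cell means contain non-finite values")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


@dataclass
class AnovaRow:
    factor: str
    F: float
    df1: int
    df2: int
    p_uncorrected: float
    eta_p2: float
    p_holm: float | None = None


@dataclass
class AnovaTable:
    """MW and MW x Freq rows of one repeated-measures model."""

    unit_kind: str
    model_name: str
    rows: dict[str, AnovaRow]
    ss: dict[str, float]

    def __getitem__(self, factor: str) -> AnovaRow:
        return self.rows[factor]


def _cell_means_one_table(
    powers: BandPowerTable, log: bool = True
) -> np.ndarray:
    """(n_channels, 2, n_bands) cell means for one subject's table."""
    if powers.labels is None:
        raise ValueError("labelled band powers required")
    vals = np.log(powers.values) if log else powers.values
    out = np.empty((vals.shape[1], 2, vals.shape[2]))
    for ci, cls in enumerate((MW, NOT_MW)):
        mask = powers.labels == cls
        if not mask.any():
            raise ValueError(f"subject {powers.subject_id} has no {cls} epochs")
        out[:, ci, :] = vals[mask].mean(axis=0)
    return out


def aggregate_cell_means(
    powers: BandPowerTable | Sequence[BandPowerTable],
    unit_kind: str,
    channel: int | str | None = None,
    log: bool = True,
) -> CellMeans:
    """Build the ANOVA response for one model.

    unit_kind="channel": one subject's table; units are its channels
    (the participant-wise model). unit_kind="participant": a list of
    per-subject tables and a target ``channel``; units are participants
    (the channel-wise model). Units missing a condition cell are dropped
    with a warning.
    """
    if unit_kind == "channel":
        if not isinstance(powers, BandPowerTable):
            raise TypeError("unit_kind='channel' expects one BandPowerTable")
        values = _cell_means_one_table(powers, log)
        return CellMeans(values, "channel", powers.channel_labels)
    if unit_kind == "participant":
        if isinstance(powers, BandPowerTable) or channel is None:
            raise TypeError(
                "unit_kind='participant' expects a list of tables and a channel"
            )
        rows, names = [], []
        for table in powers:
            ch = (
                table.channel_labels.index(channel)
                if isinstance(channel, str)
                else channel
            )
            try:
                rows.append(_cell_means_one_table(table, log)[ch])
                names.append(table.subject_id)
            except ValueError:
                warnings.warn(
                    f"subject {table.subject_id} missing a condition cell; dropped"
                )
        return CellMeans(np.stack(rows), "participant", tuple(names))
    raise ValueError("unit_kind must be 'channel' or 'participant'")


def rm_anova_2x4(cells: CellMeans, model_name: str = "") -> AnovaTable:
    """Two-factor within-subject ANOVA on an (n, 2, b) cell-mean array.

    Univariate decomposition with a separate error term per effect:
    the state factor A is tested against the A x unit interaction, the
    A x B interaction against the A x B x unit residual. No sphericity
    correction is applied (the A factor, with 2 levels, needs none; for
    the interaction this is the plain univariate test).
    """
    y = cells.values
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need at least 3 units")

    m = y.mean()
    m_i = y.mean(axis=(1, 2))  # unit means
    m_j = y.mean(axis=(0, 2))  # condition (A) means
    m_k = y.mean(axis=(0, 1))  # band (B) means
    m_ij = y.mean(axis=2)  # unit x A
    m_ik = y.mean(axis=1)  # unit x B
    m_jk = y.mean(axis=0)  # A x B

    ss_a = n * b * np.sum((m_j - m) ** 2)
    ss_as = b * np.sum((m_ij - m_i[:, None] - m_j[None, :] + m) ** 2)
    ss_b = n * a * np.sum((m_k - m) ** 2)
    ss_bs = a * np.sum((m_ik - m_i[:, None] - m_k[None, :] + m) ** 2)
    ss_ab = n * np.sum((m_jk - m_j[:, None] - m_k[None, :] + m) ** 2)
    resid = (
        y
        - m_ij[:, :, None]
        - m_ik[:, None, :]
        - m_jk[None, :, :]
        + m_i[:, None, None]
        + m_j[None, :, None]
        + m_k[None, None, :]
        - m
    )
    ss_abs = np.sum(resid**2)

    def row(factor: str, ss_eff: float, ss_err: float, df1: int, df2: int) -> AnovaRow:
        if ss_err <= 0 and ss_eff <= 0:
            raise ValueError(f"degenerate variance for factor {factor}")
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ms_err == 0:
            f, p = np.inf, 0.0
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df1, df2))
        return AnovaRow(factor, float(f), df1, df2, p,
                        partial_eta_squared(ss_eff, ss_err))

    rows = {
        "MW": row("MW", ss_a, ss_as, a - 1, (a - 1) * (n - 1)),
        "MWxFreq": row(
            "MWxFreq", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)
        ),
    }
    ss = {
        "A": ss_a, "AxS": ss_as, "B": ss_b, "BxS": ss_bs,
        "AB": ss_ab, "ABxS": ss_abs,
        "S": a * b * np.sum((m_i - m) ** 2),
        "total": np.sum((y - m) ** 2),
    }
    return AnovaTable(cells.unit_kind, model_name, rows, ss)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Effect size eta_p^2 = SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("both sums of squares are zero")
    return float(ss_effect / (ss_effect + ss_error))


def eta_p2_from_f(f: float, df1: int, df2: int) -> float:
    """eta_p^2 recovered from a reported F statistic and its dfs:
    F*df1 / (F*df1 + df2)."""
    if f < 0:
        raise ValueError("F must be non-negative")
    return float(f * df1 / (f * df1 + df2))


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="holm")[1]


def correct_family(tables: Sequence[AnovaTable], factor: str) -> None:
    """Holm-correct one factor's p-values across a family of models,
    writing p_holm into each table in place."""
    p = [t[factor].p_uncorrected for t in tables]
    adj = holm_bonferroni(p)
    for t, q in zip(tables, adj):
        t[factor].p_holm = float(q)


def posthoc_paired_t(cells: CellMeans) -> list[dict[str, float]]:
    """Paired t-test of MW vs NOT_MW cell means per band, across units.

    Uncorrected p-values. Zero-variance differences are handled exactly:
    all-zero differences give t = 0, p = 1; a constant nonzero shift gives
    t = +/-inf, p = 0.
    """
    y = cells.values
    if y.shape[0] < 2:
        raise ValueError("need at least 2 paired units")
    out = []
    for k in range(y.shape[2]):
        d = y[:, 0, k] - y[:, 1, k]
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d.mean(), 0):
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(d.mean()) * np.inf), 0.0
        else:
            t, p = sps.ttest_rel(y[:, 0, k], y[:, 1, k])
        out.append({"band": k, "t": float(t), "p": float(p)})
    return out
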