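"""Common spatial patterns: discriminative spatial filter learning.

CSP finds channel weightings whose projected variance is maximally
different between the two attentional states. With trace-normalized class
covariances C_mw and C_not, the filters w solve the generalized eigenproblem

    C_mw w = lambda (C_mw + C_not) w,    lambda in [0, 1],

where lambda is the fraction of composite variance explained by the MW
class along w. The three largest-lambda and three smallest-lambda
eigenvectors (three per class) form the default 6-filter model; the duals
of the filters ("patterns") are the interpretable scalp maps. Features are
the log normalized powers of the six projections.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import MW, NOT_MW, EpochSet
from .spectral import FrequencyBand


@dataclass
class CspModel:
    """Fitted CSP filters/patterns for one frequency band.

    filters : (k, channels), rows unit-normalized, MW-side filters first
    patterns : (channels, k) duals of the filters (scalp maps)
    eigenvalues : (k,) sorted descending; >0.5 means MW-dominant variance
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    band: FrequencyBand | None
    class_order: tuple[str, str] = (MW, NOT_MW)
    shrinkage: float = 0.0

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "filters": self.filters.tolist(),
                "patterns": self.patterns.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "band": list(self.band) if self.band else None,
                "class_order": list(self.class_order),
                "shrinkage": self.shrinkage,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CspModel":
        d = json.loads(text)
        band = FrequencyBand(*d["band"]) if d["band"] else None
        return cls(
            np.array(d["filters"]),
            np.array(d["patterns"]),
            np.array(d["eigenvalues"]),
            band,
            tuple(d["class_order"]),
            d["shrinkage"],
        )


def class_covariances(
    epochs: EpochSet, shrinkage: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Average trace-normalized epoch covariances per class.

    Each epoch's covariance X X^T is divided by its trace before averaging,
    so high-amplitude epochs do not dominate. Optional shrinkage pulls the
    average toward a scaled identity:
        C <- (1 - gamma) C + gamma (tr(C)/d) I.
    """
    if epochs.labels is None:
        raise ValueError("labelled epochs required")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    covs = {}
    for cls in (MW, NOT_MW):
        mask = epochs.labels == cls
        if not mask.any():
            raise ValueError(f"no epochs of class {cls}")
        acc = np.zeros((epochs.n_channels, epochs.n_channels))
        for x in epochs.data[mask]:
            c = x @ x.T
            tr = np.trace(c)
            if tr <= 0:
                raise ValueError("zero-variance epoch encountered")
            acc += c / tr
        c = acc / mask.sum()
        if shrinkage > 0:
            d = c.shape[0]
            c = (1 - shrinkage) * c + shrinkage * (np.trace(c) / d) * np.eye(d)
        covs[cls] = c
    return covs[MW], covs[NOT_MW]


def fit_csp(
    epochs: EpochSet,
    n_components: int = 6,
    shrinkage: float = 0.0,
    band: FrequencyBand | None = None,
) -> CspModel:
    """Learn CSP filters from band-filtered labelled epochs.

    Solves C_mw w = lambda (C_mw + C_not) w and keeps the n_components/2
    most MW-dominant and n_components/2 most NOT_MW-dominant eigenvectors.
    If the composite covariance is numerically singular with shrinkage 0,
    the fit falls back to shrinkage 0.05 with a warning.
    """
    if n_components % 2 or n_components < 2:
        raise ValueError("n_components must be a positive even number")
    if n_components > epochs.n_channels:
        raise ValueError("n_components cannot exceed channel count")

    c_mw, c_not = class_covariances(epochs, shrinkage)
    composite = c_mw + c_not
    if shrinkage == 0.0 and (
        np.linalg.cond(composite) > 1e10
    ):
        warnings.warn(
            "composite covariance ill-conditioned; refitting with shrinkage 0.05"
        )
        return fit_csp(epochs, n_components, shrinkage=0.05, band=band)
    try:
        evals, evecs = scipy.linalg.eigh(c_mw, composite)
    except scipy.linalg.LinAlgError as err:
        if shrinkage == 0.0:
            warnings.warn(
                "generalized eigenproblem failed; refitting with shrinkage 0.05"
            )
            return fit_csp(epochs, n_components, shrinkage=0.05, band=band)
        raise ValueError("singular covariances even with shrinkage") from err

    # descending lambda: MW-dominant directions first; stable mergesort keeps
    # input channel order as the tie-break
    order = np.argsort(-evals, kind="stable")
    evals, evecs = evals[order], evecs[:, order]

    half = n_components // 2
    sel = list(range(half)) + list(range(len(evals) - half, len(evals)))
    w_full = evecs.T  # rows are filters, ordered by descending lambda
    patterns_full = np.linalg.pinv(w_full)  # columns dual to filter rows

    filters = w_full[sel].copy()
    patterns = patterns_full[:, sel].copy()
    eigenvalues = evals[sel].copy()

    # unit-norm filter rows with compensating pattern scaling; sign fixed so
    # the max-|weight| filter coefficient is positive
    for i in range(n_components):
        nrm = np.linalg.norm(filters[i])
        filters[i] /= nrm
        patterns[:, i] *= nrm
        j = int(np.argmax(np.abs(filters[i])))
        if filters[i, j] < 0:
            filters[i] *= -1
            patterns[:, i] *= -1

    return CspModel(
        filters=filters,
        patterns=patterns,
        eigenvalues=eigenvalues,
        band=band,
        shrinkage=shrinkage,
    )


def csp_features(model: CspModel, epochs: EpochSet) -> np.ndarray:
    """Log normalized power of each CSP projection, per epoch.

    f_i = log(v_i / sum_j v_j) with v_i the variance of projection i; the
    normalization makes features invariant to overall epoch amplitude.
    """
    if epochs.n_channels != model.filters.shape[1]:
        raise ValueError("epoch channel count does not match model")
    proj = np.einsum("kc,ecs->eks", model.filters, epochs.data)
    v = proj.var(axis=2)
    total = v.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero-variance epoch; reject upstream")
    return np.log(v / total)
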