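import numpy as np
import pytest

from mweeg.containers import MW, NOT_MW, EpochSet, default_montage
from mweeg.synth import SyntheticConfig, generate_session


@pytest.fixture
def montage():
    return default_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def short_session_config(**overrides):
    """Session config scaled for unit tests: 6 probes, 30 s apart."""
    defaults = dict(seed=7, n_probes=6, probe_spacing=30.0)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def alpha_effect(factor, n_sources=8, source=1):
    eff = np.ones(n_sources)
    eff[source] = factor
    return eff


@pytest.fixture
def short_session():
    return generate_session(short_session_config())


def make_two_class_epochs(
    cov_mw, cov_not, n_per_class=40, n_samples=200, fs=100.0, seed=0,
    montage_labels=("A", "B"),
):
    """Draw labelled Gaussian epochs with known class covariances."""
    from mweeg.containers import Montage

    rng = np.random.default_rng(seed)
    d = cov_mw.shape[0]
    pos = np.column_stack([np.linspace(-1, 1, d), np.zeros(d)])
    montage = Montage(tuple(montage_labels), pos)
    chol_mw = np.linalg.cholesky(cov_mw)
    chol_not = np.linalg.cholesky(cov_not)
    data, labels, probe_ids = [], [], []
    for i in range(n_per_class):
        data.append(chol_mw @ rng.standard_normal((d, n_samples)))
        labels.append(MW)
        probe_ids.append(i)
    for i in range(n_per_class):
        data.append(chol_not @ rng.standard_normal((d, n_samples)))
        labels.append(NOT_MW)
        probe_ids.append(n_per_class + i)
    return EpochSet(
        np.array(data), fs, montage, np.array(labels, dtype=object),
        np.array(probe_ids),
    )
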