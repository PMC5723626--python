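"""Shared fixtures: synthetic curves and cached fits.

Fitting all twelve equations is the expensive step, so curves and fits
that several test modules need are built once per session.
"""

import logging

import numpy as np
import pytest

import tpcfit as tp

logging.getLogger("tpcfit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def noiseless_curves():
    """One noiseless 30-temperature curve per registered model."""
    return {mid: tp.generate_curve(mid, 30, 0.0, seed=1)
            for mid in range(4, 16)}


@pytest.fixture(scope="session")
def noiseless_fits(noiseless_curves):
    """Each model fitted to its own noiseless data."""
    return {mid: tp.fit_model(mid, curve)
            for mid, curve in noiseless_curves.items()}


@pytest.fixture(scope="session")
def paper_like_curve():
    """The 30-temperature member of the paper-like synthetic set."""
    datasets = tp.paper_like_datasets(seed=0)
    curve = tp.prepare_curve(datasets[1])
    assert curve.n_temperatures == 30
    return curve


@pytest.fixture(scope="session")
def paper_like_fits(paper_like_curve):
    """All twelve equations fitted to the paper-like curve."""
    return tp.fit_all(paper_like_curve, random_state=0)


@pytest.fixture(scope="session")
def distinguishability_table(paper_like_curve, paper_like_fits):
    """Cross-simulation BIC ranks (generator x fitted x replicate) on the
    paper-like 30-temperature curve, 5 replicates, fixed seed."""
    return tp.distinguishability_experiment(
        paper_like_curve, replicates=5, seed=0, fits=paper_like_fits)


@pytest.fixture()
def gaussian_fit():
    """A converged Gaussian fit with known parameters (a=1, b=5, t_ref=20)."""
    T = np.linspace(5.0, 35.0, 30)
    params = {"a": 1.0, "b": 5.0, "t_ref": 20.0}
    rates = tp.evaluate(8, params, T)
    curve = tp.PreparedCurve("gauss", T, rates)
    return tp.fit_model(8, curve)
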