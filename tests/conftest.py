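"""Shared fixtures: the reference cohort and expensive model fits.

The Bayesian sampler and quadrature posterior are session-scoped so the
acceptance tests and the unit tests share one fit each.
"""

from __future__ import annotations

import numpy as np
import pytest

import mfdbp
from mfdbp.bayes import posterior_quadrature


@pytest.fixture(scope="session")
def reference_cohort():
    return mfdbp.load_reference_cohort()


@pytest.fixture(scope="session")
def analysis_subset(reference_cohort):
    """The under-11-years cohort (n = 35) used by every model stage."""
    return mfdbp.subset_by_age(reference_cohort, 11.0)


@pytest.fixture(scope="session")
def seg_fit(analysis_subset):
    return mfdbp.fit_segmented(analysis_subset.ages, analysis_subset.mfd, psi0=6.0)


@pytest.fixture(scope="session")
def bayes_fit(analysis_subset):
    """Full-size MCMC fit (4 chains x 2500 draws) at the default seed."""
    return mfdbp.fit_bayes_segmented(analysis_subset.ages, analysis_subset.mfd, seed=0)


@pytest.fixture(scope="session")
def bayes_linear_fit(analysis_subset):
    return mfdbp.fit_bayes_linear(analysis_subset.ages, analysis_subset.mfd, seed=1)


@pytest.fixture(scope="session")
def quad_posterior(analysis_subset):
    """Exact quadrature posterior; the sampler-independent oracle."""
    return posterior_quadrature(analysis_subset.ages, analysis_subset.mfd)


@pytest.fixture()
def noiseless_twoseg():
    """Exact two-segment data: level 430 at the knot, slopes -170/-30, psi=6."""
    x = np.round(np.linspace(1.0, 10.9, 35), 1)
    y = 430.0 + (-170.0) * np.minimum(x - 6.0, 0.0) + (-30.0) * np.maximum(x - 6.0, 0.0)
    return x, y
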