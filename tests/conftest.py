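"""Shared fixtures: small synthetic datasets and an enumeration oracle.

The enumeration oracle computes a site's marginal likelihood by summing the
probability of every latent occupancy sequence in plain probability space,
independently of the package's forward recursion.
"""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import occutrend as ot


def enum_site_loglik(params: ot.ParamSet, data: ot.SurveyDataset, i: int) -> float:
    """Brute-force marginal likelihood of site i over all 2^T latent sequences."""
    y = data.y[i]
    date = data.date[i]
    x = np.asarray(data.covariates, dtype=float)[i]
    T = y.shape[0]
    psi1 = expit(params.beta0 + x @ params.beta)
    total = 0.0
    for zseq in product((0, 1), repeat=T):
        prob = psi1 if zseq[0] == 1 else 1.0 - psi1
        for t in range(1, T):
            pi = expit(
                params.a[t - 1] + params.b[t - 1] * zseq[t - 1] + x @ params.beta
            )
            prob *= pi if zseq[t] == 1 else 1.0 - pi
        for t in range(T):
            for j in range(y.shape[1]):
                if np.isnan(y[t, j]):
                    continue
                p = expit(params.alpha0 + params.alpha1 * date[t, j])
                pdet = p * zseq[t]
                prob *= pdet if y[t, j] == 1 else 1.0 - pdet
        total += prob
    return float(np.log(total)) if total > 0 else -np.inf


def make_dataset(y, date=None, covs=None, coords=None, years=None) -> ot.SurveyDataset:
    """Assemble a SurveyDataset from explicit arrays without re-standardizing.

    ``covs`` defaults to all-zero covariates (average conditions); ``date``
    defaults to 0 (mean survey date).
    """
    y = np.asarray(y, dtype=float)
    n, T, J = y.shape
    if date is None:
        date = np.where(np.isnan(y), np.nan, 0.0)
    if covs is None:
        covs = np.zeros((n, len(ot.COVARIATES)))
    if coords is None:
        coords = np.column_stack([np.arange(n) * 10.0, np.zeros(n)])
    if years is None:
        years = tuple(range(2016, 2016 + T))
    return ot.SurveyDataset(
        site_id=np.arange(1, n + 1),
        y=y,
        date=np.asarray(date, dtype=float),
        covariates=pd.DataFrame(np.asarray(covs, float), columns=list(ot.COVARIATES)),
        coords=coords,
        years=years,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """60-site, 3-season, 4-visit declining-preset dataset with truth."""
    sc = ot.ScenarioConfig(seed=42, n_sites=60, T=3, J=4,
                           preset="declining", n_cells=400)
    return ot.generate_dataset(sc)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Reduced-budget vague-prior fit of the small declining dataset."""
    data, _ = small_dataset
    priors = ot.vague_priors(ot.param_names(data.n_seasons - 1))
    cfg = ot.McmcConfig(seed=5, n_chains=2, n_burnin=300, n_retained=800, thin=1)
    return ot.fit_model(data, priors, cfg)
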