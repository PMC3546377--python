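import numpy as np
import pytest

from mvhet import (
    FitOptions,
    MVDataset,
    OutcomeSpace,
    StudyRecord,
    fixed_effects_fit,
    load_periodontal,
    reml_fit,
)


@pytest.fixture(scope="session")
def periodontal():
    return load_periodontal()


@pytest.fixture(scope="session")
def periodontal_fits(periodontal):
    """REML (obsinfo covariance) and fixed-effects fits, shared across tests."""
    re = reml_fit(periodontal, opts=FitOptions(cov_method="obsinfo"))
    fe = fixed_effects_fit(periodontal)
    return re, fe


def random_dataset(rng, n=6, p=2, sigma_scale=0.02, complete=True):
    """Small random dataset with PD within-study blocks, for property tests."""
    space = OutcomeSpace([f"Y{j+1}" for j in range(p)])
    mu = rng.normal(size=p)
    studies = []
    for i in range(n):
        sd = np.sqrt(rng.uniform(0.002, 0.05, size=p))
        # equicorrelation is PD only for r > -1/(p-1)
        r = rng.uniform(-0.9 / max(p - 1, 1), 0.6)
        corr = np.full((p, p), r)
        np.fill_diagonal(corr, 1.0)
        S = corr * np.outer(sd, sd)
        y = rng.multivariate_normal(mu, S + sigma_scale * np.eye(p))
        if complete:
            obs = list(range(p))
        else:
            obs = sorted(rng.choice(p, size=rng.integers(1, p + 1), replace=False))
        studies.append(StudyRecord(f"s{i}", obs, y[obs], S[np.ix_(obs, obs)]))
    return MVDataset(space, studies)


def random_psd(rng, p, scale=0.05):
    A = rng.normal(scale=np.sqrt(scale), size=(p, p))
    return A @ A.T
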