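import numpy as np
import pandas as pd
import pytest

from ctra_wellbeing.genesets import load_gene_set
from ctra_wellbeing.synthetic import StudyBundleConfig, gen_study_bundle


@pytest.fixture(scope="session")
def gene_set53():
    return load_gene_set()


@pytest.fixture(scope="session")
def gene_set52():
    return load_gene_set(exclude=["IL6"])


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic confirmation study on disk (n=60, known effect)."""
    out = tmp_path_factory.mktemp("bundle")
    config = StudyBundleConfig(n_subjects=60, b_true={"eudaimonic": -0.5}, seed=42)
    paths = gen_study_bundle(config, out)
    return config, paths


def make_hcs_data(rng, n, G, p, beta, sigma, rho, mu=None):
    """Direct draw from the repeated-measures model (test-side generator)."""
    X = rng.standard_normal((n, p))
    mu = np.zeros(G) if mu is None else mu
    R = np.full((G, G), rho)
    np.fill_diagonal(R, 1.0)
    Sigma = R * np.outer(sigma, sigma)
    E = rng.multivariate_normal(np.zeros(G), Sigma, size=n)
    Y = mu + (X @ beta)[:, None] + E
    Ydf = pd.DataFrame(Y, columns=[f"g{j}" for j in range(G)])
    Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    return Ydf, Xdf, Sigma
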