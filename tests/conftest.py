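import numpy as np
import pandas as pd
import pytest

from rcgmeth import build_design, sample_covariates, sample_rcg_beta

# reference single-site parameter set used across tests (cohort ML estimates
# at one CpG site, five covariates)
REF_GAMMA = np.array([-1.099, 0.096, -0.007, -0.004, 0.003, 0.001])
REF_ALPHA = 5.84
REF_RHO = 0.93


@pytest.fixture(scope="session")
def cohort_design():
    """Fixed covariate matrix emulating the cohort (n=1118), shared by all
    tests: drawn once, reused — power/type-I studies condition on X."""
    cov = sample_covariates(1118, seed=20160)
    X, names = build_design(cov)
    return X, names


@pytest.fixture(scope="session")
def small_design():
    cov = sample_covariates(400, seed=7)
    X, names = build_design(cov, ["gender", "age"])
    return X, names


@pytest.fixture
def toy_dataset_files(tmp_path):
    """3-site x 60-sample beta matrix + covariates written as TSV files."""
    rng = np.random.default_rng(42)
    cov = sample_covariates(60, seed=13)
    cov.index = pd.Index([f"s{i:02d}" for i in range(60)], name="sample")
    X, _ = build_design(cov)
    rows = []
    for g in (0.0, 0.0, 0.6):
        theta = np.exp(X @ np.array([-1.0, g, 0.0, 0.0, 0.0, 0.0]))
        rows.append(sample_rcg_beta(60, 5.0, 0.8, theta, rng))
    betas = pd.DataFrame(rows, index=["cg01", "cg02", "cg03"],
                         columns=cov.index)
    beta_path = tmp_path / "betas.tsv"
    covar_path = tmp_path / "covars.tsv"
    betas.to_csv(beta_path, sep="\t")
    cov.to_csv(covar_path, sep="\t")
    return beta_path, covar_path, betas, cov
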