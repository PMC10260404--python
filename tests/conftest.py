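import numpy as np
import pytest

from cellgp.gplvm import GPLVM, GplvmConfig
from cellgp.spatial_de import GPMixture, MixtureConfig
from cellgp.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def two_branch_data():
    """Two-branch stimulation dataset at the standard desk scale:
    8 donors x 50 cells on 4 plates, 200 genes (20% per response branch)."""
    cfg = SimConfig(n_donors=8, cells_per_donor=50, n_genes=200,
                    n_plates=4, seed=3)
    y, z, geno, truth = simulate_dataset(cfg)
    return y, z, geno, truth


@pytest.fixture(scope="session")
def gplvm_fit(two_branch_data):
    """Sparse GPLVM fitted to the two-branch dataset (shared by several
    recovery checks; the fit is deterministic given the seed)."""
    y, z, _, _ = two_branch_data
    model = GPLVM(y, z, GplvmConfig(n_inducing=30, d_X=2, d_B=1,
                                    max_iter=300, seed=0))
    return model, model.fit()


@pytest.fixture(scope="session")
def mixture_fit(gplvm_fit):
    model, fit = gplvm_fit
    mix = GPMixture(model.Y, fit.context(),
                    config=MixtureConfig(K=3, n_restarts=5,
                                         max_em_iter=60, seed=0))
    return mix.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def small_params(seed=0, n=12, j=4, m=5, p=3, d_b=1, d_x=2, jitter=1e-8):
    """A random small GPLVM parameter point for algebra checks."""
    from cellgp.gplvm import GplvmParams
    r = np.random.default_rng(seed)
    z = np.column_stack([np.ones(n), r.normal(size=(n, p - 1))])
    params = GplvmParams(
        zeta=r.normal(size=p) * 0.3,
        delta=np.abs(r.normal(size=p)) * 0.3 + 0.1,
        omega=np.abs(r.normal(size=n)) * 0.3 + 0.7,
        sigma2=np.abs(r.normal(size=j)) + 0.5,
        theta=r.uniform(0, 2 * np.pi, n),
        B=r.normal(size=(n, d_b)),
        X=r.normal(size=(n, d_x)),
        theta_u=r.uniform(0, 2 * np.pi, m),
        B_u=r.normal(size=(m, d_b)),
        X_u=r.normal(size=(m, d_x)),
        ell_theta=0.8, ell_B=1.3, ell_X=1.1, v_gp=0.7, jitter=jitter)
    y = r.normal(size=(n, j))
    return params, y, z
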