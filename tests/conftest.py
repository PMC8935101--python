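import numpy as np
import pandas as pd
import pytest

import hurdlemap as hm


@pytest.fixture(scope="session")
def small_tracts():
    """20 covariate-complete tracts on a 10 km square."""
    tracts = hm.generate_tracts(20, 10_000.0, seed=11)
    return hm.generate_covariates(tracts, seed=12)


@pytest.fixture(scope="session")
def toy_panel():
    """Hand-sized 3-tract x 2-period panel with a printed design matrix."""
    design = pd.DataFrame(
        {"x1": [0.0, 1.0, 2.0], "x2": [1.0, 0.0, -1.0]},
        index=pd.Index([1, 2, 3], name="tract_id"),
    )
    obs = pd.DataFrame(
        {
            "tract_id": [1, 1, 2, 2, 3, 3],
            "period": [1, 2, 1, 2, 1, 2],
            "count": [0, 2, 1, 3, 5, 0],
        }
    )
    centroids = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1500.0]])
    return hm.PanelDataset(
        obs=obs,
        n_trials=pd.Series([50, 80, 120], index=design.index),
        design=design,
        centroids=centroids,
    )


@pytest.fixture(scope="session")
def toy_params():
    return hm.ModelParameters(
        beta_binomial=np.array([-2.0, 0.3, -0.5]),
        beta_poisson=np.array([0.5, -0.2, 0.1]),
        matern=hm.MaternParams(sigma2=0.5, nu=1.0, kappa=hm.kappa_from_range(1.0, 800.0)),
        var_eta=0.3,
        var_tau=0.2,
    )


@pytest.fixture(scope="session")
def toy_latents():
    tau = np.array([0.15, -0.15])
    return hm.LatentEffects(
        eta=np.array([0.1, -0.2, 0.05]), tau=tau, S=np.array([-0.3, 0.2, 0.4])
    )
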