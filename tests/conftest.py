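import numpy as np
import pandas as pd
import pytest

import bbdisp as bb
from bbdisp.dispersion import ThetaObservations


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_obs(n_rows, K, rng, logD=0.0, gamma=0.0, beta=None, noise_sd=0.0,
             strand="sense", depth_median=100.0, depth_sigma=1.0):
    """Synthetic regression dataset drawn straight from the log-linear law
    (no counts involved): log theta = logD + gamma*log depth + seq + noise."""
    depth = depth_median * np.exp(depth_sigma * rng.standard_normal(n_rows))
    bases = np.array(list("ACGT"))
    ctx = np.array(["".join(bases[rng.integers(0, 4, K)]) for _ in range(n_rows)],
                   dtype=f"U{K}")
    seq_eff = np.zeros(n_rows)
    if beta:
        for i, c in enumerate(ctx):
            seq_eff[i] = sum(v for (k, h), v in beta.items() if c[k - 1] == h)
    y = logD + gamma * np.log(depth) + seq_eff + noise_sd * rng.standard_normal(n_rows)
    df = pd.DataFrame({
        "gene_id": "g1", "position": np.arange(n_rows), "strand": strand,
        "theta_hat": np.exp(y), "depth": depth, "context": ctx,
        "floored": False, "invalid": False,
    })
    return ThetaObservations(df)


@pytest.fixture(scope="session")
def replicate_sim():
    """Moderate replicate simulation in the depth-dependent regime, shared
    across tests that only read from it."""
    cfg = bb.SimulationConfig(seed=7, G=60, gene_length=300, median_depth=100.0,
                              depth_sigma=1.0, variant="primer_free", D=1.0,
                              gamma=-1.0, K=8)
    return bb.simulate_replicates(cfg, 4)
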