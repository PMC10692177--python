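import numpy as np
import pytest

import heels as H


@pytest.fixture(scope="session")
def small_panel():
    """n=300, p=30 AR(1) panel with moderate LD, plus one phenotype."""
    cfg = H.SimulationConfig(n=300, p=30, h2=0.3, seed=7, ld_model="ar1", rho=0.6)
    panel = H.simulate_genotypes(cfg)
    Xu = H.standardize(panel, "unit_variance")
    Xm = H.standardize(panel, "model_scale")
    y, beta, causal = H.simulate_phenotype(Xu, cfg)
    stats, R = H.compute_sumstats(Xm, y)
    return {
        "cfg": cfg, "panel": panel, "Xu": Xu, "Xm": Xm,
        "y": y, "beta": beta, "stats": stats, "R": R,
    }


@pytest.fixture(scope="session")
def ld60():
    """p=60 LD matrix from a strongly banded AR(1) panel (n=400)."""
    cfg = H.SimulationConfig(n=400, p=60, h2=0.3, seed=3, ld_model="ar1", rho=0.85)
    panel = H.simulate_genotypes(cfg)
    Xm = H.standardize(panel, "model_scale")
    return Xm.X.T @ Xm.X


def make_fixture(n, p, h2, seed, rho=0.6, polygenicity=1.0):
    """One simulated dataset: panel, phenotype, summary statistics, LD."""
    cfg = H.SimulationConfig(
        n=n, p=p, h2=h2, seed=seed, ld_model="ar1", rho=rho, polygenicity=polygenicity
    )
    panel = H.simulate_genotypes(cfg)
    Xu = H.standardize(panel, "unit_variance")
    Xm = H.standardize(panel, "model_scale")
    y, _, _ = H.simulate_phenotype(Xu, cfg)
    stats, R = H.compute_sumstats(Xm, y)
    return Xm, y, stats, R
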