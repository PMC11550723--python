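"""Shared fixtures: small simulated designs used across the model tests."""

import numpy as np
import pytest

from clocktraj.simulate import SiteTruth, simulate_site


@pytest.fixture(scope="session")
def balanced_design():
    """Factory for a balanced three-visit design (no jitter, no missingness)."""

    def make(n_ind: int, visits=(0.0, 6.0, 10.0)):
        idx = np.repeat(np.arange(n_ind), len(visits))
        ages = np.tile(np.asarray(visits, float), n_ind)
        return idx, ages

    return make


@pytest.fixture(scope="session")
def jittered_design():
    """Factory for a design with jittered childhood ages and missing visits."""

    def make(n_ind: int, seed: int = 0, missing: float = 0.0):
        rng = np.random.default_rng(seed)
        base = np.tile([0.0, 6.0, 10.0], n_ind)
        idx = np.repeat(np.arange(n_ind), 3)
        ages = base + np.where(base > 0, rng.normal(0, 0.4, n_ind * 3), 0.0)
        if missing:
            keep = rng.random(n_ind * 3) >= missing
            keep[::3] = True  # every individual keeps the birth visit
            return idx[keep], ages[keep]
        return idx, ages

    return make


@pytest.fixture
def linear_site_truth():
    return SiteTruth(
        cpg_id="cg_demo",
        archetype="linear",
        mu0=0.5,
        beta_age=0.004,
        sd_intercept=0.02,
        sd_slope=0.002,
        rho_int_slope=0.5,
        sd_resid=0.01,
    )


@pytest.fixture
def simulate_y():
    """Simulate one site's values for a given truth/design/seed."""

    def make(truth: SiteTruth, idx, ages, seed: int = 0):
        y, _ = simulate_site(truth, idx, ages, np.random.default_rng(seed))
        return y

    return make
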