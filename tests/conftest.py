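import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dispscan as ds

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome_map():
    """Full 19-autosome + X map, ~17 cM spacing (99 markers)."""
    return ds.default_map()


@pytest.fixture(scope="session")
def tiny_map():
    """3 autosomes x 6 markers for fast scans."""
    return ds.small_map()


@pytest.fixture(scope="session")
def dminus_cohort(genome_map):
    """n=400 cohort with one negative-dominant vQTL (sigma ratio 2, high A/J)."""
    causal = genome_map.marker_ids[10]
    eff = ds.VqtlEffect.from_preset(causal, "D-", 2.0, "P2")
    cohort, truth = ds.simulate_cohort(
        genome_map, [eff], ds.SimConfig(n=400), seed=11
    )
    return cohort, causal


@pytest.fixture(scope="session")
def null_cohort(tiny_map):
    """Small cohort with no vQTL effects."""
    cohort, _ = ds.simulate_cohort(tiny_map, [], ds.SimConfig(n=250), seed=5)
    return cohort


def make_locus_fit(mu_cc, mu_ca, mu_aa, se=1e-3, sigma=1.0, n=400):
    """A synthetic Tobit fit with prescribed genotype means and tiny SEs.

    Design columns: intercept, CC dummy, CA dummy (AA = reference), so
    beta = (mu_aa, mu_cc - mu_aa, mu_ca - mu_aa).
    """
    beta = np.array([mu_aa, mu_cc - mu_aa, mu_ca - mu_aa])
    vcov = np.zeros((4, 4))
    vcov[:3, :3] = se**2 * np.eye(3)
    vcov[3, 3] = se**2
    fit = ds.TobitFit(
        beta=beta,
        sigma=sigma,
        vcov=vcov,
        loglik=0.0,
        converged=True,
        n=n,
        iterations=0,
        colnames=["intercept", "locus[P1hom]", "locus[het]"],
    )
    return fit


LOCUS_LEVELS = {ds.HOM_P1: 1, ds.HET: 2, ds.HOM_P2: None}


@pytest.fixture
def locus_fit_factory():
    return make_locus_fit
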