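import numpy as np
import pytest

import locindex as L

FIG1 = {
    # two genes of equal length; molecules (nuclear, cytosolic) per cell type
    "lengths": np.array([1000, 1000]),
    "type1": {"m_n": np.array([40, 110]), "m_c": np.array([60, 90])},
    "type2": {"m_n": np.array([40, 20]), "m_c": np.array([60, 180])},
    "depth": 1000,
}


@pytest.fixture(scope="session")
def fig1():
    return FIG1


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale noiseless dataset: expected-mode counts at beta ~ 0.7."""
    config = L.SimConfig(
        n_transcripts=800,
        total_molecules=60_000,
        target_beta=0.7,
        depth_per_fraction=300_000,
        count_mode="expected",
        seed=7,
    )
    samples, truth = L.simulate_dataset(config)
    return config, samples, truth


@pytest.fixture(scope="session")
def small_triplet(small_sim):
    _, samples, _ = small_sim
    w, n, c = (
        samples[L.Fraction.WHOLE],
        samples[L.Fraction.NUCLEAR],
        samples[L.Fraction.CYTOSOLIC],
    )
    retained = L.filter_expression(w, n, c)
    return L.build_triplet(w, n, c, retained)


@pytest.fixture(scope="session")
def noisy_triplet():
    """Multinomial-count dataset small enough for quick MCMC."""
    config = L.SimConfig(
        n_transcripts=500,
        total_molecules=40_000,
        target_beta=0.65,
        depth_per_fraction=200_000,
        count_mode="multinomial",
        seed=13,
    )
    samples, truth = L.simulate_dataset(config)
    w, n, c = (
        samples[L.Fraction.WHOLE],
        samples[L.Fraction.NUCLEAR],
        samples[L.Fraction.CYTOSOLIC],
    )
    triplet = L.build_triplet(w, n, c, L.filter_expression(w, n, c))
    return triplet, truth


QUICK_MCMC = dict(iterations=1200, warmup=400, seed=17)


@pytest.fixture(scope="session")
def quick_posterior(noisy_triplet):
    triplet, _ = noisy_triplet
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return L.sample_posterior(triplet, L.BetaModelConfig(**QUICK_MCMC))
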