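import numpy as np
import pandas as pd
import pytest

from mucimine.synth import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured simulated cohort (planted effects)."""
    cfg = SimulationConfig(
        n_case=12, n_control=12, n_mags=40, n_hmms=40, n_differential=4,
        effect_size=3.0, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_instance(rng, n_mags, n_hmms, n_samples):
    """Random small quantification instance (N, L_kb, G_mb, A) with labels."""
    mags = [f"m{i}" for i in range(n_mags)]
    hmms = [f"h{j}" for j in range(n_hmms)]
    samples = [f"s{k}" for k in range(n_samples)]
    N = pd.DataFrame(rng.integers(0, 5, (n_mags, n_hmms)),
                     index=mags, columns=hmms)
    L = {h: float(rng.uniform(0.3, 1.5)) for h in hmms}
    G = {m: float(rng.uniform(1.0, 8.0)) for m in mags}
    A = pd.DataFrame(rng.uniform(0, 20, (n_mags, n_samples)) *
                     (rng.random((n_mags, n_samples)) > 0.3),
                     index=mags, columns=samples)
    return N, L, G, A
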