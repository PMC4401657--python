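import numpy as np
import pytest
from hypothesis import settings

import pcgsa

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """500 samples x 20 genes x 10 SNPs with strong LD and some missingness."""
    cfg = pcgsa.SimConfig(n_samples=500, n_genes=20, seed=11, missing_rate=0.01)
    ds = pcgsa.simulate_genotypes(cfg)
    return cfg, ds


def exact_corr_pair(n: int, r: float, seed: int = 0) -> np.ndarray:
    """Two columns whose *sample* correlation is exactly r (via Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = a - a.mean()
    a /= np.linalg.norm(a)
    b = b - b.mean()
    b -= (a @ b) * a
    b /= np.linalg.norm(b)
    return np.column_stack([a, r * a + np.sqrt(1 - r**2) * b])


def write_gene_loc(path, locations):
    with open(path, "w") as fh:
        for g in locations:
            fh.write(f"{g.gene_id} {g.chromosome} {g.start_bp} {g.stop_bp}\n")


def write_sets(path, sets: dict):
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write(name + " " + " ".join(members) + "\n")
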