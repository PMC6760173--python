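import numpy as np
import pandas as pd
import pytest

from transloci.io import GenotypePanel
from transloci.synth import PopulationModel, derive_population, simulate_ancestral_haplotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_panel(dosages, chrom="1", start=1_000_000, spacing=500, label="test"):
    """Wrap a raw dosage matrix in a GenotypePanel with synthetic keys."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + np.arange(m) * spacing,
            "ref": "A",
            "alt": "G",
            "rsid": [f"v{i}" for i in range(m)],
        }
    )
    return GenotypePanel(
        sample_ids=[f"s{i}" for i in range(n)],
        variants=variants,
        dosages=dosages,
        population_label=label,
    )


@pytest.fixture(scope="session")
def panel_pair():
    """A small diverged two-population locus shared across tests."""
    model = PopulationModel(n_variants=60, n_ancestral_haplotypes=300, divergence_f=0.1)
    pool = simulate_ancestral_haplotypes(model, seed=11)
    ref = derive_population(pool, 0.1, 600, seed=12, label="reference")
    tgt = derive_population(pool, 0.1, 400, seed=13, label="target")
    keep = np.flatnonzero((ref.dosages.std(0) > 0) & (tgt.dosages.std(0) > 0))
    return ref.subset_variants(keep), tgt.subset_variants(keep)
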