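import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from codonscape.bias_metrics import CodonCounts
from codonscape.synthetic_data import SimConfig, generate_genome


@pytest.fixture(scope="session")
def sim_small():
    """A small two-cluster synthetic study shared across test modules."""
    cfg = SimConfig(
        seed=42,
        n_genes=120,
        S=2,
        separation=0.5,
        mean_len=150,
        flank_width=200,
        mean_introns=2,
        intron_len=(40, 120),
    )
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def sim_small_counts(sim_small):
    return [CodonCounts.from_cds(g.gene_id, g.cds) for g in sim_small.genes]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_codon_counts(rng, max_count: int = 30) -> CodonCounts:
    """A random per-gene codon count table over all degenerate families."""
    from codonscape.genetic_code import DEGENERATE_AAS, FAMILIES

    counts = {}
    for aa in DEGENERATE_AAS:
        for codon in FAMILIES[aa]:
            counts[codon] = int(rng.integers(0, max_count))
    return CodonCounts("random", counts)
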