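import numpy as np
import pandas as pd
import pytest

from mgii import simulate as sim


@pytest.fixture(scope="session")
def diverged_pair():
    """A 100 kb two-genome set at 3% path divergence, shared across tests."""
    spec = sim.SimSpec(seed=11, tree=sim.two_taxon_tree(0.03),
                       ancestor_length=100_000)
    genomes, truth = sim.simulate_genome_set(spec)
    return genomes, truth


@pytest.fixture(scope="session")
def community_run():
    """One full community simulation (40 samples, planted warm/cold block)."""
    from mgii import abundance as ab

    spec, planted = sim.community_scenario(seed=2024)
    genomes, _ = sim.simulate_genome_set(spec)
    counts, env, manifest, truth = sim.simulate_community(spec, genomes)
    lengths = pd.Series({g: genomes[g].total_length for g in genomes})
    rpkm = ab.rpkm(counts, lengths, manifest.set_index("sample")["total_bp"])
    return {"spec": spec, "planted": planted, "genomes": genomes,
            "counts": counts, "env": env, "manifest": manifest,
            "truth": truth, "rpkm": rpkm}


@pytest.fixture
def rng():
    return np.random.default_rng(7)
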