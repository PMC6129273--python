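import numpy as np
import pytest

from cnescan.synth import SynthSpec, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_pair():
    """A small synthetic pair: 30 kb ref, 20 kb query, 8 CNEs, 2 decoys."""
    spec = SynthSpec(
        ref_len=30_000,
        query_len=20_000,
        n_cne=8,
        cne_len_range=(200, 400),
        divergence=0.02,
        n_decoys=2,
        decoy_divergence=0.20,
        exon_density=0.03,
        seed=7,
    )
    return generate_pair(spec)


@pytest.fixture(scope="session")
def small_pair_dir(small_pair, tmp_path_factory):
    """The small pair written to disk (FASTA, truth table, exon GFF3)."""
    outdir = tmp_path_factory.mktemp("small_pair")
    paths = small_pair.write(outdir)
    return paths
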