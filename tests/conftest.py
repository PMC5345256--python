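import logging

import numpy as np
import pytest

from msdaflp import (
    MethylationProfile,
    SynthGenomeSpec,
    build_db,
    generate_genome,
)
from msdaflp.evaluation import make_default_bundle

logging.getLogger("msdaflp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_db():
    """A small synthetic genome's fragment database (1 x 100 kb)."""
    genome, _ = generate_genome(
        SynthGenomeSpec(
            n_chromosomes=1,
            chromosome_length=100_000,
            sbfi_per_chromosome=40,
            seed=3,
        )
    )
    return build_db(genome)


@pytest.fixture(scope="session")
def toy_profile(toy_db):
    """Low-skewed methylation levels for the toy database's CpGs."""
    rng = np.random.default_rng(3)
    cpgs = sorted({f.cpg_key for f in toy_db})
    return MethylationProfile(
        dict(zip(cpgs, rng.beta(2.0, 10.0, size=len(cpgs)).astype(float)))
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default self-contained study bundle (2 x 500 kb, 3 tissues x 3)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return make_default_bundle(outdir, seed=1)
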