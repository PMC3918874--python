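import numpy as np
import pytest

from endosirna.genome import LocusSpec, build_genome


@pytest.fixture(scope="session")
def small_build():
    """20 kb genome with a unique locus and a 4-copy tandem family."""
    specs = [
        LocusSpec("solo", 800, 1, "single", sense_rate=0.1, antisense_rate=0.1),
        LocusSpec("fam4", 600, 4, "tandem", sense_rate=0.05, antisense_rate=0.05),
    ]
    return build_genome(specs, 20_000, seed=42)


@pytest.fixture(scope="session")
def mixed_build():
    """50 kb genome exercising all arrangements, including divergence."""
    specs = [
        LocusSpec("solo", 700, 1, "single"),
        LocusSpec("tan3", 500, 3, "tandem"),
        LocusSpec("disp3", 500, 3, "dispersed"),
        LocusSpec("div2", 1000, 2, "tandem", divergence=0.02),
        LocusSpec("plas5", 400, 5, "extrachromosomal_cluster"),
    ]
    return build_genome(specs, 50_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
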