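import numpy as np
import pytest

from dnamelt import MeltingConditions, random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def oligo_conditions():
    """Worked-example oligonucleotide conditions: 0.22 M Na+, 2 uM strand."""
    return MeltingConditions(na_molar=0.22, strand_conc=2e-6, strand_conc_units="molar")


@pytest.fixture
def genome_conditions():
    """Typical genomic hyperchromicity conditions: 0.016 M Na+, 20 ug/ml DNA."""
    return MeltingConditions(na_molar=0.016, strand_conc=2e-5, strand_conc_units="g_per_ml")


@pytest.fixture(scope="session")
def synthetic_genome():
    """A 50-kb i.i.d. random chromosome at E. coli-like GC content."""
    return random_sequence(50_000, gc_fraction=0.508, rng=np.random.default_rng(7))
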