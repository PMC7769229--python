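import pytest

from flatpeach.haplotype_model import (
    GenomeSegment,
    InversionSpec,
    build_inverted_haplotype,
    build_junction_set,
)
from flatpeach.synthetic_data import generate_reference, plant_inversion_site


@pytest.fixture(scope="session")
def toy_pair():
    """The worked 16-bp example locus: inversion [7, 12) with the ACA/GA signature."""
    h1 = GenomeSegment(id="toy", seq="TTTTACAATGCCGGGG")
    return build_inverted_haplotype(h1, InversionSpec(pb=7, db=12))


@pytest.fixture(scope="session")
def toy_junctions(toy_pair):
    return build_junction_set(toy_pair, flank=4)


@pytest.fixture(scope="session")
def small_locus():
    """A 12-kb locus with a 6-kb inversion, shared across alignment/genotyping tests."""
    ref = generate_reference(12_000, gc=0.42, seed=11)
    planted, spec = plant_inversion_site(ref, 3000, 9000)
    pair = build_inverted_haplotype(planted, spec)
    junctions = build_junction_set(pair, flank=300)
    return pair, junctions
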