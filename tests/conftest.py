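import pytest

from slimscan.formats_io import ChainSequence
from slimscan.msa_coalign import SpeciesTaggedMSA
from slimscan.synthetic_fixtures import FixtureSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_reference():
    """A small groove complex shared by the metric tests."""
    ref, _ = make_toy_complex(FixtureSpec(seed=11, peptide_length=12))
    return ref


@pytest.fixture()
def small_msa_pair():
    """Hand-built receptor/ligand MSAs with taxa {s1,s2,s3} and {s2,s3,s4}."""
    rec = SpeciesTaggedMSA(
        query=ChainSequence("r", "A", "ACDEFG"),
        rows=[("s1", "ACDEFG"), ("s2", "ACDE-G"), ("s3", "AC-EFG")],
    )
    lig = SpeciesTaggedMSA(
        query=ChainSequence("l", "B", "KLMN"),
        rows=[("s2", "KLMN"), ("s3", "K-MN"), ("s4", "KLAN")],
    )
    return rec, lig
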