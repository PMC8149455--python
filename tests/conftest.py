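import pytest

from conskit import AMINO_ACIDS, Alignment, BackgroundComposition


@pytest.fixture(scope="session")
def uniform_bg() -> BackgroundComposition:
    return BackgroundComposition(q={aa: 0.05 for aa in AMINO_ACIDS})


def make_alignment(rows: dict[str, str], query_id: str = "q") -> Alignment:
    """Build an alignment from an id -> residues mapping (insertion ordered)."""
    return Alignment(ids=tuple(rows), rows=tuple(rows.values()), query_id=query_id)


@pytest.fixture
def toy_msa_path():
    from importlib import resources

    ref = resources.files("conskit.data").joinpath("toy_msa.fasta")
    with resources.as_file(ref) as path:
        yield path
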