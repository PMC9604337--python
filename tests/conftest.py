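"""Shared fixtures for the mitocomp test suite."""
from pathlib import Path

import pytest

from mitocomp import GenomeSpec, generate_genome, load_all_references, load_reference

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def henana():
    """Bundled G. henana gene table (sequence-less record)."""
    return load_reference("gryllotalpa_henana")


@pytest.fixture(scope="session")
def all_refs():
    return load_all_references()


@pytest.fixture(scope="session")
def synthetic_genome():
    """Default synthetic mitogenome, seed 0 (henana template, planted motifs)."""
    return generate_genome(GenomeSpec(seed=0))


@pytest.fixture(scope="session")
def mini_genbank_path():
    return DATA_DIR / "mini.gb"
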