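import pytest

from mitocomp.datasets import load_belcheri_table
from mitocomp.simulate import GenomeSpec, simulate_mitogenome


@pytest.fixture(scope="session")
def belcheri():
    """The published P. belcheri annotation table (no sequence)."""
    return load_belcheri_table()


@pytest.fixture(scope="session")
def compact_sim():
    """Overlap-free synthetic mitogenome in canonical teleost order, with its
    ground-truth record; the workhorse for structure-recovery tests."""
    return simulate_mitogenome(GenomeSpec.compact(seed=7))


@pytest.fixture(scope="session")
def table_sim():
    """Synthetic mitogenome on the published P. belcheri coordinates."""
    return simulate_mitogenome(GenomeSpec.from_table(seed=3))
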