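import numpy as np
import pytest

from cmapviz.model import ContactMap, ResidueContact


def random_contact_map(
    rng: np.random.Generator,
    seq_length: int,
    density: float = 0.05,
    min_sep: int = 1,
) -> ContactMap:
    """Random symmetric contact map with scores rounded to 6 decimals.

    Rounding keeps scores exactly representable in RR text, and (unless the
    map is empty) one contact always touches the last residue so the sequence
    length survives serialization; both together make round-trips exact.
    """
    contacts = []
    for i in range(1, seq_length + 1):
        for j in range(i + max(min_sep, 1), seq_length + 1):
            if rng.random() < density:
                contacts.append(ResidueContact(i, j, round(float(rng.random()), 6)))
    if density > 0 and not any(c.j == seq_length for c in contacts) and seq_length > 1:
        contacts.append(ResidueContact(1, seq_length, round(float(rng.random()), 6)))
    return ContactMap(seq_length, contacts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def demo_bundle():
    from cmapviz.fixtures import make_membrane_protein_scenario

    return make_membrane_protein_scenario(seed=1)
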