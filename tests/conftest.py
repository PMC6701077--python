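import csv
from pathlib import Path

import pytest

from unifrag import load_default_scheme, normalize_structure
from unifrag.descriptors import DescriptorVector

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def scheme():
    """The packaged UNIFAC scheme with relations precomputed."""
    s = load_default_scheme()
    s.ensure_descriptors()
    s.ensure_relations()
    return s


@pytest.fixture(scope="session")
def published_descriptors():
    """The printed per-group descriptor values, keyed by group id."""
    out = {}
    with open(DATA_DIR / "table1_descriptors.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            out[int(row["group_id"])] = DescriptorVector(
                zero_free_bonds=row["zero_free_bonds"] == "True",
                simple=row["simple"] == "True",
                n_atoms=int(row["n_atoms"]),
                one_free_bond=row["one_free_bond"] == "True",
                n_hetero=int(row["n_hetero"]),
                in_ring=row["in_ring"] == "True",
                n_triple=int(row["n_triple"]),
                n_double=int(row["n_double"]),
            )
    return out


def mol(smiles):
    return normalize_structure(smiles)


def names(scheme, counts):
    return {scheme.group(g).name: c for g, c in counts.items() if c}
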