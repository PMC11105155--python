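import numpy as np
import pandas as pd
import pytest

from mycocomp.io_formats import DomainAnnotationTable, OrthogroupTable


@pytest.fixture
def small_domain_table() -> DomainAnnotationTable:
    rows = pd.DataFrame(
        [
            ("A", "A_g1", "Lipase_3", "PFAM", True),
            ("A", "A_g1", "Lipase_3", "PFAM", True),  # second copy, same protein
            ("A", "A_g2", "Lipase_3", "PFAM", False),
            ("A", "A_g3", "Trypsin", "PFAM", True),
            ("B", "B_g1", "Lipase_3", "PFAM", False),
            ("B", "B_g2", "Trypsin", "PFAM", False),
            ("B", "B_g3", "BD-FAE", "PFAM", False),
        ],
        columns=["species", "gene_id", "domain_id", "domain_type", "secreted"],
    )
    return DomainAnnotationTable(rows, {"A": 10, "B": 12})


@pytest.fixture
def four_species_ogs() -> OrthogroupTable:
    """10 OGs: 4 core, 3 A+B, 2 A-only, 1 C-only; plus unassigned genes."""
    species = ["A", "B", "C", "D"]

    def og(**kw):
        return {sp: kw.get(sp, []) for sp in species}

    ogs = {
        "OG0000000": og(A=["A_g1"], B=["B_g1"], C=["C_g1"], D=["D_g1"]),
        "OG0000001": og(A=["A_g2", "A_g3"], B=["B_g2"], C=["C_g2"], D=["D_g2"]),
        "OG0000002": og(A=["A_g4"], B=["B_g3"], C=["C_g3"], D=["D_g3"]),
        "OG0000003": og(A=["A_g5"], B=["B_g4"], C=["C_g4"], D=["D_g4"]),
        "OG0000004": og(A=["A_g6"], B=["B_g5"]),
        "OG0000005": og(A=["A_g7"], B=["B_g6"]),
        "OG0000006": og(A=["A_g8"], B=["B_g7"]),
        "OG0000007": og(A=["A_g9", "A_g10"]),
        "OG0000008": og(A=["A_g11"]),
        "OG0000009": og(C=["C_g5"]),
    }
    unassigned = {"A": ["A_u1", "A_u2"], "B": ["B_u1"], "C": [], "D": []}
    return OrthogroupTable(ogs, unassigned)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
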