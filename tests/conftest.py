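import numpy as np
import pytest

from consdeepsignaling import (OmicsTable, PathwayMembership, ResponseRecord,
                               SyntheticSpec, generate)


@pytest.fixture
def tiny_tables():
    """Five aligned toy tables: 4 genes x 3 cell lines, 2 pathways, 2 drugs."""
    genes = ["GA", "GB", "GC", "GD"]
    cells = ["CL1", "CL2", "CL3"]
    expr = OmicsTable("expression", genes, cells,
                      np.array([[2.0, 1.0, 3.0],
                                [0.5, 0.0, 1.5],
                                [1.0, 2.0, 0.5],
                                [4.0, 3.0, 2.0]]))
    cnv = OmicsTable("cnv", genes, cells,
                     np.array([[1, 0, -1],
                               [0, 0, 2],
                               [-2, 1, 0],
                               [0, -1, 1]], dtype=float))
    membership = PathwayMembership({"P1": {"GA", "GB"}, "P2": {"GB", "GC", "GD"}},
                                   ["P1", "P2"])
    targets = {"dA": {"GA"}, "dB": {"GC", "GD"}}
    responses = [ResponseRecord(d, c, 0.5) for d in ("dA", "dB") for c in cells]
    return expr, cnv, targets, membership, responses


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-signal dataset shared across tests (fast to train)."""
    spec = SyntheticSpec(n_genes=30, n_cell_lines=40, n_pathways=4, n_drugs=10,
                         seed=7)
    return spec, generate(spec)
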