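"""Shared fixtures: tiny hand-built inputs and one mid-sized synthetic dataset."""

import numpy as np
import pytest

from coevnet import synthetic_data as sd
from coevnet.io_formats import Alignment, Phylogeny


@pytest.fixture
def small_alignment() -> Alignment:
    return Alignment(
        ids=("s1", "s2", "s3", "s4"),
        rows=("ACD-", "ACDE", "GCDE", "AC-E"),
    )


@pytest.fixture
def three_taxon_tree() -> Phylogeny:
    return Phylogeny.from_newick("(A:0.1,(B:0.1,C:0.1):0.1);")


TOY_PDB = """\
HELIX    1   1 ALA A    2  GLY A    3  1                                   2
ATOM      1  N   MET A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  MET A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  MET A   1       0.500   0.500   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   2       0.000   0.000   3.500  1.00  0.00           C
ATOM      5  CA  GLY A   3       0.000   0.000   7.500  1.00  0.00           C
ATOM      6  CA  LYS B   9       9.000   9.000   9.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture(scope="session")
def neutral_dataset():
    """One 30-taxon, 200-column neutral alignment with tree and times."""
    from coevnet import coevolution_core as cc

    tree = sd.simulate_tree(30, 0.3, seed=7)
    aln, _ = sd.evolve_alignment(tree, 200, seed=8)
    times = cc.divergence_times(aln, "patristic", tree=tree)
    return aln, tree, times


@pytest.fixture(scope="session")
def small_null(neutral_dataset):
    from coevnet import coevolution_core as cc

    aln, tree, times = neutral_dataset
    return cc.build_null(
        aln, tree, times, n_sim_alignments=10, n_samples=20_000, seed=9
    )
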