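"""Shared fixtures: hand-built PDB texts and session-scoped synthetic runs."""

import textwrap

import pytest

from apclass.pipeline import RunConfig, run_pipeline
from apclass.synth import SynthConfig, make_bundle

# Three residues A, C, D with Cα (and SG on the Cys), pLDDT in B-factor.
THREE_RESIDUE_PDB = textwrap.dedent("""\
    ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 90.00           N
    ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 90.00           C
    ATOM      3  CA  CYS A   2       3.800   1.000   0.000  1.00 85.00           C
    ATOM      4  SG  CYS A   2       4.500   1.500   1.600  1.00 85.00           S
    ATOM      5  CA  ASP A   3       7.300   2.000   0.000  1.00 70.00           C
    TER
    END
    """)

# One atom with two altloc conformers: B has higher occupancy and must win.
ALTLOC_PDB = textwrap.dedent("""\
    ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30 90.00           C
    ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.70 90.00           C
    ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00 88.00           C
    ATOM      4  CA  VAL A   3       7.600   0.000   0.000  1.00 87.00           C
    TER
    END
    """)

# Insertion-coded residue (42A) between 42 and 43: sequential renumbering.
ICODE_PDB = textwrap.dedent("""\
    ATOM      1  CA  ALA A  42       0.000   0.000   0.000  1.00 90.00           C
    ATOM      2  CA  GLY A  42A      3.800   0.000   0.000  1.00 88.00           C
    ATOM      3  CA  VAL A  43       7.600   0.000   0.000  1.00 87.00           C
    TER
    END
    """)


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture
def icode_pdb(tmp_path):
    path = tmp_path / "icode.pdb"
    path.write_text(ICODE_PDB)
    return path


@pytest.fixture(scope="session")
def bundle200(tmp_path_factory):
    """The standard synthetic study: 200 genes, census proportions, seed 42."""
    out = tmp_path_factory.mktemp("bundle200")
    config = SynthConfig(seed=42, n_genes=200)
    truth = make_bundle(config, out)
    return out, truth


@pytest.fixture(scope="session")
def pipeline200(bundle200):
    """Full pipeline result on the standard synthetic study."""
    out, truth = bundle200
    config = RunConfig(
        out_dir=str(out / "run"),
        fasta=str(out / "proteins.fasta"),
        msa=str(out / "alignment.fasta"),
        gff=str(out / "genes.gff3"),
        models_dir=str(out / "models"),
        anchors=str(out / "anchors.tsv"),
        reference=str(out / "reference.json"),
        seed=42,
    )
    return run_pipeline(config), truth
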