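import pathlib

import pytest

from macromol.fixtures import (make_assembly, make_ligand_complex,
                               make_polyala, make_strand_pair)

DATA_DIR = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> pathlib.Path:
    return DATA_DIR


@pytest.fixture()
def helix():
    """18-residue ideal alpha helix."""
    return make_polyala(18)


@pytest.fixture()
def strand_pair():
    """Antiparallel two-strand beta pair with H-bond registry."""
    return make_strand_pair(6)


@pytest.fixture()
def ligand_complex():
    return make_ligand_complex(12)


@pytest.fixture()
def c3_trimer():
    chain = make_polyala(12).chains[0]
    return make_assembly(chain, "C3")


def dssp_reference_labels(structure) -> str:
    """8-state labels from the independent reference implementation."""
    import tempfile

    import mdtraj

    from macromol.pdbio import write_pdb

    with tempfile.NamedTemporaryFile("w", suffix=".pdb") as fh:
        fh.write(write_pdb(structure))
        fh.flush()
        traj = mdtraj.load(fh.name)
    labels = mdtraj.compute_dssp(traj, simplified=False)[0]
    return "".join(l if l != " " else "-" for l in labels)
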