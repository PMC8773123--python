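"""Shared fixtures: hand-built PDB texts and synthetic assemblies."""

from __future__ import annotations

import numpy as np
import pytest

from ddmtools import apply_motions, make_ring_assembly
from ddmtools.synthetic import MotionSpec


def pdb_atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
                  xyz: tuple[float, float, float], element: str = "C",
                  record: str = "ATOM", altloc: str = " ", occ: float = 1.0,
                  icode: str = " ") -> str:
    x, y, z = xyz
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:>3} {chain}{resnum:>4}"
        f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


def make_pdb(residues, chain: str = "A", start_serial: int = 1) -> str:
    """PDB text from [(resnum, (x, y, z)), ...] with one CA per residue."""
    lines = []
    serial = start_serial
    for resnum, xyz in residues:
        lines.append(pdb_atom_line(serial, "CA", "GLY", chain, resnum, xyz))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_pdb(tmp_path):
    """3-4-5 right triangle of alpha-carbons."""
    path = tmp_path / "tri.pdb"
    path.write_text(make_pdb([(1, (0, 0, 0)), (2, (3, 0, 0)), (3, (0, 4, 0))]))
    return path


@pytest.fixture
def water_pdb(tmp_path):
    lines = [
        pdb_atom_line(1, "CA", "GLY", "A", 1, (0, 0, 0)),
        pdb_atom_line(2, "CA", "GLY", "A", 2, (3, 0, 0)),
        pdb_atom_line(3, "O", "HOH", "A", 101, (9, 9, 9), element="O", record="HETATM"),
        "END",
    ]
    path = tmp_path / "wat.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    body1 = make_pdb([(1, (0, 0, 0)), (2, (3, 0, 0)), (3, (0, 4, 0))]).replace("END\n", "")
    body2 = make_pdb([(1, (10, 0, 0)), (2, (13, 0, 0)), (3, (10, 4, 0))]).replace("END\n", "")
    text = "MODEL        1\n" + body1 + "ENDMDL\nMODEL        2\n" + body2 + "ENDMDL\nEND\n"
    path = tmp_path / "nmr.pdb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def trimer():
    """3-protomer ring, 12 residues each — the small workhorse assembly."""
    return make_ring_assembly(3, 12, 20.0, seed=11)


@pytest.fixture(scope="session")
def hexamer():
    return make_ring_assembly(6, 12, 20.0, seed=12)


@pytest.fixture(scope="session")
def translated_trimer(trimer):
    """Trimer with protomer A translated 6 Å along +x in state B."""
    model, dmap = trimer
    motion = MotionSpec(block="prot_A", translation=(6.0, 0.0, 0.0))
    state_b, truth = apply_motions(model, dmap, [motion], seed=0)
    return model, state_b, dmap, truth


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    return q, t
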