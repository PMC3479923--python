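"""Shared fixtures: programmatically built PDB text and toy networks."""

from __future__ import annotations

import numpy as np
import pytest


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    altloc: str = " ",
    occupancy: float = 1.0,
    hetatm: bool = False,
    element: str | None = None,
) -> str:
    record = "HETATM" if hetatm else "ATOM"
    element = element or name[0]
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {pad_name}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def tripeptide_pdb_text() -> str:
    """Ala-Gly-Trp with full heavy-atom side chains plus a HETATM water.

    Backbone spacing is ~3.8 A between consecutive C-alphas; coordinates
    are synthetic but sterically sane.
    """
    lines = []
    s = iter(range(1, 100))
    # Ala 1
    lines += [
        pdb_line(next(s), "N", "ALA", "A", 1, (-1.2, 0.3, 0.0)),
        pdb_line(next(s), "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        pdb_line(next(s), "C", "ALA", "A", 1, (1.2, 0.9, 0.3)),
        pdb_line(next(s), "O", "ALA", "A", 1, (1.1, 2.1, 0.4)),
        pdb_line(next(s), "CB", "ALA", "A", 1, (0.3, -1.2, -0.9)),
    ]
    # Gly 2
    lines += [
        pdb_line(next(s), "N", "GLY", "A", 2, (2.5, 0.3, 0.4)),
        pdb_line(next(s), "CA", "GLY", "A", 2, (3.8, 0.9, 0.5)),
        pdb_line(next(s), "C", "GLY", "A", 2, (4.9, 0.0, 1.0)),
        pdb_line(next(s), "O", "GLY", "A", 2, (4.8, -1.2, 1.0)),
    ]
    # Trp 3
    lines += [
        pdb_line(next(s), "N", "TRP", "A", 3, (6.1, 0.6, 1.3)),
        pdb_line(next(s), "CA", "TRP", "A", 3, (7.4, 0.0, 1.5)),
        pdb_line(next(s), "C", "TRP", "A", 3, (8.5, 1.0, 1.8)),
        pdb_line(next(s), "O", "TRP", "A", 3, (8.4, 2.2, 1.6)),
        pdb_line(next(s), "CB", "TRP", "A", 3, (7.7, -0.9, 0.3)),
        pdb_line(next(s), "CG", "TRP", "A", 3, (8.9, -1.8, 0.4)),
        pdb_line(next(s), "CD1", "TRP", "A", 3, (10.2, -1.4, 0.5)),
        pdb_line(next(s), "CD2", "TRP", "A", 3, (8.9, -3.2, 0.4)),
        pdb_line(next(s), "NE1", "TRP", "A", 3, (11.1, -2.5, 0.6)),
        pdb_line(next(s), "CE2", "TRP", "A", 3, (10.3, -3.7, 0.5)),
        pdb_line(next(s), "CE3", "TRP", "A", 3, (7.9, -4.2, 0.3)),
        pdb_line(next(s), "CZ2", "TRP", "A", 3, (10.7, -5.0, 0.5)),
        pdb_line(next(s), "CZ3", "TRP", "A", 3, (8.3, -5.5, 0.3)),
        pdb_line(next(s), "CH2", "TRP", "A", 3, (9.7, -5.9, 0.4)),
    ]
    # a water that must never become a bead
    lines.append(pdb_line(next(s), "O", "HOH", "A", 101, (20.0, 20.0, 20.0), hetatm=True))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def tripeptide_pdb(tmp_path):
    path = tmp_path / "tripeptide.pdb"
    path.write_text(tripeptide_pdb_text())
    return path


@pytest.fixture
def ring_network():
    """Complete-graph 4-bead ring: internally rigid, exactly 6 zero modes."""
    from hbflex.cg_model import build_enm
    from hbflex.synthetic_data import ToyStructureSpec, gen_toy_structure

    # stiff springs keep fluctuations << bond lengths so that nonlinear
    # (curvilinear) corrections to distance statistics stay below ~1%
    beads = gen_toy_structure(ToyStructureSpec(kind="ring", n_residues=4))
    return build_enm(beads, cutoff=9.0, k_spring=60.0)


@pytest.fixture
def bundle_network():
    """Two-helix bundle, 16 residues, connected and rigid."""
    from hbflex.cg_model import build_enm
    from hbflex.synthetic_data import ToyStructureSpec, gen_toy_structure

    beads = gen_toy_structure(ToyStructureSpec(kind="helix_bundle", n_residues=8, n_helices=2))
    return build_enm(beads)


@pytest.fixture
def two_bead_network():
    from hbflex.cg_model import CGBead, build_enm

    beads = [
        CGBead("A", 1, "GLY", "CA", np.array([0.0, 0.0, 0.0])),
        CGBead("A", 2, "GLY", "CA", np.array([5.0, 0.0, 0.0])),
    ]
    return build_enm(beads, cutoff=9.0, k_spring=0.6)
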