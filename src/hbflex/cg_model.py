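"""Coarse-grained bead representation and elastic-network construction.

Each amino acid is reduced to a pseudoatom at the C-alpha position plus one
side-chain bead for small residues or two for large ones (none for Gly); the
placement table ships with the package (``data/sidechain_beads.tsv``).  All
bead pairs closer than a cutoff (default 9 A) are then joined by identical
harmonic springs (default 0.6 kcal mol^-1 A^-2 = 0.42 N m^-1) that are
relaxed at the input-structure geometry.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import kcal_mol_A2_to_N_m  # re-exported: unit conversion lives here

__all__ = [
    "CGBead",
    "Spring",
    "ElasticNetwork",
    "load_sidechain_table",
    "load_pdb",
    "build_cg",
    "build_enm",
    "kcal_mol_A2_to_N_m",
    "expected_bead_count",
]

logger = logging.getLogger(__name__)

#: Default distance cutoff for spring creation, Angstrom.
DEFAULT_CUTOFF: float = 9.0

#: Default uniform spring force constant, kcal mol^-1 A^-2.
DEFAULT_K_SPRING: float = 0.6

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


@dataclass(frozen=True)
class CGBead:
    """One pseudoatom of the reduced model.

    ``role`` is ``CA`` for the backbone bead, ``SC1``/``SC2`` for side-chain
    beads.  ``residue_index`` keeps the author numbering of the source PDB
    and ``icode`` any insertion code.
    """

    chain_id: str
    residue_index: int
    residue_name: str
    role: str
    position: np.ndarray
    icode: str = ""

    @property
    def residue_uid(self) -> tuple[str, int, str]:
        """Hashable residue identity (chain, number, insertion code)."""
        return (self.chain_id, self.residue_index, self.icode)


@dataclass(frozen=True)
class Spring:
    """Harmonic spring between beads ``i < j``, relaxed at ``rest_length``."""

    i: int
    j: int
    rest_length: float
    k_spring: float = DEFAULT_K_SPRING


@dataclass
class ElasticNetwork:
    """Beads plus the complete set of springs within the cutoff."""

    beads: list[CGBead]
    spring_i: np.ndarray
    spring_j: np.ndarray
    rest_length: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    k_spring: float = DEFAULT_K_SPRING

    def __post_init__(self) -> None:
        self.spring_i = np.asarray(self.spring_i, dtype=np.intp)
        self.spring_j = np.asarray(self.spring_j, dtype=np.intp)
        self.rest_length = np.asarray(self.rest_length, dtype=float)
        if np.any(self.spring_i >= self.spring_j):
            raise ValueError("springs must be stored with i < j")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_springs(self) -> int:
        return len(self.spring_i)

    @property
    def positions(self) -> np.ndarray:
        """(n_beads, 3) reference coordinates, Angstrom."""
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def springs(self) -> list[Spring]:
        return [
            Spring(int(i), int(j), float(r), self.k_spring)
            for i, j, r in zip(self.spring_i, self.spring_j, self.rest_length)
        ]

    def bead_table(self) -> pd.DataFrame:
        pos = self.positions
        return pd.DataFrame(
            {
                "index": np.arange(self.n_beads),
                "chain": [b.chain_id for b in self.beads],
                "resid": [b.residue_index for b in self.beads],
                "icode": [b.icode for b in self.beads],
                "resname": [b.residue_name for b in self.beads],
                "role": [b.role for b in self.beads],
                "x": pos[:, 0],
                "y": pos[:, 1],
                "z": pos[:, 2],
            }
        )

    def spring_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.spring_i, "j": self.spring_j, "rest_length": self.rest_length}
        )

    def n_components(self) -> int:
        """Number of connected components of the spring graph."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        n = self.n_beads
        data = np.ones(self.n_springs)
        adj = coo_matrix((data, (self.spring_i, self.spring_j)), shape=(n, n))
        return int(connected_components(adj, directed=False)[0])

    def network_hash(self) -> str:
        """Stable identifier of geometry + topology, for trajectory sidecars."""
        h = hashlib.sha256()
        h.update(np.round(self.positions, 6).tobytes())
        h.update(self.spring_i.tobytes())
        h.update(self.spring_j.tobytes())
        h.update(f"{self.cutoff:.6f}|{self.k_spring:.6f}".encode())
        return h.hexdigest()[:16]

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``PREFIX.beads.tsv`` and ``PREFIX.springs.tsv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        bead_path = prefix.with_name(prefix.name + ".beads.tsv")
        spring_path = prefix.with_name(prefix.name + ".springs.tsv")
        header = (
            f"# hbflex elastic network; cutoff_A={self.cutoff}; "
            f"k_spring_kcal_mol_A2={self.k_spring}; hash={self.network_hash()}\n"
        )
        for path, table in ((bead_path, self.bead_table()), (spring_path, self.spring_table())):
            with open(path, "w") as fh:
                fh.write(header)
                table.to_csv(fh, sep="\t", index=False)
        return bead_path, spring_path

    @classmethod
    def read(cls, prefix: str | Path) -> "ElasticNetwork":
        prefix = Path(prefix)
        bead_path = prefix.with_name(prefix.name + ".beads.tsv")
        spring_path = prefix.with_name(prefix.name + ".springs.tsv")
        with open(bead_path) as fh:
            meta = fh.readline()
        kv = dict(
            item.strip().split("=")
            for item in meta.lstrip("# ").split(";")
            if "=" in item
        )
        beads_df = pd.read_csv(bead_path, sep="\t", comment="#",
                               keep_default_na=False, dtype={"icode": str, "chain": str})
        springs_df = pd.read_csv(spring_path, sep="\t", comment="#")
        beads = [
            CGBead(
                chain_id=str(r.chain),
                residue_index=int(r.resid),
                residue_name=str(r.resname),
                role=str(r.role),
                position=np.array([r.x, r.y, r.z], dtype=float),
                icode=str(r.icode),
            )
            for r in beads_df.itertuples()
        ]
        return cls(
            beads=beads,
            spring_i=springs_df["i"].to_numpy(),
            spring_j=springs_df["j"].to_numpy(),
            rest_length=springs_df["rest_length"].to_numpy(),
            cutoff=float(kv.get("cutoff_A", DEFAULT_CUTOFF)),
            k_spring=float(kv.get("k_spring_kcal_mol_A2", DEFAULT_K_SPRING)),
        )


def load_sidechain_table() -> dict[str, list[tuple[str, list[str]]]]:
    """Load the side-chain bead mapping as ``{resname: [(role, atoms), ...]}``."""
    table: dict[str, list[tuple[str, list[str]]]] = {}
    path = resources.files("hbflex.data").joinpath("sidechain_beads.tsv")
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        resname, role, atoms = line.split("\t")
        table.setdefault(resname, []).append((role, atoms.split(",")))
    table["GLY"] = []
    return table


def expected_bead_count(sequence: Iterable[str]) -> int:
    """Number of beads the mapping table assigns to a 3-letter-code sequence."""
    table = load_sidechain_table()
    n = 0
    for resname in sequence:
        n += 1 + len(table.get(resname.upper(), []))
    return n


def load_pdb(path: str | Path, model: int = 1):
    """Read a PDB file into a biotite ``AtomArray``.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer (first in file on ties, biotite's convention).
    """
    from biotite.structure.io.pdb import PDBFile

    pdb_file = PDBFile.read(str(path))
    return pdb_file.get_structure(model=model, altloc="occupancy")


def build_cg(structure, chain_filter: set[str] | None = None) -> list[CGBead]:
    """Build the coarse-grained bead list from a biotite ``AtomArray``.

    Hetero groups (haem, waters, ions) are excluded; the prosthetic group is
    deliberately not represented.  Bead order is chain-major, residue
    ascending, with roles CA -> SC1 -> SC2 within a residue.  Residues
    without a C-alpha atom are skipped with a warning; side-chain beads with
    some atoms missing are placed from the atoms present.
    """
    import biotite.structure as struc

    table = load_sidechain_table()
    mask = ~structure.hetero
    if chain_filter is not None:
        mask &= np.isin(structure.chain_id, sorted(chain_filter))
    atoms = structure[mask]
    if atoms.array_length() == 0:
        raise ValueError("no protein residues found in structure")

    beads: list[CGBead] = []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        res = atoms[s:e]
        resname = str(res.res_name[0]).upper()
        chain = str(res.chain_id[0])
        resid = int(res.res_id[0])
        icode = str(res.ins_code[0]) if hasattr(res, "ins_code") else ""
        names = list(res.atom_name)
        if "CA" not in names:
            logger.warning("residue %s %s%d has no CA atom; skipped", resname, chain, resid)
            continue
        ca_pos = np.asarray(res.coord[names.index("CA")], dtype=float)
        beads.append(CGBead(chain, resid, resname, "CA", ca_pos, icode))

        if resname not in table:
            if resname != "GLY":
                logger.warning(
                    "residue %s %s%d not in mapping table; CA bead only", resname, chain, resid
                )
            continue
        sidechain_coords = {
            n: np.asarray(c, dtype=float)
            for n, c in zip(names, res.coord)
            if n not in _BACKBONE_ATOMS and not n.startswith(("H", "D"))
        }
        for role, wanted in table[resname]:
            present = [sidechain_coords[a] for a in wanted if a in sidechain_coords]
            if not present:
                # fall back to any side-chain heavy atoms so the bead count
                # stays faithful to the mapping for incomplete residues
                present = list(sidechain_coords.values())
                if not present:
                    warnings.warn(
                        f"residue {resname} {chain}{resid}: no side-chain atoms; "
                        f"{role} bead skipped"
                    )
                    continue
                warnings.warn(
                    f"residue {resname} {chain}{resid}: atoms for {role} missing; "
                    "bead placed from available side-chain atoms"
                )
            elif len(present) < len(wanted):
                warnings.warn(
                    f"residue {resname} {chain}{resid}: incomplete side chain; "
                    f"{role} placed from {len(present)}/{len(wanted)} atoms"
                )
            beads.append(
                CGBead(chain, resid, resname, role, np.mean(present, axis=0), icode)
            )

    if not any(b.role == "CA" for b in beads):
        raise ValueError("no protein residues with CA atoms found")
    return beads


def build_enm(
    beads: Sequence[CGBead],
    cutoff: float = DEFAULT_CUTOFF,
    k_spring: float = DEFAULT_K_SPRING,
) -> ElasticNetwork:
    """Join every bead pair strictly closer than ``cutoff`` with one spring.

    The comparison is strict (``distance < cutoff``); a pair at exactly the
    cutoff is not joined.  Springs are relaxed at the input geometry, so the
    rest length is the observed inter-bead distance.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if len(beads) < 2:
        raise ValueError("need at least two beads to build a network")

    pos = np.array([b.position for b in beads], dtype=float)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")  # distance <= cutoff
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        dists = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
        keep = dists < cutoff  # enforce the strict boundary convention
        pairs, dists = pairs[keep], dists[keep]
    else:
        pairs = np.empty((0, 2), dtype=np.intp)
        dists = np.empty(0)

    network = ElasticNetwork(
        beads=list(beads),
        spring_i=pairs[:, 0] if len(pairs) else np.empty(0, dtype=np.intp),
        spring_j=pairs[:, 1] if len(pairs) else np.empty(0, dtype=np.intp),
        rest_length=dists,
        cutoff=cutoff,
        k_spring=k_spring,
    )

    n_comp = network.n_components()
    if n_comp > 1:
        warnings.warn(f"network is disconnected ({n_comp} components)")
    logger.info("built ENM: %d beads, %d springs", network.n_beads, network.n_springs)
    return network
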