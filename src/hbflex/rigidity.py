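"""Per-residue effective force constants from simulated fluctuations.

For each pseudoatom i the scalar coordinate followed is d_i, the mean
distance from i to all other pseudoatoms j, excluding (a) beads of i's own
residue and (b), when i is a C-alpha, the C-alpha beads of the two
sequence-adjacent residues.  The effective force constant is

    k_i = 3 k_B T / < (d_i - <d_i>)^2 >

with the average taken over the (post-equilibration) simulation frames, and
a residue's force constant is the mean of its beads' k_i.  The ordered
sequence of residue force constants is the protein's rigidity profile;
profiles of two homologous structures are compared residue-by-residue via
Delta-k.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .brownian_dynamics import Trajectory
from .cg_model import ElasticNetwork
from .constants import KB_KCAL

__all__ = [
    "mean_distance_series",
    "distance_series_matrix",
    "particle_force_constant",
    "residue_profile",
    "monomer_profiles",
    "delta_profile",
    "attach_helix_labels",
]

logger = logging.getLogger(__name__)

#: Prefactor of the force-constant estimator (3 k_B T / var by default).
DEFAULT_PREFACTOR: float = 3.0

#: Fraction of initial frames discarded as equilibration for BD trajectories.
DEFAULT_DISCARD: float = 0.10


def _partner_mask(
    network: ElasticNetwork,
    exclude_adjacent_ca: bool = True,
    restrict_chain: str | None = None,
) -> np.ndarray:
    """Boolean (n, n) mask: partners j counted in d_i (row i)."""
    beads = network.beads
    n = len(beads)
    uids = [b.residue_uid for b in beads]
    chains = np.array([b.chain_id for b in beads])
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)

    # same-residue exclusion
    uid_codes = pd.factorize(pd.Series(uids))[0]
    mask &= uid_codes[:, None] != uid_codes[None, :]

    if exclude_adjacent_ca:
        # adjacent C-alpha exclusion: CA(m) <-> CA(m +/- 1) in the same chain
        ca_idx = [k for k, b in enumerate(beads) if b.role == "CA"]
        by_key = {(beads[k].chain_id, beads[k].residue_index, beads[k].icode): k for k in ca_idx}
        for k in ca_idx:
            b = beads[k]
            for step in (-1, 1):
                nb = by_key.get((b.chain_id, b.residue_index + step, b.icode))
                if nb is not None:
                    mask[k, nb] = False
                    mask[nb, k] = False

    if restrict_chain is not None:
        in_chain = chains == restrict_chain
        mask &= in_chain[None, :]  # partners restricted to the monomer
        mask[~in_chain, :] = False

    return mask


def _retained_frames(traj: Trajectory, discard_fraction: float) -> np.ndarray:
    if traj.kind == "equilibrium":
        return traj.frames  # i.i.d. frames need no equilibration discard
    n_skip = int(np.floor(discard_fraction * traj.n_frames))
    frames = traj.frames[n_skip:]
    if len(frames) == 0:
        raise ValueError("equilibration discard leaves no frames")
    return frames


def distance_series_matrix(
    traj: Trajectory,
    network: ElasticNetwork,
    exclude_adjacent_ca: bool = True,
    restrict_chain: str | None = None,
    discard_fraction: float = DEFAULT_DISCARD,
) -> np.ndarray:
    """d_i for every particle and retained frame, shape (n_frames, n_beads).

    Entries for particles whose exclusions leave no partners are NaN.
    """
    mask = _partner_mask(network, exclude_adjacent_ca, restrict_chain)
    counts = mask.sum(axis=1).astype(float)
    frames = _retained_frames(traj, discard_fraction)
    out = np.empty((len(frames), network.n_beads))
    with np.errstate(invalid="ignore", divide="ignore"):
        for f, pos in enumerate(frames):
            dists = cdist(pos, pos)
            out[f] = np.where(counts > 0, (dists * mask).sum(axis=1) / counts, np.nan)
    return out


def mean_distance_series(
    traj: Trajectory,
    network: ElasticNetwork,
    particle: int,
    exclude_adjacent_ca: bool = True,
    restrict_chain: str | None = None,
    discard_fraction: float = DEFAULT_DISCARD,
) -> np.ndarray:
    """Per-frame mean distance d_i of one particle (see module docstring)."""
    mask = _partner_mask(network, exclude_adjacent_ca, restrict_chain)[particle]
    if not mask.any():
        raise ValueError(f"particle {particle}: exclusions leave no partners")
    frames = _retained_frames(traj, discard_fraction)
    partners = np.where(mask)[0]
    diffs = frames[:, partners, :] - frames[:, [particle], :]
    return np.linalg.norm(diffs, axis=2).mean(axis=1)


def particle_force_constant(
    d_series: np.ndarray,
    temperature: float,
    prefactor: float = DEFAULT_PREFACTOR,
    min_frames: int = 100,
) -> float:
    """Effective force constant 3 k_B T / var(d_i), kcal mol^-1 A^-2."""
    d = np.asarray(d_series, dtype=float)
    if len(d) < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {len(d)}")
    var = float(np.var(d))
    if var <= 0.0:
        raise ValueError("frozen particle: zero variance of d_i")
    return prefactor * KB_KCAL * temperature / var


def residue_profile(
    traj: Trajectory,
    network: ElasticNetwork,
    temperature: float,
    exclude_adjacent_ca: bool = True,
    restrict_chain: str | None = None,
    prefactor: float = DEFAULT_PREFACTOR,
    discard_fraction: float = DEFAULT_DISCARD,
) -> pd.DataFrame:
    """Rigidity profile: one row per residue, ordered as in the network.

    Columns: chain, resid, icode, resname, k (kcal mol^-1 A^-2).  The
    residue force constant is the arithmetic mean over the residue's beads.
    """
    dmat = distance_series_matrix(
        traj, network, exclude_adjacent_ca, restrict_chain, discard_fraction
    )
    if dmat.shape[0] < 2:
        raise ValueError("need at least two frames for a variance")
    var = np.var(dmat, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        k_bead = prefactor * KB_KCAL * temperature / var
    beads = network.beads
    sel = (
        range(len(beads))
        if restrict_chain is None
        else [i for i, b in enumerate(beads) if b.chain_id == restrict_chain]
    )
    rows: dict[tuple, dict] = {}
    for i in sel:
        b = beads[i]
        if not np.isfinite(k_bead[i]):
            raise ValueError(
                f"particle {i} ({b.residue_name} {b.chain_id}{b.residue_index}) "
                "has no valid force constant (no partners or zero variance)"
            )
        rec = rows.setdefault(
            b.residue_uid,
            {"chain": b.chain_id, "resid": b.residue_index, "icode": b.icode,
             "resname": b.residue_name, "ks": []},
        )
        rec["ks"].append(k_bead[i])
    profile = pd.DataFrame(
        [
            {
                "chain": r["chain"],
                "resid": r["resid"],
                "icode": r["icode"],
                "resname": r["resname"],
                "k": float(np.mean(r["ks"])),
            }
            for r in rows.values()
        ]
    )
    profile.attrs["temperature"] = temperature
    profile.attrs["prefactor"] = prefactor
    return profile


def monomer_profiles(
    traj: Trajectory,
    network: ElasticNetwork,
    temperature: float,
    chains: Sequence[str] | None = None,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Domain-separated rigidity profile per chain.

    Domain separation restricts the partner set of d_i to beads of the same
    chain, removing rigid-body contributions of the inter-subunit motion.
    ``chains`` limits the computation to a subset (e.g. to skip short
    linker chains whose exclusions leave no partners).  With a single-chain
    network this returns the whole-network profile with a warning.
    """
    all_chains = sorted({b.chain_id for b in network.beads})
    if len(all_chains) < 2:
        warnings.warn("network has a single chain; monomer profile equals full profile")
        return {all_chains[0]: residue_profile(traj, network, temperature, **kwargs)}
    selected = list(chains) if chains is not None else all_chains
    return {
        c: residue_profile(traj, network, temperature, restrict_chain=c, **kwargs)
        for c in selected
    }


def delta_profile(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    residue_mapping: Mapping[tuple[str, int], tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Residue-wise force-constant difference Delta-k = k_A - k_B.

    The default correspondence pairs residues with the same chain label and
    residue number; an explicit mapping {(chain_A, resid_A): (chain_B,
    resid_B)} built from an external alignment may be supplied instead.
    Only residues present in both profiles appear; the rest are reported in
    ``df.attrs['unmapped_a' / 'unmapped_b']``.
    """
    a = profile_a.set_index(["chain", "resid"])
    b = profile_b.set_index(["chain", "resid"])
    if residue_mapping is None:
        residue_mapping = {idx: idx for idx in a.index}
    pairs = [
        (ka, kb) for ka, kb in residue_mapping.items() if ka in a.index and kb in b.index
    ]
    if not pairs:
        raise ValueError("empty residue mapping between profiles")
    recs = []
    for ka, kb in pairs:
        recs.append(
            {
                "chain": ka[0],
                "resid": ka[1],
                "resname": a.loc[ka, "resname"],
                "k_a": float(a.loc[ka, "k"]),
                "k_b": float(b.loc[kb, "k"]),
                "dk": float(a.loc[ka, "k"] - b.loc[kb, "k"]),
            }
        )
    out = pd.DataFrame(recs)
    mapped_a = {ka for ka, _ in pairs}
    mapped_b = {kb for _, kb in pairs}
    out.attrs["unmapped_a"] = sorted(set(a.index) - mapped_a)
    out.attrs["unmapped_b"] = sorted(set(b.index) - mapped_b)
    return out


def _helix_table() -> pd.DataFrame:
    from importlib import resources

    path = resources.files("hbflex.data").joinpath("globin_helices.tsv")
    return pd.read_csv(path, sep="\t", comment="#",
                       names=["chain_kind", "helix", "start", "end"])


def attach_helix_labels(profile: pd.DataFrame, chain_kind: str) -> pd.DataFrame:
    """Add globin helix-position labels (e.g. ``G3``) to a profile.

    ``chain_kind`` is ``"alpha"`` or ``"beta"``; residues outside the
    canonical helices get an empty label.  Labels are positional names used
    in the globin literature, not a secondary-structure computation.
    """
    table = _helix_table()
    table = table[table.chain_kind == chain_kind]
    labels = []
    for resid in profile["resid"]:
        lab = ""
        for row in table.itertuples():
            if row.start <= resid <= row.end:
                lab = f"{row.helix}{resid - row.start + 1}"
                break
        labels.append(lab)
    out = profile.copy()
    out["helix_label"] = labels
    return out
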