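"""Distance-fluctuation rigidity profiles and Delta-k comparisons."""

import numpy as np
import pandas as pd
import pytest

from hbflex.brownian_dynamics import BDConfig, Trajectory, propagate, sample_equilibrium
from hbflex.cg_model import CGBead, build_enm
from hbflex.constants import KB_KCAL
from hbflex.rigidity import (
    attach_helix_labels,
    delta_profile,
    mean_distance_series,
    monomer_profiles,
    particle_force_constant,
    residue_profile,
)
from hbflex.synthetic_data import ToyStructureSpec, gen_toy_structure, tetramer_standin


def _static_traj(positions_per_frame, net):
    """Wrap explicit frame coordinates as an equilibrium-kind trajectory."""
    return Trajectory(
        frames=np.asarray(positions_per_frame, dtype=float),
        frame_interval_fs=None,
        config=None,
        network_hash=net.network_hash(),
        kind="equilibrium",
    )


def test_mean_distance_is_arithmetic_mean():
    """Partners at 4 A and 6 A give d_i = 5 A."""
    beads = [
        CGBead("A", 1, "GLY", "CA", np.array([0.0, 0.0, 0.0])),
        CGBead("A", 3, "GLY", "CA", np.array([4.0, 0.0, 0.0])),
        CGBead("A", 5, "GLY", "CA", np.array([0.0, 6.0, 0.0])),
    ]
    net = build_enm(beads)
    traj = _static_traj([net.positions], net)
    d = mean_distance_series(traj, net, 0)
    assert d[0] == pytest.approx(5.0)


def test_adjacent_calpha_exclusion_hand_enumerated():
    """Middle residue of a 5-residue chain averages over residues m+/-2 only."""
    beads = gen_toy_structure(ToyStructureSpec(kind="chain", n_residues=5))
    net = build_enm(beads)
    traj = _static_traj([net.positions], net)
    # bead 2 sits at x = 7.6; partners after exclusions: beads 0 and 4
    d_on = mean_distance_series(traj, net, 2, exclude_adjacent_ca=True)
    assert d_on[0] == pytest.approx(7.6)
    d_off = mean_distance_series(traj, net, 2, exclude_adjacent_ca=False)
    assert d_off[0] == pytest.approx((3.8 + 3.8 + 7.6 + 7.6) / 4.0)
    assert d_on[0] != d_off[0]


def test_same_residue_beads_always_excluded(tripeptide_pdb):
    from hbflex.cg_model import build_cg, load_pdb

    beads = build_cg(load_pdb(tripeptide_pdb))
    net = build_enm(beads)
    traj = _static_traj([net.positions], net)
    # bead 3 = Trp CA; partners exclude Trp SC1/SC2 and both adjacent CAs...
    # remaining: Ala CA is adjacent?  Ala is residue 1, Trp is residue 3:
    # only Gly (residue 2) CA is adjacent; partners = {Ala CA, Ala SC1}
    pos = net.positions
    expected = np.mean(
        [np.linalg.norm(pos[3] - pos[0]), np.linalg.norm(pos[3] - pos[1])]
    )
    assert mean_distance_series(traj, net, 3)[0] == pytest.approx(expected)


def test_exclusions_leaving_no_partner_is_error():
    beads = gen_toy_structure(ToyStructureSpec(kind="chain", n_residues=3))
    net = build_enm(beads)
    traj = _static_traj([net.positions], net)
    with pytest.raises(ValueError, match="no partners"):
        mean_distance_series(traj, net, 1)  # middle of 3: both partners excluded


def test_particle_force_constant_generative_roundtrip():
    """i.i.d. normal d-series with var 3kBT/k0 recovers k0 within 5%."""
    rng = np.random.default_rng(0)
    T, k0 = 300.0, 2.5
    sigma = np.sqrt(3 * KB_KCAL * T / k0)
    d = 10.0 + rng.normal(0.0, sigma, size=10_000)
    assert particle_force_constant(d, T) == pytest.approx(k0, rel=0.05)


def test_force_constant_linear_in_temperature():
    rng = np.random.default_rng(1)
    d = 10.0 + rng.normal(0.0, 0.5, size=5000)
    assert particle_force_constant(d, 600.0) == pytest.approx(
        2.0 * particle_force_constant(d, 300.0)
    )


def test_force_constant_input_validation():
    with pytest.raises(ValueError, match="frames"):
        particle_force_constant(np.ones(10), 300.0)
    with pytest.raises(ValueError, match="frozen"):
        particle_force_constant(np.ones(200), 300.0)


def test_residue_k_is_mean_over_bead_ks(tripeptide_pdb):
    """Profile values equal the mean of per-bead estimates from the same frames."""
    from hbflex.cg_model import build_cg, load_pdb

    beads = build_cg(load_pdb(tripeptide_pdb))
    net = build_enm(beads)
    traj = sample_equilibrium(net, 300.0, n_frames=500, seed=4)
    prof = residue_profile(traj, net, 300.0).set_index("resid")
    # residue 3 (Trp) has three beads: indices 3, 4, 5
    ks = [
        particle_force_constant(mean_distance_series(traj, net, i), 300.0, min_frames=2)
        for i in (3, 4, 5)
    ]
    assert prof.loc[3, "k"] == pytest.approx(np.mean(ks), rel=1e-9)


def test_delta_profile_identity_and_antisymmetry(bundle_network):
    traj = sample_equilibrium(bundle_network, 300.0, n_frames=400, seed=2)
    prof = residue_profile(traj, bundle_network, 300.0)
    dd = delta_profile(prof, prof)
    assert np.allclose(dd["dk"], 0.0)
    traj2 = sample_equilibrium(bundle_network, 300.0, n_frames=400, seed=3)
    prof2 = residue_profile(traj2, bundle_network, 300.0)
    ab = delta_profile(prof, prof2)
    ba = delta_profile(prof2, prof)
    np.testing.assert_allclose(ab["dk"].to_numpy(), -ba["dk"].to_numpy(), atol=1e-9)


def test_delta_profile_empty_mapping_rejected(bundle_network):
    traj = sample_equilibrium(bundle_network, 300.0, n_frames=200, seed=2)
    prof = residue_profile(traj, bundle_network, 300.0)
    other = prof.copy()
    other["chain"] = "Z"
    with pytest.raises(ValueError, match="mapping"):
        delta_profile(prof, other)


def test_cluster_beads_stiffer_than_linker():
    """Compact clusters out-rank the sparse linker chain in rigidity."""
    beads = gen_toy_structure(ToyStructureSpec(kind="two_cluster", n_residues=26))
    net = build_enm(beads)
    traj = sample_equilibrium(net, 300.0, n_frames=2000, seed=6)
    prof = residue_profile(traj, net, 300.0)
    k_cluster = prof[prof.chain.isin(["A", "B"])]["k"].min()
    k_linker = prof[prof.chain == "C"]["k"].max()
    assert k_cluster > k_linker


def test_identical_chains_have_identical_monomer_profiles():
    """Four symmetry-equivalent helices give matching monomer profiles."""
    net = build_enm(tetramer_standin(n_residues=14))
    traj = sample_equilibrium(net, 300.0, n_frames=6000, seed=7)
    profs = monomer_profiles(traj, net, 300.0)
    assert set(profs) == {"A", "B", "C", "D"}
    ref = profs["A"]["k"].to_numpy()
    for chain in "BCD":
        np.testing.assert_allclose(profs[chain]["k"].to_numpy(), ref, rtol=0.15)


def test_monomer_profile_removes_intersubunit_softening():
    """Domain separation discards the dominant inter-cluster fluctuation."""
    beads = gen_toy_structure(ToyStructureSpec(kind="two_cluster", n_residues=26))
    net = build_enm(beads)
    traj = sample_equilibrium(net, 300.0, n_frames=2000, seed=8)
    complex_prof = residue_profile(traj, net, 300.0)
    # the 2-bead linker chain is skipped: its exclusions leave no partners
    mono = monomer_profiles(traj, net, 300.0, chains=["A", "B"])
    for chain in ("A", "B"):
        k_mono = mono[chain].set_index("resid")["k"]
        k_full = complex_prof[complex_prof.chain == chain].set_index("resid")["k"]
        # within the monomer everything is stiff; the complex profile is
        # softened by the inter-cluster swinging for every residue
        assert (k_mono > k_full).all()


def test_single_chain_monomer_profile_warns(ring_network):
    traj = sample_equilibrium(ring_network, 300.0, n_frames=300, seed=1)
    with pytest.warns(UserWarning, match="single chain"):
        profs = monomer_profiles(traj, ring_network, 300.0)
    assert list(profs) == ["A"]


def test_profile_scales_linearly_with_sampling_temperature(ring_network):
    """Resampling the ensemble at 2T doubles variances; k stays ~constant,
    while evaluating the estimator at 2T on the same frames doubles k."""
    t1 = sample_equilibrium(ring_network, 300.0, n_frames=3000, seed=11)
    k_300 = residue_profile(t1, ring_network, 300.0)["k"].to_numpy()
    k_600_same_frames = residue_profile(t1, ring_network, 600.0)["k"].to_numpy()
    np.testing.assert_allclose(k_600_same_frames, 2.0 * k_300, rtol=1e-12)
    t2 = sample_equilibrium(ring_network, 600.0, n_frames=3000, seed=11)
    k_600 = residue_profile(t2, ring_network, 600.0)["k"].to_numpy()
    np.testing.assert_allclose(k_600, k_300, rtol=0.10)


def test_bd_profile_matches_gaussian_ensemble_oracle():
    """BD-sampled residue force constants track the analytic ensemble <=10%.

    Low friction (small bead radius) shortens relaxation times so a 2 ns
    free-draining run decorrelates well; equilibrium statistics are
    friction-independent.
    """
    rng = np.random.default_rng(5)
    pos: list[np.ndarray] = []
    while len(pos) < 20:  # compact blob, min separation 3.2 A
        p = rng.uniform(0, 11, 3)
        if all(np.linalg.norm(p - q) > 3.2 for q in pos):
            pos.append(p)
    beads = [CGBead("A", i + 1, "GLY", "CA", p) for i, p in enumerate(pos)]
    net = build_enm(beads, k_spring=3.0)
    assert net.n_beads <= 50
    cfg = BDConfig(
        n_steps=200_000, dt_fs=5.0, temperature=300.0, seed=13,
        save_every=20, bead_radius_A=0.5,
    )
    traj_bd = propagate(net, cfg)
    traj_eq = sample_equilibrium(net, 300.0, n_frames=40_000, seed=14)
    k_bd = residue_profile(traj_bd, net, 300.0)["k"].to_numpy()
    k_eq = residue_profile(traj_eq, net, 300.0)["k"].to_numpy()
    np.testing.assert_allclose(k_bd, k_eq, rtol=0.10)


def test_helix_labels_positional():
    prof = pd.DataFrame(
        {"chain": ["A"] * 3, "resid": [96, 99, 45], "icode": [""] * 3,
         "resname": ["VAL", "LYS", "GLY"], "k": [1.0, 2.0, 3.0]}
    )
    lab = attach_helix_labels(prof, "alpha")
    assert list(lab["helix_label"]) == ["G3", "G6", ""]
    lab_b = attach_helix_labels(
        pd.DataFrame({"chain": ["B"] * 2, "resid": [101, 104], "icode": [""] * 2,
                      "resname": ["GLU", "ARG"], "k": [1.0, 1.0]}),
        "beta",
    )
    assert list(lab_b["helix_label"]) == ["G3", "G6"]
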