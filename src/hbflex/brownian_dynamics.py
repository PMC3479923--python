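"""Overdamped Brownian dynamics of the elastic network.

The propagator is the first-order Ermak-McCammon scheme: for each step

    dr = (D / k_B T) F dt + g,   g ~ N(0, 2 D dt)

with a diagonal, identical-per-bead diffusion matrix in the free-draining
default.  Hydrodynamic coupling through the Rotne-Prager-Yamakawa mobility
tensor is available but off by default: it changes relaxation times, not the
equilibrium (Boltzmann) statistics that the rigidity analysis consumes.

The module also provides the analytic Gaussian equilibrium of the network
(`equilibrium_covariance`) and i.i.d. sampling from it
(`sample_equilibrium`); both serve as independent routes to the same
harmonic ensemble that BD samples in time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cg_model import ElasticNetwork
from .constants import KB_KCAL

__all__ = [
    "BDConfig",
    "Trajectory",
    "stokes_friction",
    "propagate",
    "enm_hessian",
    "equilibrium_covariance",
    "sample_equilibrium",
]

#: Dynamic viscosity of water at ~300 K, Pa s.
WATER_VISCOSITY_PA_S = 0.89e-3

#: Boltzmann constant, J K^-1 (for friction/diffusion in SI-derived units).
_KB_J = 1.380649e-23

#: Maximum per-step displacement before the integrator aborts, Angstrom.
_MAX_STEP_A = 10.0


def stokes_friction(bead_radius_A: float, temperature: float) -> float:
    """Translational friction coefficient from Stokes' law.

    Returned in units such that ``D = k_B T / friction`` is in A^2 fs^-1
    when ``k_B T`` is in kcal mol^-1.  Only relaxation times depend on this
    choice; equilibrium averages do not.
    """
    gamma_si = 6.0 * np.pi * WATER_VISCOSITY_PA_S * bead_radius_A * 1e-10  # kg/s
    d_si = _KB_J * temperature / gamma_si  # m^2/s
    d_A2_fs = d_si * 1e20 / 1e15
    return KB_KCAL * temperature / d_A2_fs


@dataclass
class BDConfig:
    """Run parameters for :func:`propagate`.

    Defaults follow the simulation protocol the package targets: 200 000
    steps of 10 fs at 300 K (a 2 ns span).
    """

    n_steps: int = 200_000
    dt_fs: float = 10.0
    temperature: float = 300.0
    seed: int = 0
    hydrodynamics: bool = False
    bead_radius_A: float = 3.0
    friction_per_bead: float | None = None  # kcal mol^-1 fs A^-2; Stokes if None
    save_every: int = 10

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")

    @property
    def friction(self) -> float:
        if self.friction_per_bead is not None:
            return self.friction_per_bead
        return stokes_friction(self.bead_radius_A, self.temperature)

    @property
    def diffusion_A2_fs(self) -> float:
        """Free-bead diffusion coefficient D = k_B T / friction, A^2 fs^-1."""
        return KB_KCAL * self.temperature / self.friction


@dataclass
class Trajectory:
    """Time-ordered bead coordinates with full provenance.

    ``frames`` has shape (n_frames, n_beads, 3) and includes the initial
    configuration.  ``frame_interval_fs`` is ``None`` for equilibrium-sampled
    (non-dynamical) frame sets.
    """

    frames: np.ndarray
    frame_interval_fs: float | None
    config: BDConfig | None
    network_hash: str
    kind: str = "bd"  # "bd" or "equilibrium"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``PREFIX.traj.npy`` plus a JSON sidecar with the metadata."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        arr_path = prefix.with_name(prefix.name + ".traj.npy")
        meta_path = prefix.with_name(prefix.name + ".traj.json")
        np.save(arr_path, self.frames.astype(np.float32))
        meta = {
            "frame_interval_fs": self.frame_interval_fs,
            "network_hash": self.network_hash,
            "kind": self.kind,
            "config": asdict(self.config) if self.config else None,
        }
        meta_path.write_text(json.dumps(meta, indent=1))
        return arr_path, meta_path

    @classmethod
    def load(cls, prefix: str | Path) -> "Trajectory":
        prefix = Path(prefix)
        frames = np.load(prefix.with_name(prefix.name + ".traj.npy")).astype(float)
        meta = json.loads(prefix.with_name(prefix.name + ".traj.json").read_text())
        cfg = BDConfig(**meta["config"]) if meta.get("config") else None
        return cls(
            frames=frames,
            frame_interval_fs=meta["frame_interval_fs"],
            config=cfg,
            network_hash=meta["network_hash"],
            kind=meta.get("kind", "bd"),
        )


def _spring_forces(
    pos: np.ndarray,
    si: np.ndarray,
    sj: np.ndarray,
    rest: np.ndarray,
    k: float,
    out: np.ndarray,
) -> float:
    """Accumulate harmonic spring forces into ``out``; returns max |F_pair|."""
    out[:] = 0.0
    dr = pos[sj] - pos[si]
    dist = np.linalg.norm(dr, axis=1)
    # relaxed springs: F = -k (dist - rest) along the bond
    fmag = -k * (dist - rest)
    fvec = (fmag / np.maximum(dist, 1e-12))[:, None] * dr
    np.add.at(out, sj, fvec)
    np.subtract.at(out, si, fvec)
    return float(np.max(np.abs(fmag))) if len(fmag) else 0.0


def _rpy_mobility(pos: np.ndarray, a: float, friction: float) -> np.ndarray:
    """Rotne-Prager-Yamakawa diffusion tensor (3n x 3n), units of D."""
    n = len(pos)
    d0 = 1.0  # in units of the single-bead D; caller rescales
    D = np.zeros((3 * n, 3 * n))
    eye = np.eye(3)
    for i in range(n):
        D[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = d0 * eye
        for j in range(i + 1, n):
            r = pos[j] - pos[i]
            dist = np.linalg.norm(r)
            u = r / dist
            uu = np.outer(u, u)
            if dist >= 2 * a:
                c1 = 3 * a / (4 * dist)
                c2 = (a / dist) ** 3 / 2
                block = d0 * (c1 * (eye + uu) + c2 * (eye - 3 * uu))
            else:  # overlapping correction keeps the tensor positive definite
                block = d0 * (
                    (1 - 9 * dist / (32 * a)) * eye + (3 * dist / (32 * a)) * uu
                )
            D[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            D[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
    return D


def propagate(network: ElasticNetwork, config: BDConfig) -> Trajectory:
    """Run Brownian dynamics on the network; bit-reproducible under a seed.

    Raises ``RuntimeError`` if any bead moves more than 10 A in a single
    step (diverging integration; the diagnostic names dt and the max force).
    """
    pos = network.positions.copy()
    n = network.n_beads
    si, sj, rest = network.spring_i, network.spring_j, network.rest_length
    if len(si) == 0:
        warnings.warn("network has no springs; propagating free diffusion")

    if len(si) > 0 and network.n_components() > 1:
        warnings.warn("network is disconnected; rigidity output may be ill-defined")

    kBT = KB_KCAL * config.temperature
    D = config.diffusion_A2_fs
    dt = config.dt_fs
    rng = np.random.default_rng(config.seed)

    n_saved = config.n_steps // config.save_every + 1
    frames = np.empty((n_saved, n, 3))
    frames[0] = pos
    forces = np.zeros_like(pos)
    save_idx = 1

    use_hi = config.hydrodynamics
    if use_hi:
        # configuration-dependent mobility; factorized fresh each step
        a = config.bead_radius_A

    for step in range(1, config.n_steps + 1):
        fmax = _spring_forces(pos, si, sj, rest, network.k_spring, forces)
        if use_hi:
            Dmat = D * _rpy_mobility(pos, a, config.friction)
            drift = (Dmat @ forces.ravel()) * (dt / kBT)
            L = np.linalg.cholesky(2.0 * dt * Dmat)
            noise = L @ rng.standard_normal(3 * n)
            disp = (drift + noise).reshape(n, 3)
        else:
            disp = (D / kBT) * forces * dt + rng.normal(
                0.0, np.sqrt(2.0 * D * dt), size=(n, 3)
            )
        step_len = np.max(np.linalg.norm(disp, axis=1))
        if step_len > _MAX_STEP_A:
            raise RuntimeError(
                f"BD diverged at step {step}: displacement {step_len:.2f} A "
                f"with dt={dt} fs and max pair force {fmax:.3g} kcal/mol/A; "
                "reduce dt"
            )
        pos = pos + disp
        if step % config.save_every == 0:
            frames[save_idx] = pos
            save_idx += 1

    return Trajectory(
        frames=frames[:save_idx],
        frame_interval_fs=dt * config.save_every,
        config=config,
        network_hash=network.network_hash(),
        kind="bd",
    )


def enm_hessian(network: ElasticNetwork) -> np.ndarray:
    """Quadratic-energy Hessian (3n x 3n, kcal mol^-1 A^-2) at the minimum.

    For relaxed springs only the bond-stretch curvature survives, giving the
    familiar rank-one ``k u u^T`` block per spring.
    """
    n = network.n_beads
    pos = network.positions
    H = np.zeros((3 * n, 3 * n))
    for i, j in zip(network.spring_i, network.spring_j):
        r = pos[j] - pos[i]
        u = r / np.linalg.norm(r)
        block = network.k_spring * np.outer(u, u)
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
    return H


def _eig_decompose(network: ElasticNetwork):
    from scipy.linalg import eigh

    H = enm_hessian(network)
    evals, evecs = eigh(H)
    scale = max(evals[-1], 1.0)
    tol = 1e-8 * scale
    n_zero = int(np.sum(evals < tol))
    # 3-D bodies have 6 rigid modes; a 2-bead pair has only 5.  More than 6
    # means internal zero modes, i.e. mechanically under-constrained.
    if n_zero > 6:
        raise ValueError(
            f"floppy network: {n_zero} near-zero modes (> 6 rigid-body modes)"
        )
    return evals, evecs, n_zero


def equilibrium_covariance(network: ElasticNetwork, temperature: float) -> np.ndarray:
    """Analytic positional covariance k_B T H^+ of the harmonic network.

    The six rigid-body modes are projected out.  Units: A^2.  Raises on
    networks with internal zero modes ("floppy network").
    """
    if network.n_springs < 1:
        raise ValueError("network has no springs")
    evals, evecs, n_drop = _eig_decompose(network)
    kBT = KB_KCAL * temperature
    inv = np.zeros_like(evals)
    inv[n_drop:] = 1.0 / evals[n_drop:]
    return kBT * (evecs * inv) @ evecs.T


def sample_equilibrium(
    network: ElasticNetwork,
    temperature: float,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """Draw i.i.d. frames from the network's Boltzmann (Gaussian) ensemble.

    Each internal mode m receives an independent normal displacement of
    variance k_B T / lambda_m about the reference structure.  The frames are
    statistically equivalent to a fully equilibrated, infinitely long BD
    trajectory but free of time correlation, so ensemble averages converge
    much faster per frame.
    """
    evals, evecs, n_drop = _eig_decompose(network)
    kBT = KB_KCAL * temperature
    rng = np.random.default_rng(seed)
    amp = np.zeros_like(evals)
    amp[n_drop:] = np.sqrt(kBT / evals[n_drop:])
    coeffs = rng.standard_normal((n_frames, len(evals))) * amp
    disp = coeffs @ evecs.T
    frames = network.positions[None, :, :] + disp.reshape(n_frames, network.n_beads, 3)
    return Trajectory(
        frames=frames,
        frame_interval_fs=None,
        config=None,
        network_hash=network.network_hash(),
        kind="equilibrium",
    )
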