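"""Seeded generators for every input the analysis pipeline consumes.

Real backscattering spectrometers and spectropolarimeters produce the
elastic scans and melting curves this package analyses; those raw data are
not redistributable, so the generators here emulate them with known ground
truth: Gaussian-decay elastic intensities with a linear <u2>(T) regime and
multiplicative counting noise, closed-form two-state melting curves with
sloping baselines, and deterministic toy bead structures for the mechanics
modules.  Every generator stores its ground truth in a sidecar dict so
recovery tests never have to re-derive it from the generated output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cd_thermo import MeltingCurve
from .cg_model import CGBead
from .constants import (
    DEFAULT_GAUSSIAN_DIVISOR,
    R_KJ,
    RESILIENCE_CONSTANT,
)
from .neutron_elastic import ElasticScan

__all__ = [
    "ScanGeneratorSpec",
    "MeltGeneratorSpec",
    "ToyStructureSpec",
    "gen_elastic_scans",
    "gen_melting_curve",
    "gen_toy_structure",
    "tetramer_standin",
    "two_state_folded_fraction",
    "IN13_T_GRID",
    "SPHERES_T_GRID",
    "DEFAULT_Q2_GRID",
]

#: Stepwise temperature points of a thermal-backscattering solution scan, K.
IN13_T_GRID: tuple[float, ...] = tuple(float(t) for t in range(280, 316, 5))

#: Continuous-ramp powder scan binned into 5 K steps, K.
SPHERES_T_GRID: tuple[float, ...] = tuple(float(t) for t in range(10, 301, 5))

#: Default q^2 grid covering both instrument fit windows, A^-2.
DEFAULT_Q2_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.2, 4.01, 0.15), 3))


@dataclass
class ScanGeneratorSpec:
    """Parameters of the elastic-scan generator.

    Either ``slope`` (A^2 K^-1) or ``k_target`` (N m^-1, converted through
    the resilience convention linked to ``divisor``) fixes d<u2>/dT.
    ``non_gaussian_c4`` switches on curvature of ln I versus q^2 beyond
    ``non_gaussian_onset`` (default: the upper edge of the standard fit
    window), emulating the measured behaviour where the decay is linear
    only in its initial-slope region.  ``noise_cv`` is the relative
    (multiplicative Gaussian) noise level, emulating counting statistics at
    high count rates.
    """

    slope: float | None = None
    k_target: float | None = None
    intercept: float = 0.0
    T_grid: tuple[float, ...] = IN13_T_GRID
    q2_grid: tuple[float, ...] = DEFAULT_Q2_GRID
    noise_cv: float = 0.02
    non_gaussian_c4: float = 0.0
    non_gaussian_onset: float = 3.5
    divisor: int = DEFAULT_GAUSSIAN_DIVISOR
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.slope is None) == (self.k_target is None):
            raise ValueError("specify exactly one of slope / k_target")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def effective_slope(self) -> float:
        if self.slope is not None:
            return self.slope
        return RESILIENCE_CONSTANT[self.divisor] / self.k_target


@dataclass
class MeltGeneratorSpec:
    """Parameters of the two-state melting-curve generator.

    ``dH`` in kJ mol^-1, ``Tm`` in K; baselines are (intercept, slope-per-K)
    pairs for the folded and unfolded signals.  ``noise_cv`` is relative to
    the baseline separation at Tm.
    """

    dH: float
    Tm: float
    baseline_F: tuple[float, float] = (1.0, -0.002)
    baseline_U: tuple[float, float] = (0.0, -0.0005)
    T_grid: tuple[float, ...] = tuple(float(t) for t in np.arange(283.15, 368.16, 1.0))
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (min(self.T_grid) < self.Tm < max(self.T_grid)):
            raise ValueError("Tm must lie inside the temperature grid")
        sep = abs(
            self._baseline(self.baseline_F, self.Tm) - self._baseline(self.baseline_U, self.Tm)
        )
        if sep == 0:
            raise ValueError("baselines coincide at Tm")
        # noise std is noise_cv * separation, so the separation exceeds 5x
        # the noise amplitude only while noise_cv < 0.2
        if self.noise_cv >= 0.2:
            raise ValueError("noise_cv too large: baselines < 5x noise apart at Tm")

    @staticmethod
    def _baseline(coef: tuple[float, float], T: float) -> float:
        return coef[0] + coef[1] * T


@dataclass
class ToyStructureSpec:
    """Deterministic toy bead geometries for the mechanics modules."""

    kind: str  # helix_bundle | two_cluster | ring | chain
    n_residues: int = 12
    spacing: float = 3.8  # A, consecutive-bead distance for chain/ring
    n_helices: int = 4
    cluster_gap: float = 12.0  # A, centre separation of the two clusters
    jitter: float = 0.0  # A, optional seeded positional noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"helix_bundle", "two_cluster", "ring", "chain"}:
            raise ValueError(f"unknown toy structure kind {self.kind!r}")
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")


def gen_elastic_scans(spec: ScanGeneratorSpec) -> tuple[list[ElasticScan], dict]:
    """Generate one elastic scan per grid temperature plus a truth sidecar.

    I(q^2) = exp(-u2(T) q^2 / divisor + c4 max(q^2 - onset, 0)^2) * (1 + noise)
    with u2(T) = intercept + slope * T, which must stay non-negative over
    the grid.
    """
    slope = spec.effective_slope
    u2 = spec.intercept + slope * np.asarray(spec.T_grid)
    if np.any(u2 < 0):
        raise ValueError("generated <u2> negative on the temperature grid")
    rng = np.random.default_rng(spec.seed)
    q2 = np.asarray(spec.q2_grid, dtype=float)
    scans = []
    curvature = spec.non_gaussian_c4 * np.clip(q2 - spec.non_gaussian_onset, 0.0, None) ** 2
    for T, u2_T in zip(spec.T_grid, u2):
        clean = np.exp(-u2_T * q2 / spec.divisor + curvature)
        noisy = clean * (1.0 + rng.normal(0.0, spec.noise_cv, size=q2.shape))
        if np.any(noisy <= 0):
            raise ValueError("noise drove intensities non-positive; lower noise_cv")
        sigma = spec.noise_cv * clean if spec.noise_cv > 0 else np.zeros_like(clean)
        scans.append(
            ElasticScan(
                temperature=float(T),
                q2=q2,
                intensity=noisy,
                sigma=sigma if spec.noise_cv > 0 else None,
                instrument_label="synthetic",
            )
        )
    truth = {
        "slope": slope,
        "intercept": spec.intercept,
        "u2": dict(zip(map(float, spec.T_grid), map(float, u2))),
        "divisor": spec.divisor,
        "k_N_m": RESILIENCE_CONSTANT[spec.divisor] / slope if slope > 0 else None,
        "non_gaussian_c4": spec.non_gaussian_c4,
        "non_gaussian_onset": spec.non_gaussian_onset,
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
    }
    return scans, truth


def two_state_folded_fraction(T: np.ndarray, dH: float, Tm: float) -> np.ndarray:
    """Closed-form folded fraction of the dCp = 0 two-state model.

    K(T) = exp(-(dH / R)(1/T - 1/Tm)) is the unfolding constant, so
    f_F = 1 / (1 + K); at T = Tm, f_F = 1/2 exactly.
    """
    K = np.exp(-(dH / R_KJ) * (1.0 / np.asarray(T, dtype=float) - 1.0 / Tm))
    return 1.0 / (1.0 + K)


def gen_melting_curve(spec: MeltGeneratorSpec) -> tuple[MeltingCurve, dict]:
    """Two-state melting curve with sloping baselines and additive noise."""
    T = np.asarray(spec.T_grid, dtype=float)
    fF = two_state_folded_fraction(T, spec.dH, spec.Tm)
    y_F = spec.baseline_F[0] + spec.baseline_F[1] * T
    y_U = spec.baseline_U[0] + spec.baseline_U[1] * T
    clean = fF * y_F + (1.0 - fF) * y_U
    sep_tm = abs(
        (spec.baseline_F[0] + spec.baseline_F[1] * spec.Tm)
        - (spec.baseline_U[0] + spec.baseline_U[1] * spec.Tm)
    )
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_cv * sep_tm, size=T.shape)
    curve = MeltingCurve(T, noisy, wavelength_note="synthetic 222 nm")
    truth = {
        "dH": spec.dH,
        "Tm": spec.Tm,
        "dS": spec.dH / spec.Tm,
        "baseline_F": list(spec.baseline_F),
        "baseline_U": list(spec.baseline_U),
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
        "fF": dict(zip(map(float, T), map(float, fF))),
    }
    return curve, truth


def tetramer_standin(
    n_residues: int = 30,
    variant: str = "reference",
    shift: float = 1.5,
) -> list[CGBead]:
    """Synthetic four-chain helix-bundle stand-in for a tetrameric protein.

    This is NOT a haemoglobin structure: it is a synthetic fixture used to
    exercise the tetramer-scale pipeline (chains A-D, monomer separation,
    Delta-k comparisons) when real crystal structures are not on hand.  The
    ``softened`` variant pulls chain D radially ``shift`` A away from the
    bundle axis, loosening its interface contacts so that interface
    residues of the softened structure show negative Delta-k relative to
    the reference.
    """
    if variant not in {"reference", "softened"}:
        raise ValueError("variant must be 'reference' or 'softened'")
    beads: list[CGBead] = []
    radius = 6.0
    base = _ideal_helix(n_residues, np.array([radius, 0.0, 0.0]))
    for h, chain in enumerate("ABCD"):
        # exact 4-fold symmetry: every chain is the same helix rotated
        # about the bundle axis, so all four are statistically equivalent
        ang = np.pi / 2.0 * h
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        coords = base @ rot.T
        if variant == "softened" and chain == "D":
            centre = coords.mean(axis=0)
            out = centre / np.linalg.norm(centre[:2] + 1e-12)
            coords = coords + shift * np.array([out[0], out[1], 0.0])
        for k, xyz in enumerate(coords):
            beads.append(CGBead(chain, k + 1, "ALA", "CA", np.asarray(xyz, dtype=float)))
    return beads


def _ideal_helix(n: int, origin: np.ndarray, axis_z: float = 0.0) -> np.ndarray:
    """Ideal alpha-helix C-alpha trace: radius 2.3 A, rise 1.5 A, 100 deg."""
    idx = np.arange(n)
    ang = np.radians(100.0) * idx
    return np.column_stack(
        [
            origin[0] + 2.3 * np.cos(ang),
            origin[1] + 2.3 * np.sin(ang),
            origin[2] + axis_z + 1.5 * idx,
        ]
    )


def gen_toy_structure(spec: ToyStructureSpec) -> list[CGBead]:
    """Deterministic C-alpha-only toy structures (seeded jitter optional).

    ``chain``: straight trace at ``spacing``; ``ring``: regular polygon of
    side ``spacing``; ``helix_bundle``: ``n_helices`` parallel ideal helices
    (one chain each) on a 10 A square lattice; ``two_cluster``: two compact
    clusters (one chain each) bridged by a sparse linker chain, built so
    intra-cluster beads are stiff and the linker soft.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    beads: list[CGBead] = []

    def add_chain(chain_id: str, coords: np.ndarray, start_resid: int = 1) -> None:
        for k, xyz in enumerate(coords):
            pos = np.asarray(xyz, dtype=float)
            if spec.jitter > 0:
                pos = pos + rng.normal(0.0, spec.jitter, 3)
            beads.append(CGBead(chain_id, start_resid + k, "GLY", "CA", pos))

    if spec.kind == "chain":
        coords = np.column_stack([spec.spacing * np.arange(n), np.zeros(n), np.zeros(n)])
        add_chain("A", coords)
    elif spec.kind == "ring":
        # regular n-gon with side ~ spacing, puckered out of plane so the
        # distance-spring network has no planar zero modes
        radius = spec.spacing / (2.0 * np.sin(np.pi / n))
        ang = 2.0 * np.pi * np.arange(n) / n
        pucker = 0.5 * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), pucker])
        add_chain("A", coords)
    elif spec.kind == "helix_bundle":
        side = int(np.ceil(np.sqrt(spec.n_helices)))
        for h in range(spec.n_helices):
            origin = np.array([10.0 * (h % side), 10.0 * (h // side), 0.0])
            add_chain(chr(ord("A") + h), _ideal_helix(n, origin))
    elif spec.kind == "two_cluster":
        half = n // 2
        # compact 3.8 A-spaced coils so each cluster is densely connected
        t = np.arange(half)
        coil = np.column_stack(
            [2.5 * np.cos(1.7 * t), 2.5 * np.sin(1.7 * t), 1.9 * t]
        )
        add_chain("A", coil)
        add_chain("B", coil + np.array([spec.cluster_gap, 0.0, 0.0]))
        # sparse linker chain bridging the cluster tops
        n_link = max(n - 2 * half, 2)
        link_x = np.linspace(2.0, spec.cluster_gap - 2.0, n_link + 2)[1:-1]
        link = np.column_stack(
            [link_x, np.full(n_link, 6.0), np.full(n_link, 1.9 * half)]
        )
        add_chain("C", link)
    return beads
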