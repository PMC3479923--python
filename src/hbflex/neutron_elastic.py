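"""Elastic incoherent neutron scattering analysis.

Mean square displacements are extracted from the q^2-dependence of the
elastic intensity in the Gaussian approximation,

    I(q) = I_0 exp(-<u2> q^2 / 6),

by a weighted straight-line fit of ln I versus q^2 inside a fixed window
where the decay is linear (1.6 <= q^2 <= 3.5 A^-2 for an IN13-like thermal
backscattering setup, 0.36 <= q^2 <= 3.10 A^-2 for a SPHERES-like cold
one).  The mean resilience then follows from the slope of <u2> versus
temperature,

    <k'> = 0.00276 / (d<u2>/dT)  [N m^-1, <u2> in A^2, T in K],

fitted either over one window or over the three quasi-linear regimes of
hydrated-powder scans (10-100, 100-200 and 252-292 K).  The divisor-6 /
0.00276 pairing is one linked convention option; divisor 3 pairs with
0.00138.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_GAUSSIAN_DIVISOR,
    GAUSSIAN_VALIDITY_BOUND,
    RESILIENCE_CONSTANT,
)

__all__ = [
    "ElasticScan",
    "MSDSeries",
    "ResilienceFit",
    "IN13_Q2_WINDOW",
    "SPHERES_Q2_WINDOW",
    "SPHERES_T_WINDOWS",
    "q_from_angle",
    "fit_msd",
    "scans_to_msd_series",
    "force_constant",
    "windowed_force_constants",
    "rmsd_at_temperature",
    "read_scans",
]

#: q^2 fit windows (A^-2) where the intensity decay is linear.
IN13_Q2_WINDOW: tuple[float, float] = (1.6, 3.5)
SPHERES_Q2_WINDOW: tuple[float, float] = (0.36, 3.10)

#: Quasi-linear temperature regimes of hydrated-powder MSD scans (K):
#: harmonic solid, methyl-rotation onset, post-dynamical-transition.
SPHERES_T_WINDOWS: tuple[tuple[float, float], ...] = ((10, 100), (100, 200), (252, 292))


@dataclass
class ElasticScan:
    """One elastic scan I(q^2) at fixed temperature."""

    temperature: float
    q2: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    instrument_label: str = ""

    def __post_init__(self) -> None:
        self.q2 = np.asarray(self.q2, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")
        if np.any(self.q2 <= 0) or np.any(np.diff(self.q2) <= 0):
            raise ValueError("q2 must be positive and strictly increasing")


@dataclass
class MSDSeries:
    """<u2>(T) table with the extraction convention recorded."""

    table: pd.DataFrame  # columns T, u2, u2_sigma
    divisor: int = DEFAULT_GAUSSIAN_DIVISOR
    fit_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        required = {"T", "u2", "u2_sigma"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"MSD table needs columns {sorted(required)}")
        if self.table["T"].duplicated().any():
            raise ValueError("one row per temperature required")


@dataclass
class ResilienceFit:
    """Result of a <u2>-vs-T straight-line fit and the derived resilience."""

    k_eff: float  # N m^-1 (NaN when the slope is non-positive)
    k_sigma: float
    slope: float  # A^2 K^-1
    slope_sigma: float
    intercept: float  # A^2
    intercept_sigma: float
    slope_intercept_cov: float
    T_window: tuple[float, float]
    n_points: int
    diagnostic: str = ""


def q_from_angle(wavelength: float, two_theta: float) -> float:
    """Elastic scattering vector q = 4 pi / lambda * sin(two_theta / 2).

    ``wavelength`` in Angstrom, ``two_theta`` in degrees; q in A^-1.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if not 0 <= two_theta <= 180:
        raise ValueError("two_theta must be within [0, 180] degrees")
    return 4.0 * np.pi / wavelength * np.sin(np.radians(two_theta) / 2.0)


def _weighted_linefit(x: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """Weighted least squares y = a + b x; returns (a, b, cov 2x2)."""
    if w is None:
        w = np.ones_like(x)
    W = np.asarray(w, dtype=float)
    A = np.column_stack([np.ones_like(x), x])
    Aw = A * np.sqrt(W)[:, None]
    yw = y * np.sqrt(W)
    coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    resid = y - A @ coef
    dof = max(len(x) - 2, 1)
    # scale covariance by reduced chi^2 so unweighted fits get sane errors
    chi2 = float(np.sum(W * resid**2)) / dof
    cov = np.linalg.inv(Aw.T @ Aw) * max(chi2, np.finfo(float).tiny)
    return float(coef[0]), float(coef[1]), cov


def fit_msd(
    scan: ElasticScan,
    q2_window: tuple[float, float] = IN13_Q2_WINDOW,
    divisor: int = DEFAULT_GAUSSIAN_DIVISOR,
    background: float = 0.0,
    validity_bound: float = GAUSSIAN_VALIDITY_BOUND,
) -> tuple[float, float, bool]:
    """Extract (<u2>, sigma, validity_flag) from one scan.

    Weighted fit of ln(I - background) versus q^2 inside ``q2_window``;
    <u2> = -divisor * slope.  The flag is ``True`` when the Gaussian
    exponent at the window edge, <u2> * q2_max / divisor, exceeds the
    validity bound (~2): beyond it the low-q expansion underlying the fit
    is unreliable.
    """
    if divisor not in RESILIENCE_CONSTANT:
        raise ValueError(f"divisor must be one of {sorted(RESILIENCE_CONSTANT)}")
    lo, hi = q2_window
    sel = (scan.q2 >= lo) & (scan.q2 <= hi)
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 points in q2 window [{lo}, {hi}], got {int(sel.sum())}"
        )
    inten = scan.intensity[sel] - background
    if np.any(inten <= 0):
        raise ValueError("non-positive intensities inside the fit window")
    q2 = scan.q2[sel]
    ln_i = np.log(inten)
    weights = None
    if scan.sigma is not None and np.all(scan.sigma[sel] > 0):
        weights = (inten / scan.sigma[sel]) ** 2  # sigma_lnI = sigma_I / I
    _, slope, cov = _weighted_linefit(q2, ln_i, weights)
    u2 = -divisor * slope
    u2_sigma = divisor * float(np.sqrt(cov[1, 1]))
    flag = bool(u2 * q2.max() / divisor > validity_bound)
    return u2, u2_sigma, flag


def scans_to_msd_series(
    scans: list[ElasticScan],
    q2_window: tuple[float, float] = IN13_Q2_WINDOW,
    divisor: int = DEFAULT_GAUSSIAN_DIVISOR,
    background: float = 0.0,
) -> MSDSeries:
    """Fit every scan and assemble the <u2>(T) series (sorted by T)."""
    rows = []
    for scan in sorted(scans, key=lambda s: s.temperature):
        u2, u2_sigma, flag = fit_msd(scan, q2_window, divisor, background)
        if flag:
            warnings.warn(
                f"T={scan.temperature} K: <u2> q2_max beyond Gaussian validity bound"
            )
        rows.append({"T": scan.temperature, "u2": u2, "u2_sigma": u2_sigma})
    return MSDSeries(pd.DataFrame(rows), divisor=divisor, fit_window=q2_window)


def force_constant(
    series: MSDSeries,
    T_window: tuple[float, float] | None = None,
) -> ResilienceFit:
    """Resilience <k'> from the slope of <u2> versus T inside ``T_window``.

    Error-weighted straight-line fit; k = C / slope with C the constant
    linked to the series' Gaussian divisor, and the slope uncertainty
    propagated to ``k_sigma``.  A non-positive slope yields NaN k with a
    diagnostic instead of an exception.
    """
    tbl = series.table
    if T_window is None:
        T_window = (float(tbl["T"].min()), float(tbl["T"].max()))
    lo, hi = T_window
    sub = tbl[(tbl["T"] >= lo) & (tbl["T"] <= hi)]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 temperatures in window [{lo}, {hi}], got {len(sub)}")
    T = sub["T"].to_numpy()
    u2 = sub["u2"].to_numpy()
    sig = sub["u2_sigma"].to_numpy()
    weights = 1.0 / sig**2 if np.all(sig > 0) else None
    intercept, slope, cov = _weighted_linefit(T, u2, weights)
    C = RESILIENCE_CONSTANT[series.divisor]
    if slope <= 0:
        k_eff, k_sigma = float("nan"), float("nan")
        diag = f"non-positive slope {slope:.3g} A^2/K: resilience undefined"
    else:
        k_eff = C / slope
        k_sigma = C * float(np.sqrt(cov[1, 1])) / slope**2
        diag = ""
    return ResilienceFit(
        k_eff=k_eff,
        k_sigma=k_sigma,
        slope=slope,
        slope_sigma=float(np.sqrt(cov[1, 1])),
        intercept=intercept,
        intercept_sigma=float(np.sqrt(cov[0, 0])),
        slope_intercept_cov=float(cov[0, 1]),
        T_window=(lo, hi),
        n_points=len(sub),
        diagnostic=diag,
    )


def windowed_force_constants(
    series: MSDSeries,
    windows: tuple[tuple[float, float], ...] = SPHERES_T_WINDOWS,
) -> dict[tuple[float, float], ResilienceFit]:
    """Independent resilience fits in each temperature window.

    Windows with fewer than three points are skipped with a warning.
    """
    fits: dict[tuple[float, float], ResilienceFit] = {}
    for window in windows:
        try:
            fits[tuple(window)] = force_constant(series, window)
        except ValueError as err:
            warnings.warn(f"window {window}: {err}; skipped")
    return fits


def rmsd_at_temperature(fit: ResilienceFit, T_b: float) -> tuple[float, float]:
    """Root mean square displacement sqrt(<u2>(T_b)) from a fitted line.

    First-order error propagation through intercept + slope * T_b using the
    full parameter covariance.  Raises when the interpolated <u2> is
    negative.
    """
    u2 = fit.intercept + fit.slope * T_b
    if u2 <= 0:
        raise ValueError(
            f"interpolated <u2> = {u2:.3g} A^2 at T={T_b} K is non-positive"
        )
    var_u2 = (
        fit.intercept_sigma**2
        + (T_b * fit.slope_sigma) ** 2
        + 2.0 * T_b * fit.slope_intercept_cov
    )
    rmsd = float(np.sqrt(u2))
    rmsd_sigma = float(np.sqrt(max(var_u2, 0.0)) / (2.0 * rmsd))
    return rmsd, rmsd_sigma


def read_scans(path: str | Path) -> list[ElasticScan]:
    """Read scans from long-format delimited text (columns T, q2, I[, sigma])."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    for need in ("t", "q2", "i"):
        if need not in cols:
            raise ValueError(f"scan file must have columns T, q2, I; missing {need!r}")
    scans = []
    for T, grp in df.groupby(cols["t"]):
        grp = grp.sort_values(cols["q2"])
        sigma = grp[cols["sigma"]].to_numpy() if "sigma" in cols else None
        scans.append(
            ElasticScan(
                temperature=float(T),
                q2=grp[cols["q2"]].to_numpy(),
                intensity=grp[cols["i"]].to_numpy(),
                sigma=sigma,
            )
        )
    return scans
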