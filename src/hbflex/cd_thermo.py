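"""Two-state van't Hoff analysis of CD melting curves.

The ellipticity at fixed wavelength (222 nm for the alpha-helical band) is
assumed proportional to the folded fraction after correcting for linear
pre- and post-transitional baselines:

    f_F(T) = (y_U(T) - y(T)) / (y_U(T) - y_F(T)).

In the transition region the two-state free-energy difference is

    dG(T) = -R T ln(f_U / f_F),   f_U = 1 - f_F,

and a straight-line fit dG = dH - T dS in the linear regime gives the
enthalpy and entropy differences at the melting temperature, with
Tm = dH / dS (the root of the fitted line, where dG = 0 and f_F = 1/2).
A temperature-independent dH (dCp = 0) is assumed throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_KJ, celsius_to_kelvin

__all__ = [
    "MeltingCurve",
    "ThermoResult",
    "correct_baselines",
    "vant_hoff",
    "entropy_at_tm",
]

logger = logging.getLogger(__name__)


@dataclass
class MeltingCurve:
    """Ellipticity versus temperature; T stored in Kelvin."""

    T: np.ndarray
    signal: np.ndarray
    wavelength_note: str = "222 nm"

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.T) < 20:
            raise ValueError("melting curve needs >= 20 points")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def from_celsius(cls, T_celsius, signal, **kwargs) -> "MeltingCurve":
        return cls(celsius_to_kelvin(np.asarray(T_celsius, dtype=float)), signal, **kwargs)

    @classmethod
    def from_file(cls, path) -> "MeltingCurve":
        """Read delimited text with columns T, signal; a header comment line
        ``# units: C`` (or K) declares the temperature unit, default K."""
        unit = "K"
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "units" in line.lower():
                    unit = line.split(":")[-1].strip().upper()[:1]
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        T = df.iloc[:, 0].to_numpy(dtype=float)
        y = df.iloc[:, 1].to_numpy(dtype=float)
        return cls.from_celsius(T, y) if unit == "C" else cls(T, y)


@dataclass
class ThermoResult:
    """Thermodynamic parameters of the two-state transition.

    dH in kJ mol^-1, dS in kJ mol^-1 K^-1, Tm in K (all unfolded minus
    folded, evaluated at Tm).  ``Tm_crossing`` is the raw f_F = 0.5
    crossing, logged alongside the line-root Tm.
    """

    Tm: float
    Tm_sigma: float
    dH: float
    dH_sigma: float
    dS: float
    dS_sigma: float
    Tm_crossing: float
    dG_table: pd.DataFrame  # columns T, dG (kJ/mol)
    fF_table: pd.DataFrame  # columns T, fF


def correct_baselines(
    curve: MeltingCurve,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    eps: float = 1e-4,
) -> pd.DataFrame:
    """Fit linear pre/post baselines and convert the signal to f_F(T).

    Windows are (T_lo, T_hi) in Kelvin and must each hold >= 3 points.
    f_F is clipped to [eps, 1 - eps] for the downstream log step; any
    clipping is logged.  Baselines crossing inside the data range make the
    folded-fraction denominator vanish and raise ``degenerate baselines``.
    """
    T, y = curve.T, curve.signal

    def fit_window(window, name):
        lo, hi = window
        sel = (T >= lo) & (T <= hi)
        if sel.sum() < 3:
            raise ValueError(f"{name} baseline window {window} holds < 3 points")
        coef = np.polyfit(T[sel], y[sel], 1)
        return np.poly1d(coef)

    y_F = fit_window(pre_window, "pre")
    y_U = fit_window(post_window, "post")
    denom = y_U(T) - y_F(T)
    if np.any(np.sign(denom) != np.sign(denom[np.argmax(np.abs(denom))])) or np.any(
        np.abs(denom) < 1e-12
    ):
        raise ValueError("degenerate baselines: pre/post lines cross inside the data range")
    fF = (y_U(T) - y) / denom
    n_clip = int(np.sum((fF < eps) | (fF > 1 - eps)))
    if n_clip:
        logger.info("folded fraction clipped at %d of %d points (eps=%g)", n_clip, len(fF), eps)
    fF = np.clip(fF, eps, 1 - eps)
    return pd.DataFrame({"T": T, "fF": fF})


def vant_hoff(
    fF: pd.DataFrame,
    transition_window: tuple[float, float] | None = None,
    fF_bounds: tuple[float, float] = (0.05, 0.95),
    linear_bounds: tuple[float, float] = (0.1, 0.9),
    R: float = R_KJ,
) -> ThermoResult:
    """Two-state analysis of a folded-fraction table (columns T, fF).

    dG is computed pointwise for ``fF_bounds``-interior points inside
    ``transition_window`` (whole range by default); dH and dS come from the
    unweighted line fit dG = dH - T dS restricted to the ``linear_bounds``
    regime, and Tm is the root of that line.  Standard errors are taken
    from the fit covariance with first-order propagation to Tm.
    """
    from .neutron_elastic import _weighted_linefit

    T = fF["T"].to_numpy(dtype=float)
    f = fF["fF"].to_numpy(dtype=float)
    if transition_window is not None:
        lo, hi = transition_window
        sel = (T >= lo) & (T <= hi)
        T, f = T[sel], f[sel]
    usable = (f >= fF_bounds[0]) & (f <= fF_bounds[1])
    if usable.sum() < 4:
        raise ValueError(
            f"fewer than 4 usable points with {fF_bounds[0]} <= f_F <= {fF_bounds[1]}"
        )
    if np.any(np.diff(f[usable]) > 0):
        warnings.warn("folded fraction is non-monotone inside the transition window")

    T_u, f_u = T[usable], f[usable]
    dG = -R * T_u * np.log((1.0 - f_u) / f_u)

    lin = (f_u >= linear_bounds[0]) & (f_u <= linear_bounds[1])
    if lin.sum() < 4:
        raise ValueError("fewer than 4 points in the linear (mid-transition) regime")
    intercept, slope, cov = _weighted_linefit(T_u[lin], dG[lin], None)
    dH = intercept  # dG = dH - T dS
    dS = -slope
    dH_sigma = float(np.sqrt(cov[0, 0]))
    dS_sigma = float(np.sqrt(cov[1, 1]))
    if dS <= 0:
        raise ValueError("fitted dS <= 0: not a thermal unfolding transition")
    Tm = dH / dS
    # var(Tm) by the delta method; note cov(dH, dS) = -cov(intercept, slope)
    gH, gS = 1.0 / dS, -dH / dS**2
    var_tm = (
        gH * gH * cov[0, 0] + gS * gS * cov[1, 1] + 2.0 * gH * gS * (-cov[0, 1])
    )
    Tm_sigma = float(np.sqrt(max(var_tm, 0.0)))

    Tm_crossing = float(np.interp(0.5, f_u[np.argsort(f_u)], T_u[np.argsort(f_u)]))
    if abs(Tm_crossing - Tm) > 0.5:
        warnings.warn(
            f"Tm from the dG line root ({Tm:.2f} K) and the raw f_F=0.5 crossing "
            f"({Tm_crossing:.2f} K) differ by more than 0.5 K"
        )

    return ThermoResult(
        Tm=float(Tm),
        Tm_sigma=Tm_sigma,
        dH=float(dH),
        dH_sigma=dH_sigma,
        dS=float(dS),
        dS_sigma=dS_sigma,
        Tm_crossing=Tm_crossing,
        dG_table=pd.DataFrame({"T": T_u, "dG": dG}),
        fF_table=pd.DataFrame({"T": T, "fF": f}),
    )


def entropy_at_tm(dH: float, Tm: float) -> float:
    """Two-state midpoint identity: dG(Tm) = 0 implies dS = dH / Tm.

    ``dH`` in kJ mol^-1, ``Tm`` in K; result in kJ mol^-1 K^-1.
    """
    if Tm <= 0:
        raise ValueError("Tm must be positive (Kelvin)")
    return dH / Tm
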