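"""Theoretical REES curves: coordinate sweeps, wavelength views, shape summaries.

Sweeping the collective coordinate ``x`` and plotting the ensemble mean
emission energy against the ensemble absorption energy produces the
theoretical red-edge excitation shift curve.  In wavelength space this is the
familiar sigmoid-like plot of peak emission wavelength versus excitation
wavelength.  The curve's shape is summarized by its two emission endpoints,
the excitation wavelength of the half-transition (mid-point), and the slope
d(em)/d(ex) there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FelSpec, LigandPhotophysics, ModelConfig, ensemble_abs_energy, ensemble_em_energy

#: hc in eV*nm, for photon energy <-> wavelength conversion.
HC_EV_NM = 1239.84193

#: Emission ranges below this (nm) are treated as flat (no REES transition).
FLAT_TOL_NM = 1e-9


def energy_to_wavelength(e):
    """Convert photon energy (eV) to wavelength (nm)."""
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0):
        raise ValueError("photon energy must be positive")
    w = HC_EV_NM / e
    return w if w.ndim else float(w)


def wavelength_to_energy(w):
    """Convert wavelength (nm) to photon energy (eV)."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wavelength must be positive")
    e = HC_EV_NM / w
    return e if e.ndim else float(e)


@dataclass(frozen=True)
class ReesCurve:
    """Theoretical REES curve on a coordinate grid.

    ``ex_energy`` must be strictly decreasing in ``x`` so the curve can be
    resampled onto an excitation-wavelength grid.
    """

    x_grid: np.ndarray
    ex_energy: np.ndarray
    em_energy: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x_grid) == len(self.ex_energy) == len(self.em_energy)):
            raise ValueError("curve arrays must have equal length")
        if not np.all(np.diff(self.ex_energy) < 0):
            raise ValueError(
                "ensemble absorption energy is not strictly decreasing along x; "
                "review grid bounds or model parameters (x_ct must be > 0)"
            )

    @property
    def ex_nm(self) -> np.ndarray:
        return energy_to_wavelength(self.ex_energy)

    @property
    def em_nm(self) -> np.ndarray:
        return energy_to_wavelength(self.em_energy)

    def to_frame(self, include_ev: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"ex_nm": self.ex_nm, "em_nm": self.em_nm})
        if include_ev:
            df["ex_ev"] = self.ex_energy
            df["em_ev"] = self.em_energy
        return df

    def resample_em_nm(self, ex_nm: np.ndarray) -> np.ndarray:
        """Emission wavelengths at the given excitation wavelengths.

        Monotone piecewise-linear interpolation; the query grid must lie
        within the curve's excitation range.
        """
        ex_nm = np.asarray(ex_nm, dtype=float)
        lo, hi = self.ex_nm[0], self.ex_nm[-1]
        if np.any(ex_nm < lo - 1e-9) or np.any(ex_nm > hi + 1e-9):
            raise ValueError(
                f"excitation grid [{ex_nm.min():.1f}, {ex_nm.max():.1f}] nm "
                f"outside curve range [{lo:.1f}, {hi:.1f}] nm"
            )
        return np.interp(ex_nm, self.ex_nm, self.em_nm)


@dataclass(frozen=True)
class CurveSummary:
    """Shape descriptors of a REES curve (wavelength space)."""

    em_blue_nm: float
    em_red_nm: float
    midpoint_ex_nm: float
    midpoint_slope: float
    midpoint_defined: bool = True


def simulate_rees_curve(
    lig: LigandPhotophysics,
    fel: FelSpec,
    cfg: ModelConfig | None = None,
    strict_surfaces: bool = False,
) -> ReesCurve:
    """Sweep the coordinate grid and return the theoretical REES curve."""
    cfg = cfg or ModelConfig()
    if lig.dg_ctgs0 <= lig.reorg(cfg.kappa) or lig.dg_ctgsn <= lig.reorg(cfg.kappa):
        raise ValueError(
            "CT-GS gaps must exceed the reorganization energy "
            "(emission energy would be non-positive)"
        )
    xs = cfg.x_grid()
    ex = ensemble_abs_energy(xs, fel, lig, cfg, strict_surfaces=strict_surfaces)
    em = ensemble_em_energy(xs, fel, lig, cfg)
    return ReesCurve(x_grid=xs, ex_energy=ex, em_energy=em)


def summarize_curve(curve: ReesCurve) -> CurveSummary:
    """Endpoints, mid-point position and mid-point slope of a REES curve.

    The mid-point is where the emission reaches halfway between its blue and
    red endpoints, located by linear interpolation; the slope there is a
    central difference of em_nm with respect to ex_nm.  A flat curve (single
    microstate) yields an undefined mid-point, flagged rather than raised.
    """
    if len(curve.x_grid) < 3:
        raise ValueError("curve must have at least 3 points")
    ex_nm = curve.ex_nm
    em_nm = curve.em_nm
    blue = float(min(em_nm[0], em_nm[-1]))
    red = float(max(em_nm[0], em_nm[-1]))
    if red - blue < FLAT_TOL_NM:
        return CurveSummary(blue, red, float("nan"), float("nan"), False)

    mid_em = 0.5 * (blue + red)
    d = em_nm - mid_em
    # first sign change along the grid
    k = int(np.argmax(d[:-1] * d[1:] <= 0))
    if d[k] == d[k + 1]:
        frac = 0.5
    else:
        frac = d[k] / (d[k] - d[k + 1])
    mid_ex = float(ex_nm[k] + frac * (ex_nm[k + 1] - ex_nm[k]))

    j = min(max(k, 1), len(ex_nm) - 2)
    slope = float((em_nm[j + 1] - em_nm[j - 1]) / (ex_nm[j + 1] - ex_nm[j - 1]))
    return CurveSummary(blue, red, mid_ex, slope, True)


def write_curve_csv(curve: ReesCurve, path, include_ev: bool = False) -> None:
    """Export a curve as two-column CSV (ex_nm, em_nm), optional eV columns."""
    curve.to_frame(include_ev=include_ev).to_csv(path, index=False)
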