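"""Derived thermodynamics of the fitted landscape.

Successive microstate gaps, the ground-state reorganization energy
RE = kappa*x_GS^2/2, Marcus activation barriers (gap + RE)^2 / (4*RE),
unit conversions, the dissociation-constant to binding-free-energy map, and
the decomposition of total binding free energy into surface association and
intrusion (surface-bound to interior-bound) terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FelSpec, K_B_EV_PER_K, ModelConfig

EV_TO_KJ_PER_MOL = 96.485
EV_TO_KCAL_PER_MOL = 23.0605


@dataclass(frozen=True)
class LandscapeReport:
    """Per-microstate energetics of a fitted free-energy landscape (eV)."""

    minima_ev: np.ndarray
    gaps_ev: np.ndarray
    gs_reorg_ev: float
    barriers_ev: np.ndarray
    span_ev: float

    def to_frame(self) -> pd.DataFrame:
        m = len(self.minima_ev)
        return pd.DataFrame(
            {
                "state": np.arange(m),
                "minimum_eV": self.minima_ev,
                "gap_eV": np.append(self.gaps_ev, np.nan),
                "barrier_eV": np.append(self.barriers_ev, np.nan),
            }
        )

    def to_dict(self) -> dict:
        return {
            "minima_ev": list(map(float, self.minima_ev)),
            "gaps_ev": list(map(float, self.gaps_ev)),
            "gs_reorg_ev": float(self.gs_reorg_ev),
            "barriers_ev": list(map(float, self.barriers_ev)),
            "span_ev": float(self.span_ev),
        }


@dataclass(frozen=True)
class BindingDecomposition:
    """Total binding free energy split into intrusion and association parts
    (kcal/mol, negative favorable)."""

    dg_total_kcal: float
    dg_intrusion_kcal: float
    dg_assoc_kcal: float


@dataclass(frozen=True)
class BindingEnergy:
    """Binding free energy from a dissociation constant."""

    kbt: float
    kcal_per_mol: float


def state_gap(i: int, fel: FelSpec) -> float:
    """Free-energy gap between microstates i+1 and i: A*(i+1)^b - A*i^b (eV).

    Reduces to A for a linear ramp and A*(2i+1) for a quadratic landscape.
    """
    if not 0 <= i <= fel.m - 2:
        raise IndexError(
            f"gap index i={i} out of range for m={fel.m} states (valid: 0..{fel.m - 2})"
        )
    return fel.a * (float(i + 1) ** fel.b - float(i) ** fel.b)


def gs_reorg(fel: FelSpec, cfg: ModelConfig | None = None) -> float:
    """Ground-state reorganization energy kappa*x_GS^2/2 (eV)."""
    cfg = cfg or ModelConfig()
    return 0.5 * cfg.kappa * fel.x_gs ** 2


def activation_barrier(i: int, fel: FelSpec, cfg: ModelConfig | None = None) -> float:
    """Marcus activation barrier for the i -> i+1 transition (eV).

    (gap + RE)^2 / (4*RE) with RE the ground-state reorganization energy;
    undefined (raises) at RE = 0.
    """
    cfg = cfg or ModelConfig()
    re = gs_reorg(fel, cfg)
    if re <= 0:
        raise ValueError("activation barrier undefined for zero x_GS (RE = 0)")
    gap = state_gap(i, fel)
    return (gap + re) ** 2 / (4.0 * re)


_UNITS = ("eV", "kJ/mol", "kcal/mol", "kbT")


def convert_energy(
    value: float, from_unit: str, to_unit: str, temperature_K: float = 298.0
) -> float:
    """Convert an energy between eV, kJ/mol, kcal/mol and kbT."""

    def to_ev(v: float, unit: str) -> float:
        if unit == "eV":
            return v
        if unit == "kJ/mol":
            return v / EV_TO_KJ_PER_MOL
        if unit == "kcal/mol":
            return v / EV_TO_KCAL_PER_MOL
        if unit == "kbT":
            return v * K_B_EV_PER_K * temperature_K
        raise ValueError(f"unknown unit {unit!r}; expected one of {_UNITS}")

    ev = to_ev(value, from_unit)
    if to_unit == "eV":
        return ev
    if to_unit == "kJ/mol":
        return ev * EV_TO_KJ_PER_MOL
    if to_unit == "kcal/mol":
        return ev * EV_TO_KCAL_PER_MOL
    if to_unit == "kbT":
        return ev / (K_B_EV_PER_K * temperature_K)
    raise ValueError(f"unknown unit {to_unit!r}; expected one of {_UNITS}")


def kd_to_binding_energy(kd_molar: float, temperature_K: float = 298.0) -> BindingEnergy:
    """Binding free energy from an equilibrium dissociation constant.

    dG = ln(Kd / 1 M) in kbT units (standard state 1 M; negative for
    sub-molar Kd), converted to kcal/mol at the given temperature.
    """
    if not kd_molar > 0:
        raise ValueError(f"Kd must be positive, got {kd_molar}")
    dg_kbt = math.log(kd_molar)
    dg_kcal = convert_energy(dg_kbt, "kbT", "kcal/mol", temperature_K)
    return BindingEnergy(kbt=dg_kbt, kcal_per_mol=dg_kcal)


def binding_decomposition(
    dg_total_kcal: float, dg_intrusion_kcal: float
) -> BindingDecomposition:
    """Split total binding free energy into association and intrusion parts:
    dG_assoc = dG_total - dG_intrusion (all kcal/mol)."""
    if not (math.isfinite(dg_total_kcal) and math.isfinite(dg_intrusion_kcal)):
        raise ValueError("binding free energies must be finite")
    return BindingDecomposition(
        dg_total_kcal=dg_total_kcal,
        dg_intrusion_kcal=dg_intrusion_kcal,
        dg_assoc_kcal=dg_total_kcal - dg_intrusion_kcal,
    )


def landscape_report(fel: FelSpec, cfg: ModelConfig | None = None) -> LandscapeReport:
    """Minima, successive gaps, RE, barriers and span of a landscape."""
    if fel.m < 2:
        raise ValueError(f"landscape report requires m >= 2, got {fel.m}")
    cfg = cfg or ModelConfig()
    i = np.arange(fel.m, dtype=float)
    minima = fel.a * i ** fel.b
    gaps = np.diff(minima)
    barriers = np.array(
        [activation_barrier(j, fel, cfg) for j in range(fel.m - 1)]
    )
    return LandscapeReport(
        minima_ev=minima,
        gaps_ev=gaps,
        gs_reorg_ev=gs_reorg(fel, cfg),
        barriers_ev=barriers,
        span_ev=fel.span,
    )
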