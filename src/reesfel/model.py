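"""Marcus free-energy surfaces for a fluorescent ligand in discrete protein microstates.

A two-level ligand (ground state GS, charge-transfer excited state CT) is
distributed over ``m`` discrete bound microstates of a protein-ligand complex.
Each microstate ``i`` carries a pair of harmonic (Marcus) free-energy surfaces
along a collective coordinate ``x``:

* the GS surface, offset vertically by a parametric free-energy landscape
  (FEL) ``A * i**b`` and displaced horizontally by ``i * x_GS``;
* the CT surface, additionally displaced by the ligand's CT-state shift
  ``x_CT`` and raised by a CT-GS gap that interpolates linearly from
  ``dG_CTGS0`` (most stable state) to ``dG_CTGSN`` (least stable state).

Thermal equilibrium in the ground state gives Boltzmann weights over the
microstates at each ``x``; ensemble absorption and emission energies are the
weight-averaged per-microstate energies.  Emission within a microstate is
independent of the excitation energy (vibrational relaxation to the CT
minimum precedes emission, and there is no transfer between microstates
during the excited-state lifetime), so a single microstate shows zero
red-edge excitation shift.

Energies are in eV, the coordinate in eV^0.5 so that the curvature constant
``kappa`` is dimensionless (default 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("reesfel")

#: Boltzmann constant in eV/K.
K_B_EV_PER_K = 8.617333262e-5


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Global model settings: curvature, temperature and the coordinate grid.

    Parameters
    ----------
    kappa : float
        Curvature constant of all harmonic surfaces (shared between GS and
        CT states).  Dimensionless under the eV^0.5 coordinate convention.
    temperature_K : float
        Absolute temperature in kelvin.
    x_min, x_max : float
        Sweep bounds of the collective coordinate.
    n_grid : int
        Number of grid points on [x_min, x_max].
    """

    kappa: float = 1.0
    temperature_K: float = 298.0
    x_min: float = -1.0
    x_max: float = 2.0
    n_grid: int = 1001

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not self.temperature_K > 0:
            raise ValueError(
                f"temperature_K must be positive, got {self.temperature_K}"
            )
        if not self.x_min < self.x_max:
            raise ValueError(
                f"x_min must be < x_max, got [{self.x_min}, {self.x_max}]"
            )
        if self.n_grid < 3:
            raise ValueError(f"n_grid must be >= 3, got {self.n_grid}")

    @property
    def kbt(self) -> float:
        """Thermal energy k_b*T in eV."""
        return K_B_EV_PER_K * self.temperature_K

    def x_grid(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_grid)


@dataclass(frozen=True)
class LigandPhotophysics:
    """Photophysical parameters of the fluorescent ligand.

    ``x_ct`` is the displacement of the CT surface along the collective
    coordinate; ``dg_ctgs0`` / ``dg_ctgsn`` are the CT-GS free-energy gaps of
    the most and least stable microstates.  The reorganization energy is not
    stored: it is always recomputed as ``kappa * x_ct**2 / 2`` (half the
    Stokes shift).
    """

    x_ct: float
    dg_ctgs0: float
    dg_ctgsn: float

    def __post_init__(self) -> None:
        if self.x_ct < 0:
            raise ValueError(f"x_ct must be non-negative, got {self.x_ct}")
        if self.dg_ctgs0 <= 0 or self.dg_ctgsn <= 0:
            raise ValueError("CT-GS gaps must be positive")

    def reorg(self, kappa: float = 1.0) -> float:
        """Marcus reorganization energy kappa*x_ct^2/2 (eV)."""
        return 0.5 * kappa * self.x_ct ** 2


@dataclass(frozen=True)
class FelSpec:
    """Parametric ground-state free-energy landscape A*i**b over m microstates.

    Microstates are indexed ``i = 0 .. m-1`` and equally spaced along the
    coordinate by ``x_gs``; the landscape span is ``a * (m-1)**b``.
    """

    a: float
    b: float
    x_gs: float
    m: int

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"energy scale a must be >= 0, got {self.a}")
        if not self.b > 0:
            raise ValueError(f"exponent b must be positive, got {self.b}")
        if self.x_gs < 0:
            raise ValueError(f"x_gs must be >= 0, got {self.x_gs}")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")

    @property
    def span(self) -> float:
        """FEL span a*(m-1)**b in eV (zero for a single state)."""
        return self.a * float(self.m - 1) ** self.b


@dataclass(frozen=True)
class MicrostateWeights:
    """Boltzmann weights of the m microstates at one coordinate value.

    The partition value is kept in log space (``log_z``) so extreme energies
    do not underflow; ``z`` exposes exp(log_z).
    """

    x: float
    weights: np.ndarray
    log_z: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if not np.isfinite(self.log_z):
            raise ValueError("partition value must be positive and finite")

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))


def _check_index(i: int, m: int) -> None:
    if not 0 <= i <= m - 1:
        raise IndexError(
            f"microstate index i={i} out of range for m={m} states "
            f"(valid: 0..{m - 1})"
        )


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

def gs_free_energy(i, x, fel: FelSpec, cfg: ModelConfig | None = None):
    """Ground-state free energy of microstate ``i`` at coordinate ``x`` (eV).

    ``kappa*(x - i*x_gs)**2/2 + a*i**b``.  ``x`` may be a scalar or array.
    """
    cfg = cfg or ModelConfig()
    _check_index(i, fel.m)
    x = np.asarray(x, dtype=float)
    g = 0.5 * cfg.kappa * (x - i * fel.x_gs) ** 2 + fel.a * float(i) ** fel.b
    return g if g.ndim else float(g)


def ct_gap(i, fel: FelSpec, lig: LigandPhotophysics):
    """CT-GS free-energy gap of microstate ``i``.

    Linear interpolation from ``dg_ctgs0`` at i=0 to ``dg_ctgsn`` at the top
    state i=m-1; a single-state model uses ``dg_ctgs0``.
    """
    if fel.m == 1:
        return lig.dg_ctgs0 * np.ones_like(np.asarray(i, dtype=float)) \
            if np.ndim(i) else lig.dg_ctgs0
    frac = np.asarray(i, dtype=float) / (fel.m - 1)
    g = lig.dg_ctgs0 + frac * (lig.dg_ctgsn - lig.dg_ctgs0)
    return g if g.ndim else float(g)


def ct_free_energy(
    i, x, fel: FelSpec, lig: LigandPhotophysics, cfg: ModelConfig | None = None
):
    """CT-state free energy of microstate ``i`` at coordinate ``x`` (eV)."""
    cfg = cfg or ModelConfig()
    _check_index(i, fel.m)
    x = np.asarray(x, dtype=float)
    g = (
        0.5 * cfg.kappa * (x - i * fel.x_gs - lig.x_ct) ** 2
        + fel.a * float(i) ** fel.b
        + ct_gap(i, fel, lig)
    )
    return g if g.ndim else float(g)


# ---------------------------------------------------------------------------
# Boltzmann populations
# ---------------------------------------------------------------------------

def _gs_energy_matrix(xs: np.ndarray, fel: FelSpec, cfg: ModelConfig) -> np.ndarray:
    """GS energies, shape (len(xs), m)."""
    i = np.arange(fel.m, dtype=float)
    return (
        0.5 * cfg.kappa * (xs[:, None] - i[None, :] * fel.x_gs) ** 2
        + fel.a * i[None, :] ** fel.b
    )


def _weights_matrix(xs: np.ndarray, fel: FelSpec, cfg: ModelConfig) -> np.ndarray:
    """Normalized Boltzmann weights on a coordinate grid, shape (len(xs), m).

    Stabilized by subtracting the row-minimum energy before exponentiation;
    the shift cancels in the normalization.
    """
    g = _gs_energy_matrix(xs, fel, cfg)
    g -= g.min(axis=1, keepdims=True)
    w = np.exp(-g / cfg.kbt)
    return w / w.sum(axis=1, keepdims=True)


def boltzmann_weights(
    x: float, fel: FelSpec, cfg: ModelConfig | None = None
) -> MicrostateWeights:
    """Equilibrium microstate populations at coordinate ``x`` (Boltzmann)."""
    cfg = cfg or ModelConfig()
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"coordinate must be finite, got {x}")
    g = _gs_energy_matrix(np.array([x]), fel, cfg)[0]
    gmin = g.min()
    shifted = np.exp(-(g - gmin) / cfg.kbt)
    z_shifted = shifted.sum()
    log_z = float(-gmin / cfg.kbt + np.log(z_shifted))
    return MicrostateWeights(x=x, weights=shifted / z_shifted, log_z=log_z)


# ---------------------------------------------------------------------------
# per-microstate and ensemble transition energies
# ---------------------------------------------------------------------------

def microstate_abs_energy(
    i,
    x,
    fel: FelSpec,
    lig: LigandPhotophysics,
    cfg: ModelConfig | None = None,
    strict_surfaces: bool = False,
):
    """Absorption energy GS->CT of microstate ``i`` at coordinate ``x`` (eV).

    Default: ``gap(i) + reorg - kappa*x*x_ct`` — the same linear function of
    ``x`` for every microstate.  With ``strict_surfaces=True`` the vertical
    gap is taken directly between the two harmonic surfaces, which adds a
    ``kappa*i*x_gs*x_ct`` cross-term (diagnostic mode).
    """
    cfg = cfg or ModelConfig()
    _check_index(i, fel.m)
    x = np.asarray(x, dtype=float)
    reorg = lig.reorg(cfg.kappa)
    if strict_surfaces:
        e = ct_gap(i, fel, lig) + reorg - cfg.kappa * (x - i * fel.x_gs) * lig.x_ct
    else:
        e = ct_gap(i, fel, lig) + reorg - cfg.kappa * x * lig.x_ct
    return e if e.ndim else float(e)


def microstate_em_energy(
    i, fel: FelSpec, lig: LigandPhotophysics, kappa: float = 1.0
):
    """Peak emission energy CT->GS of microstate ``i`` (eV).

    ``gap(i) - reorg``; independent of the excitation coordinate because the
    CT state relaxes to its minimum before emitting.
    """
    _check_index(i, fel.m)
    return ct_gap(i, fel, lig) - lig.reorg(kappa)


def ensemble_abs_energy(
    x,
    fel: FelSpec,
    lig: LigandPhotophysics,
    cfg: ModelConfig | None = None,
    strict_surfaces: bool = False,
):
    """Population-weighted ensemble absorption energy at coordinate ``x`` (eV)."""
    cfg = cfg or ModelConfig()
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    w = _weights_matrix(xs, fel, cfg)
    i = np.arange(fel.m)
    reorg = lig.reorg(cfg.kappa)
    gaps = np.atleast_1d(ct_gap(i, fel, lig))
    if strict_surfaces:
        e_im = (
            gaps[None, :]
            + reorg
            - cfg.kappa * (xs[:, None] - i[None, :] * fel.x_gs) * lig.x_ct
        )
    else:
        e_im = gaps[None, :] + reorg - cfg.kappa * xs[:, None] * lig.x_ct
    e = (w * e_im).sum(axis=1)
    return e if np.ndim(x) else float(e[0])


def ensemble_em_energy(
    x, fel: FelSpec, lig: LigandPhotophysics, cfg: ModelConfig | None = None
):
    """Population-weighted mean emission energy at coordinate ``x`` (eV)."""
    cfg = cfg or ModelConfig()
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    w = _weights_matrix(xs, fel, cfg)
    i = np.arange(fel.m)
    em_i = np.atleast_1d(ct_gap(i, fel, lig)) - lig.reorg(cfg.kappa)
    e = (w * em_i[None, :]).sum(axis=1)
    return e if np.ndim(x) else float(e[0])
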