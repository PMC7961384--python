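"""Ligand photophysics from spectral observables.

Three of the model's parameters belong to the ligand and are fixed from
experiment before any landscape fitting: the reorganization energy is half
the Stokes shift between the absorption maximum and the blue emission
endpoint, the CT-GS gap of the most stable state is their average, and the
gap of the least stable state follows from the blue-red emission endpoint
separation.
"""

from __future__ import annotations

import logging
import math

from .fitting import SigmoidFit
from .model import LigandPhotophysics
from .spectra import wavelength_to_energy

logger = logging.getLogger("reesfel")


def ligand_from_spectra(
    abs_max: float, em_blue: float, em_red: float, kappa: float = 1.0
) -> LigandPhotophysics:
    """Ligand parameters from the absorption maximum and the two emission
    endpoints (all in eV).

    reorg = (abs_max - em_blue)/2, dG_CTGS0 = (abs_max + em_blue)/2,
    dG_CTGSN = dG_CTGS0 - (em_blue - em_red), x_CT = sqrt(2*reorg/kappa).
    """
    if not (abs_max > 0 and em_blue > 0 and em_red > 0):
        raise ValueError("spectral energies must be positive")
    if em_blue > abs_max:
        raise ValueError(
            f"negative Stokes shift: em_blue ({em_blue} eV) exceeds "
            f"abs_max ({abs_max} eV)"
        )
    if em_red > em_blue:
        raise ValueError(
            f"em_red ({em_red} eV) exceeds em_blue ({em_blue} eV)"
        )
    reorg = 0.5 * (abs_max - em_blue)
    dg0 = 0.5 * (abs_max + em_blue)
    dgn = dg0 - (em_blue - em_red)
    x_ct = math.sqrt(2.0 * reorg / kappa)
    return LigandPhotophysics(x_ct=x_ct, dg_ctgs0=dg0, dg_ctgsn=dgn)


def endpoints_from_sigmoid(sig: SigmoidFit) -> tuple[float, float]:
    """(em_blue, em_red) energies in eV from a sigmoid fit's asymptotes.

    The blue endpoint is the shorter-wavelength asymptote; inverted
    asymptotes are reordered with a warning, a degenerate (flat) fit yields
    equal endpoints.
    """
    blue_nm, red_nm = sig.em_blue_nm, sig.em_red_nm
    if blue_nm > red_nm:
        logger.warning(
            "sigmoid asymptotes given red-first (%.1f > %.1f nm); reordering",
            blue_nm, red_nm,
        )
        blue_nm, red_nm = red_nm, blue_nm
    if sig.degenerate:
        logger.warning("degenerate sigmoid fit: equal emission endpoints")
    return wavelength_to_energy(blue_nm), wavelength_to_energy(red_nm)
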