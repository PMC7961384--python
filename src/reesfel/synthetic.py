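"""Synthetic REES datasets with known ground truth, and parameter recovery.

The experimental REES points behind the two kinase-inhibitor case studies
were never published as tables, so reference datasets are reconstructed from
the fitted parameters: the simulator evaluates the theoretical curve,
samples it on an excitation grid spanning the transition, and optionally
adds independent Gaussian noise to the emission wavelengths.  The recovery
experiment closes the loop — simulate, sigmoid-fit, landscape-fit with all
parameters free — and records how well the known inputs come back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fitting import FelFitResult, ReesDataset, fit_sigmoid, scan_models
from .model import FelSpec, LigandPhotophysics, ModelConfig
from .spectra import simulate_rees_curve

logger = logging.getLogger("reesfel")

#: Fitted case-study parameters of the two reconstructed complexes.
P38A_LIGAND = LigandPhotophysics(x_ct=0.891, dg_ctgs0=3.347, dg_ctgsn=3.223)
P38A_FEL = FelSpec(a=0.00178, b=2.0, x_gs=0.153, m=10)
APH_LIGAND = LigandPhotophysics(x_ct=1.076, dg_ctgs0=3.172, dg_ctgsn=3.015)
APH_FEL = FelSpec(a=0.00172, b=2.0, x_gs=0.258, m=5)


@dataclass(frozen=True)
class RecoveryResult:
    """One simulate-then-refit row: ground truth vs. recovered landscape."""

    true_fel: FelSpec
    ligand: LigandPhotophysics
    recovered: FelFitResult
    rel_errors: dict

    @property
    def max_rel_error(self) -> float:
        return max(self.rel_errors.values())


def transition_grid_nm(
    lig: LigandPhotophysics,
    fel: FelSpec,
    cfg: ModelConfig | None = None,
    n: int = 10,
    band: tuple[float, float] = (0.02, 0.98),
) -> np.ndarray:
    """Excitation grid (nm) covering the given fractional band of the
    model curve's emission transition."""
    cfg = cfg or ModelConfig()
    curve = simulate_rees_curve(lig, fel, cfg)
    em = curve.em_nm
    lo_em = em[0] + band[0] * (em[-1] - em[0])
    hi_em = em[0] + band[1] * (em[-1] - em[0])
    ex_lo = float(np.interp(lo_em, em, curve.ex_nm))
    ex_hi = float(np.interp(hi_em, em, curve.ex_nm))
    return np.linspace(ex_lo, ex_hi, n)


def generate_rees_dataset(
    lig: LigandPhotophysics,
    fel: FelSpec,
    cfg: ModelConfig | None,
    ex_grid_nm: np.ndarray,
    noise_sd_nm: float,
    seed: int,
) -> ReesDataset:
    """Sample the theoretical curve on an excitation grid, with optional
    Gaussian noise (sd in nm) on the emission wavelengths.

    The seed is mandatory: identical seeds give identical datasets.
    """
    if noise_sd_nm < 0:
        raise ValueError(f"noise_sd_nm must be >= 0, got {noise_sd_nm}")
    cfg = cfg or ModelConfig()
    curve = simulate_rees_curve(lig, fel, cfg)
    em = curve.resample_em_nm(np.asarray(ex_grid_nm, dtype=float))
    if noise_sd_nm > 0:
        rng = np.random.default_rng(seed)
        em = em + rng.normal(0.0, noise_sd_nm, size=em.shape)
    meta = (
        f"synthetic: m={fel.m} b={fel.b:g} A={fel.a:g} x_gs={fel.x_gs:g} "
        f"noise_sd={noise_sd_nm:g} seed={seed}"
    )
    return ReesDataset(ex_nm=np.asarray(ex_grid_nm, float), em_nm=em, meta=meta)


def recovery_experiment(
    span_values,
    m_true: int = 10,
    b_true: float = 2.0,
    lig: LigandPhotophysics = P38A_LIGAND,
    cfg: ModelConfig | None = None,
    seed: int = 20210304,
    x_gs_true: float = 0.153,
    m_scan=range(5, 16),
    n_points: int = 10,
    noise_sd_nm: float = 0.0,
) -> list[RecoveryResult]:
    """Simulate-then-refit validation over a set of input landscape spans.

    For each span, the energy scale is A = span/(m_true-1)**b_true; a
    dataset is simulated and condensed to a sigmoid (recording the quality
    of that representation), then the landscape is refit against the raw
    points with the state count scanned over ``m_scan`` and the exponent b
    free.  Relative errors are recorded for the span, the state count and
    the exponent.
    """
    cfg = cfg or ModelConfig()
    results: list[RecoveryResult] = []
    for row, span in enumerate(span_values):
        if not span > 0:
            raise ValueError(f"span must be positive, got {span}")
        a = span / float(m_true - 1) ** b_true
        true_fel = FelSpec(a=a, b=b_true, x_gs=x_gs_true, m=m_true)
        try:
            grid = transition_grid_nm(lig, true_fel, cfg, n=n_points)
            data = generate_rees_dataset(
                lig, true_fel, cfg, grid, noise_sd_nm, seed + row
            )
            sig = fit_sigmoid(data)
            comp = scan_models(
                sig, lig, m_scan, "free", cfg=cfg, criterion="slsq", data=data
            )
        except (RuntimeError, ValueError) as err:
            logger.warning("recovery row span=%.3g failed: %s", span, err)
            continue
        rec = comp.best_result
        rel = {
            "span": abs(rec.fel.span - span) / span,
            "m": abs(rec.fel.m - m_true) / m_true,
            "b": abs(rec.fel.b - b_true) / b_true,
        }
        results.append(
            RecoveryResult(
                true_fel=true_fel, ligand=lig, recovered=rec, rel_errors=rel
            )
        )
    return results


def make_reference_fixtures(
    cfg: ModelConfig | None = None, n_points: int = 10
) -> dict:
    """Reconstructed noiseless case-study datasets with their ligands.

    Returns ``{"p38a": (dataset, ligand, fel), "aph": (dataset, ligand, fel)}``
    sampled across each model's transition band.
    """
    cfg = cfg or ModelConfig()
    out = {}
    for name, lig, fel in (
        ("p38a", P38A_LIGAND, P38A_FEL),
        ("aph", APH_LIGAND, APH_FEL),
    ):
        grid = transition_grid_nm(lig, fel, cfg, n=n_points)
        data = generate_rees_dataset(lig, fel, cfg, grid, 0.0, seed=0)
        out[name] = (data, lig, fel)
    return out
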