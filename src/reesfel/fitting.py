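"""Fitting REES data: Boltzmann sigmoid, FEL least squares, AIC model scans.

The pipeline mirrors standard practice for REES analysis: observed
(excitation, peak-emission) wavelength pairs are first condensed into a
four-parameter Boltzmann sigmoid

    em(ex) = em_red + (em_blue - em_red) / (1 + exp((ex - mid) / width))

whose asymptotes fix the ligand photophysics; the theoretical microstate
model is then fit to that sigmoid representation by adjusting the landscape
parameters (A, x_GS; optionally the exponent b), once per candidate state
count m.  Candidates are ranked by the sum of least squares (SLSQ, nm^2) or
by the Akaike information criterion AIC = 2k + n*ln(LSQ) when models with
different parameter counts are compared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit, minimize

from .model import FelSpec, LigandPhotophysics, ModelConfig
from .spectra import simulate_rees_curve

logger = logging.getLogger("reesfel")

# optimizer bounds for the landscape fit
A_BOUNDS = (1e-5, 0.2)       # eV
X_GS_BOUNDS = (0.005, 0.5)   # eV^0.5
B_BOUNDS = (0.5, 4.0)
SLSQ_TOL = 1e-10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReesDataset:
    """Observed REES points: excitation vs. peak emission wavelength (nm)."""

    ex_nm: np.ndarray
    em_nm: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        ex = np.asarray(self.ex_nm, dtype=float)
        em = np.asarray(self.em_nm, dtype=float)
        if ex.shape != em.shape or ex.ndim != 1:
            raise ValueError("ex_nm and em_nm must be 1-d arrays of equal length")
        order = np.argsort(ex)
        object.__setattr__(self, "ex_nm", ex[order])
        object.__setattr__(self, "em_nm", em[order])

    def __len__(self) -> int:
        return len(self.ex_nm)


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter Boltzmann sigmoid representation of a REES dataset."""

    em_blue_nm: float
    em_red_nm: float
    mid_nm: float
    width_nm: float
    residual_ss: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.width_nm > 0:
            raise ValueError(f"width_nm must be positive, got {self.width_nm}")
        if self.residual_ss < 0:
            raise ValueError("residual_ss must be non-negative")

    def __call__(self, ex_nm):
        ex = np.asarray(ex_nm, dtype=float)
        out = self.em_red_nm + (self.em_blue_nm - self.em_red_nm) / (
            1.0 + np.exp((ex - self.mid_nm) / self.width_nm)
        )
        return out if out.ndim else float(out)

    def transition_grid(self, n: int = 50, frac: float = 0.01) -> np.ndarray:
        """Evenly spaced excitation grid across the 1-99% transition band."""
        half = self.width_nm * np.log((1 - frac) / frac)
        return np.linspace(self.mid_nm - half, self.mid_nm + half, n)


@dataclass(frozen=True)
class FelFitResult:
    """One fitted landscape candidate with its goodness-of-fit."""

    fel: FelSpec
    slsq: float
    n_free_params: int
    aic: float
    n_points: int
    error: str | None = None

    def __post_init__(self) -> None:
        if self.error is None and self.slsq < 0:
            raise ValueError("slsq must be non-negative")
        if self.n_free_params not in (2, 3, 4):
            raise ValueError(
                f"n_free_params must be 2, 3 or 4, got {self.n_free_params}"
            )


@dataclass(frozen=True)
class ModelComparison:
    """Candidate landscape fits ranked by SLSQ or AIC."""

    results: tuple
    best: int
    criterion: str

    @property
    def best_result(self) -> FelFitResult:
        return self.results[self.best]


# ---------------------------------------------------------------------------
# sigmoid fit
# ---------------------------------------------------------------------------

def _sigmoid(ex, em_blue, em_red, mid, width):
    return em_red + (em_blue - em_red) / (1.0 + np.exp((ex - mid) / width))


def fit_sigmoid(data: ReesDataset) -> SigmoidFit:
    """Least-squares Boltzmann-sigmoid fit with multi-start initialization.

    Starts are built from the data extremes (asymptotes), the median and the
    half-transition crossing (mid-point), and several width guesses.
    """
    if len(data) < 5:
        raise ValueError(
            f"sigmoid fit needs at least 5 points, got {len(data)}"
        )
    ex, em = data.ex_nm, data.em_nm
    em_span = float(em.max() - em.min())
    if em_span < 1e-6:
        logger.warning("flat REES data: returning degenerate sigmoid fit")
        return SigmoidFit(
            em_blue_nm=float(em.mean()),
            em_red_nm=float(em.mean()),
            mid_nm=float(np.median(ex)),
            width_nm=1.0,
            residual_ss=float(((em - em.mean()) ** 2).sum()),
            degenerate=True,
        )

    ex_span = float(ex.max() - ex.min())
    mid_em = 0.5 * (em.min() + em.max())
    cross = float(np.interp(mid_em, em, ex)) if np.all(np.diff(em) >= 0) else float(
        np.median(ex)
    )
    starts = [
        (em[0], em[-1], m0, w0)
        for m0 in (cross, float(np.median(ex)))
        for w0 in (ex_span / 20, ex_span / 8, ex_span / 3)
    ]
    lower = [em.min() - 5 * em_span, em.min() - 5 * em_span, ex.min() - ex_span, 1e-3]
    upper = [em.max() + 5 * em_span, em.max() + 5 * em_span, ex.max() + ex_span, 10 * ex_span]

    best = None
    last_err: Exception | None = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _sigmoid, ex, em, p0=p0, bounds=(lower, upper), maxfev=20000
                )
            ss = float(((em - _sigmoid(ex, *popt)) ** 2).sum())
            if best is None or ss < best[1]:
                best = (popt, ss)
        except (RuntimeError, ValueError) as err:  # non-convergence at this start
            last_err = err
    if best is None:
        raise RuntimeError(f"sigmoid fit failed to converge: {last_err}")
    popt, ss = best
    return SigmoidFit(
        em_blue_nm=float(popt[0]),
        em_red_nm=float(popt[1]),
        mid_nm=float(popt[2]),
        width_nm=float(popt[3]),
        residual_ss=ss,
    )


# ---------------------------------------------------------------------------
# FEL objective and fit
# ---------------------------------------------------------------------------

def _curve_slsq(
    fel: FelSpec,
    lig: LigandPhotophysics,
    eval_ex_nm: np.ndarray,
    em_target_fn,
    cfg: ModelConfig,
    warn_on_clip: bool = True,
) -> float:
    """Sum of squared emission differences (nm^2) between the simulated curve
    and a target emission function on the evaluation excitation grid."""
    curve = simulate_rees_curve(lig, fel, cfg)
    ex = np.asarray(eval_ex_nm, dtype=float)
    lo, hi = curve.ex_nm[0], curve.ex_nm[-1]
    inside = (ex >= lo) & (ex <= hi)
    if not inside.any():
        raise ValueError(
            f"evaluation grid [{ex.min():.1f}, {ex.max():.1f}] nm does not "
            f"overlap the model excitation range [{lo:.1f}, {hi:.1f}] nm"
        )
    if not inside.all():
        log = logger.warning if warn_on_clip else logger.debug
        log(
            "clipping %d evaluation points outside the model excitation range",
            int((~inside).sum()),
        )
    em_model = np.interp(ex[inside], curve.ex_nm, curve.em_nm)
    em_target = np.asarray(em_target_fn(ex))[inside]
    return float(((em_model - em_target) ** 2).sum())


def fel_objective(
    fel: FelSpec,
    lig: LigandPhotophysics,
    sig: SigmoidFit,
    eval_ex_nm: np.ndarray,
    cfg: ModelConfig | None = None,
) -> float:
    """Sum of squared emission differences (nm^2) between the simulated curve
    and the sigmoid representation, on the evaluation excitation grid."""
    return _curve_slsq(fel, lig, np.asarray(eval_ex_nm, float), sig,
                       cfg or ModelConfig())


def aic(k: int, n: int, lsq: float) -> float:
    """Akaike information criterion 2k + n*ln(LSQ)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not lsq > 0:
        raise ValueError(f"lsq must be positive, got {lsq}")
    return 2.0 * k + n * float(np.log(lsq))


def _safe_aic(k: int, n: int, lsq: float) -> float:
    return aic(k, n, lsq) if lsq > 0 else float("-inf")


def fit_fel(
    sig: SigmoidFit,
    lig: LigandPhotophysics,
    m: int,
    b: float,
    cfg: ModelConfig | None = None,
    eval_ex_nm: np.ndarray | None = None,
    free_b: bool = False,
    data: ReesDataset | None = None,
) -> FelFitResult:
    """Fit landscape parameters (A, x_GS), optionally the exponent b, by
    bounded multi-start Nelder-Mead search.

    The default target is the sigmoid representation, evaluated on
    ``eval_ex_nm`` (the sigmoid's 1-99% transition grid when omitted).  When
    ``data`` is given the raw points are the target instead: the residuals
    are taken against the observed emission wavelengths at the dataset's
    excitation wavelengths.  A is searched in log space over [1e-5, 0.2] eV,
    x_GS linearly over [0.005, 0.5] eV^0.5; the 2-parameter fit uses a 5x5
    start grid, the free-b fit a 3x3 grid with three exponent starts.
    """
    if m < 2:
        raise ValueError(f"FEL fit requires m >= 2, got {m}")
    if not b > 0:
        raise ValueError(f"b must be positive, got {b}")
    cfg = cfg or ModelConfig()
    if data is not None:
        eval_ex_nm = data.ex_nm
        target_fn = lambda ex: np.interp(ex, data.ex_nm, data.em_nm)  # noqa: E731
    else:
        if eval_ex_nm is None:
            eval_ex_nm = sig.transition_grid()
        target_fn = sig
    eval_ex_nm = np.asarray(eval_ex_nm, dtype=float)
    n = len(eval_ex_nm)

    def objective(params) -> float:
        la, xgs = params[0], params[1]
        bb = params[2] if free_b else b
        try:
            fel = FelSpec(a=10.0 ** la, b=bb, x_gs=xgs, m=m)
            return _curve_slsq(
                fel, lig, eval_ex_nm, target_fn, cfg, warn_on_clip=False
            )
        except (ValueError, IndexError):
            return 1e12

    la_lo, la_hi = np.log10(A_BOUNDS[0]), np.log10(A_BOUNDS[1])
    n_start = 3 if free_b else 5
    la_starts = np.linspace(la_lo + 0.3, la_hi - 0.3, n_start)
    xgs_starts = np.linspace(X_GS_BOUNDS[0] + 0.02, X_GS_BOUNDS[1] - 0.05, n_start)
    b_starts = (1.5, 2.0, 2.5) if free_b else (b,)

    bounds = [(la_lo, la_hi), X_GS_BOUNDS] + ([B_BOUNDS] if free_b else [])
    best = None
    failures = []
    for la0 in la_starts:
        for x0 in xgs_starts:
            for b0 in b_starts:
                p0 = [la0, x0] + ([b0] if free_b else [])
                try:
                    res = minimize(
                        objective,
                        p0,
                        method="Nelder-Mead",
                        bounds=bounds,
                        options={"fatol": SLSQ_TOL, "xatol": 1e-6, "maxiter": 600},
                    )
                except Exception as err:  # pragma: no cover - defensive
                    failures.append(str(err))
                    continue
                if best is None or res.fun < best.fun:
                    best = res
    if best is None or best.fun >= 1e12:
        raise RuntimeError(
            f"FEL fit failed for m={m}, b={b}: no start converged "
            f"({failures[:3]})"
        )
    la, xgs = best.x[0], best.x[1]
    b_fit = float(best.x[2]) if free_b else float(b)
    a_fit = float(10.0 ** la)
    if a_fit <= A_BOUNDS[0] * 1.01:
        logger.warning(
            "fitted A at its lower bound (%.2g eV): no resolvable transition", a_fit
        )
    fel = FelSpec(a=a_fit, b=b_fit, x_gs=float(xgs), m=m)
    k = 3 if free_b else 2
    slsq = float(best.fun)
    return FelFitResult(
        fel=fel, slsq=slsq, n_free_params=k, aic=_safe_aic(k, n, slsq), n_points=n
    )


def scan_models(
    sig: SigmoidFit,
    lig: LigandPhotophysics,
    m_range,
    b_values,
    cfg: ModelConfig | None = None,
    eval_ex_nm: np.ndarray | None = None,
    criterion: str = "slsq",
    data: ReesDataset | None = None,
) -> ModelComparison:
    """Fit every candidate (m, b) and rank by the configured criterion.

    ``b_values`` is an iterable of exponents, or the string ``"free"`` to fit
    b continuously within each m.  ``data`` switches every candidate fit to
    the raw-points target (see :func:`fit_fel`).  Candidates whose fit fails
    are recorded with an error flag rather than aborting the scan.  Ties
    break toward smaller m (parsimony); when m is scanned AIC bookkeeping
    counts it as a third free parameter (fourth with b free).
    """
    cfg = cfg or ModelConfig()
    if eval_ex_nm is None:
        eval_ex_nm = data.ex_nm if data is not None else sig.transition_grid()
    m_list = list(m_range)
    if not m_list:
        raise ValueError("empty candidate set")
    free_b = isinstance(b_values, str) and b_values == "free"
    b_list = [None] if free_b else list(b_values)
    if not b_list:
        raise ValueError("empty candidate set")
    scan_m = len(m_list) > 1

    results = []
    for m in m_list:
        for b in b_list:
            try:
                r = fit_fel(
                    sig, lig, m, b if b is not None else 2.0,
                    cfg=cfg, eval_ex_nm=eval_ex_nm, free_b=free_b, data=data,
                )
                if scan_m:
                    k = r.n_free_params + 1
                    r = replace(
                        r, n_free_params=k, aic=_safe_aic(k, r.n_points, r.slsq)
                    )
            except (RuntimeError, ValueError) as err:
                logger.warning("candidate m=%s b=%s failed: %s", m, b, err)
                r = FelFitResult(
                    fel=FelSpec(a=0.0, b=b or 2.0, x_gs=0.0, m=max(m, 1)),
                    slsq=float("inf"),
                    n_free_params=2,
                    aic=float("inf"),
                    n_points=len(eval_ex_nm),
                    error=str(err),
                )
            results.append(r)

    if criterion not in ("slsq", "aic"):
        raise ValueError(f"criterion must be 'slsq' or 'aic', got {criterion!r}")
    values = [getattr(r, criterion) if r.error is None else float("inf") for r in results]
    if not np.isfinite(min(values)):
        raise RuntimeError("all scan candidates failed")
    # argmin with ties broken toward smaller m
    best = min(
        range(len(results)), key=lambda j: (values[j], results[j].fel.m)
    )
    return ModelComparison(results=tuple(results), best=best, criterion=criterion)
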