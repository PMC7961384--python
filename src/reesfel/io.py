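"""File formats: REES dataset CSV, landscape CSV and the JSON fit report."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .fitting import FelFitResult, ModelComparison, ReesDataset, SigmoidFit
from .thermo import BindingDecomposition, LandscapeReport

logger = logging.getLogger("reesfel")

REPORT_SCHEMA_VERSION = 1
_REQUIRED_COLUMNS = ("excitation_nm", "emission_nm")


def read_rees_csv(path) -> ReesDataset:
    """Read a two-column REES dataset CSV ("excitation_nm,emission_nm").

    Lines starting with '#' are comments; rows are sorted by excitation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    df = df[list(_REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)].index.tolist()
        raise ValueError(f"non-numeric rows {bad} in {path}")
    if len(df) < 2:
        raise ValueError(f"need at least 2 data rows, got {len(df)} in {path}")
    return ReesDataset(
        ex_nm=df["excitation_nm"].to_numpy(),
        em_nm=df["emission_nm"].to_numpy(),
        meta=f"read from {path}",
    )


def write_rees_csv(data: ReesDataset, path) -> None:
    pd.DataFrame(
        {"excitation_nm": data.ex_nm, "emission_nm": data.em_nm}
    ).to_csv(path, index=False)


def _fit_result_dict(r: FelFitResult) -> dict:
    return {
        "m": int(r.fel.m),
        "b": float(r.fel.b),
        "a_ev": float(r.fel.a),
        "x_gs": float(r.fel.x_gs),
        "span_ev": float(r.fel.span),
        "slsq": float(r.slsq),
        "n_free_params": int(r.n_free_params),
        "aic": float(r.aic),
        "n_points": int(r.n_points),
        "error": r.error,
    }


def write_report(
    path,
    sigmoid: SigmoidFit,
    comparison: ModelComparison,
    landscape: LandscapeReport,
    decomposition: BindingDecomposition | None = None,
    extra: dict | None = None,
) -> dict:
    """Write the machine-readable JSON fit report plus a landscape CSV.

    ``path`` is the JSON file; the landscape CSV lands next to it with a
    ``_landscape.csv`` suffix.  Returns the report dict.
    """
    if not comparison.results:
        raise ValueError("empty model comparison: nothing to report")
    path = Path(path)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "sigmoid": asdict(sigmoid),
        "criterion": comparison.criterion,
        "candidates": [_fit_result_dict(r) for r in comparison.results],
        "best": _fit_result_dict(comparison.best_result),
        "landscape": landscape.to_dict(),
    }
    if decomposition is not None:
        report["binding_decomposition"] = asdict(decomposition)
    if extra:
        report["extra"] = extra
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    landscape.to_frame().to_csv(
        path.with_name(path.stem + "_landscape.csv"), index=False
    )
    return report


def read_report(path) -> dict:
    """Read back a JSON fit report."""
    return json.loads(Path(path).read_text())
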