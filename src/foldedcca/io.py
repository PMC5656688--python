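"""Delimited-text I/O: matrices, loadings, CV summaries, run manifests.

Matrices are plain CSV/TSV tables (rows = subjects, columns = features)
with an optional header row and row-ID column; genotype/imaging extraction
to numeric matrices is upstream of this package.  Outputs are TSV plus
JSON manifests so every run is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .penalties import PenaltySpec
from .solver import DISPLAY_ZERO_TOL, Dataset, FitResult, SolverConfig
from .evaluate import CVReport, GridSearchResult
from .simulate import SimulationDesign

__all__ = [
    "read_matrix",
    "load_dataset",
    "write_matrix",
    "write_dataset",
    "write_fit",
    "write_cv_report",
]


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_matrix(
    path,
    delimiter: Optional[str] = None,
    header: bool = True,
    index_col: Optional[int] = None,
):
    """Read a rectangular numeric table.

    Returns ``(matrix, row_ids, col_names)``; ``row_ids`` is None unless
    ``index_col`` is given.  Ragged rows and non-numeric cells raise a
    descriptive error naming the offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if header else None,
            index_col=index_col,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty table")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        cell = df[col][~df[col].apply(lambda x: isinstance(x, (int, float)))]
        row = cell.index[0] if len(cell) else "?"
        raise ValueError(
            f"{path}: non-numeric value in column {col!r} (row {row})"
        )
    matrix = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(matrix)):
        r, c = np.argwhere(~np.isfinite(matrix))[0]
        raise ValueError(f"{path}: non-finite value at row {r}, column {c}")
    row_ids = [str(i) for i in df.index] if index_col is not None else None
    col_names = [str(c) for c in df.columns] if header else None
    return matrix, row_ids, col_names


def load_dataset(
    x_path,
    y_path,
    covariates_path=None,
    delimiter: Optional[str] = None,
    header: bool = True,
) -> tuple[Dataset, Optional[np.ndarray]]:
    """Load paired X/Y matrices (and optional covariates), validating rows."""
    X, rx, cx = read_matrix(x_path, delimiter, header)
    Y, _, cy = read_matrix(y_path, delimiter, header)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"row-count mismatch: {x_path} has {X.shape[0]} rows, "
            f"{y_path} has {Y.shape[0]}"
        )
    C = None
    if covariates_path is not None:
        C, *_ = read_matrix(covariates_path, delimiter, header)
        if C.shape[0] != X.shape[0]:
            raise ValueError(
                f"row-count mismatch: covariates file has {C.shape[0]} rows, "
                f"X has {X.shape[0]}"
            )
    return Dataset(X=X, Y=Y, row_ids=rx, x_names=cx, y_names=cy), C


def write_matrix(M: np.ndarray, path, col_prefix: str = "f") -> None:
    path = Path(path)
    sep = _delimiter_for(path, None)
    cols = [f"{col_prefix}{j}" for j in range(M.shape[1])]
    pd.DataFrame(M, columns=cols).to_csv(path, sep=sep, index=False)


def write_dataset(dataset: Dataset, outdir, design: Optional[SimulationDesign] = None) -> None:
    """Write X/Y (CSV), ground-truth loadings (TSV) and a design manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.X, outdir / "X.csv", "x")
    write_matrix(dataset.Y, outdir / "Y.csv", "y")
    for name, w in (("true_u", dataset.true_u), ("true_v", dataset.true_v)):
        if w is not None:
            _write_loadings(w, None, outdir / f"{name}.tsv", raw_only=True)
    manifest = {"n": dataset.n, "p": dataset.p, "q": dataset.q}
    if design is not None:
        manifest.update(
            name=design.name,
            signal_scale=design.signal_scale,
            seed=design.seed,
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _write_loadings(w, names, path, raw_only: bool = False) -> None:
    names = names if names is not None else [f"f{j}" for j in range(len(w))]
    data = {"feature_id": list(names), "weight": [repr(float(x)) for x in w]}
    if not raw_only:
        disp = np.where(np.abs(w) < DISPLAY_ZERO_TOL, 0.0, w)
        data["weight_display"] = disp
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_loadings(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df["weight"].to_numpy(dtype=float)


def _spec_dict(spec: PenaltySpec) -> dict:
    return {"family": spec.family, "lam": spec.lam, "gamma": spec.gamma}


def write_fit(
    result: FitResult,
    outdir,
    x_names=None,
    y_names=None,
    spec_u: Optional[PenaltySpec] = None,
    spec_v: Optional[PenaltySpec] = None,
    config: Optional[SolverConfig] = None,
) -> None:
    """Write loadings (u.tsv, v.tsv) and a run manifest.

    The ``weight`` column keeps full precision (round-trips exactly);
    ``weight_display`` applies the sparsity display threshold.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_loadings(result.u, x_names, outdir / "u.tsv")
    _write_loadings(result.v, y_names, outdir / "v.tsv")
    manifest = {
        "corr": result.corr,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "objective_final": result.objective_trace[-1] if result.objective_trace else None,
    }
    if spec_u is not None:
        manifest["penalty_u"] = _spec_dict(spec_u)
    if spec_v is not None:
        manifest["penalty_v"] = _spec_dict(spec_v)
    if config is not None:
        manifest["solver"] = asdict(config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def write_cv_report(
    report,
    outdir,
    name: str = "cv",
) -> None:
    """Write a CV (or grid-search) summary TSV plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(report, GridSearchResult):
        frame = report.to_frame()
        manifest = {
            "family": report.family,
            "best_gamma": report.best_gamma,
            "summary": report.best_report.summary(),
            "seed": report.best_report.seed,
            "k": report.best_report.k,
            "solver": asdict(report.best_report.config),
        }
    elif isinstance(report, CVReport):
        frame = report.to_frame()
        manifest = {
            "penalty_u": _spec_dict(report.spec_u),
            "penalty_v": _spec_dict(report.spec_v),
            "summary": report.summary(),
            "seed": report.seed,
            "k": report.k,
            "solver": asdict(report.config),
        }
    else:
        raise TypeError(f"unsupported report type {type(report)!r}")
    frame.to_csv(outdir / f"{name}_folds.tsv", sep="\t", index=False)
    (outdir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2))
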