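"""Reading, writing and run configuration.

One canonical interchange format: a delimited long-format table with
columns id, age_months, count, exposure (bin codes are always derived,
never required). Fit results and bin diagnostics are written as a JSON
document plus CSV tables; numeric fields round-trip at full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .measurement import SelectionReport
from .model import FitResult

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_long_table", "write_report", "read_fit_json"]

CANONICAL = ("id", "age_months", "count", "exposure")


@dataclass
class RunConfig:
    """Settings for a pipeline run; every stochastic stage has an explicit seed."""

    input_path: str = ""
    out_dir: str = "."
    bin_width: float = 3.0
    origin: float = 18.0
    max_age: float = 72.0
    min_exposure: int = 25
    dispersion: str = "expdecay"
    re_structure: str = "diagonal"
    nodes_per_dim: int = 7
    adaptive: bool = True
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-9
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        return cls(**known, extra=extra) if "extra" not in known else cls(**known)


def read_long_table(path, column_map: dict | None = None):
    """Read and validate a long-format count table.

    ``column_map`` renames input columns onto the canonical header, e.g.
    ``{"utts": "exposure"}``. Returns (DataFrame, report) where report lists
    row-level validation failures (row number and reason); offending rows
    are dropped. Missing columns raise, naming the column.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    for col in CANONICAL:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    df = df[list(CANONICAL)]

    report = []
    keep = np.ones(len(df), dtype=bool)
    count_num = pd.to_numeric(df["count"], errors="coerce")
    age_num = pd.to_numeric(df["age_months"], errors="coerce")
    exp_num = pd.to_numeric(df["exposure"], errors="coerce")
    checks = [
        (count_num.isna() | (count_num < 0) | (np.mod(count_num.fillna(0), 1) != 0),
         "count must be a nonnegative integer"),
        (exp_num.isna() | (exp_num < 1), "exposure must be >= 1"),
        (age_num.isna(), "age_months must be numeric"),
    ]
    for bad, reason in checks:
        for idx in df.index[bad & keep]:
            report.append({"row": int(idx), "reason": reason})
            logger.warning("row %d rejected: %s", idx, reason)
        keep &= ~bad.to_numpy()
    out = df[keep].copy()
    out["count"] = out["count"].astype(int)
    out["exposure"] = out["exposure"].astype(int)
    out["age_months"] = out["age_months"].astype(float)
    return out.reset_index(drop=True), report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def _fit_to_doc(fit: FitResult, config=None, seed=None) -> dict:
    p = fit.params
    return {
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(asdict(config)) if config is not None else None,
        "estimates": _jsonable(fit.estimates),
        "se": _jsonable(fit.se),
        "robust_se": _jsonable(fit.robust_se),
        "loglik": float(fit.loglik),
        "aic": float(fit.aic),
        "bic": float(fit.bic),
        "n_params": int(fit.n_params),
        "converged": bool(fit.converged),
        "message": fit.message,
        "niter": int(fit.niter),
        "n_individuals": int(fit.n_individuals),
        "n_obs": int(fit.n_obs),
        "W": int(fit.W),
        "fixed": _jsonable(asdict(p.fixed)),
        "T": _jsonable(p.T),
        "dispersion": {"form": p.disp.form, "coeffs": list(p.disp.coeffs),
                       "times": list(p.disp.times)},
        "random_effect_mask": list(p.random_effect_mask),
        "identification": _jsonable(asdict(fit.identification)),
        "convergence_log": _jsonable(fit.history[-50:]),
    }


def write_report(obj, out_dir, config: RunConfig | None = None, seed=None, stem=None) -> list:
    """Write a stage result to ``out_dir``; returns the list of files written.

    FitResult -> fit.json + eb.csv; SelectionReport -> binfit.csv +
    selection.json; a DataFrame (e.g. recovery table) -> <stem>.csv.
    Unconverged fits still emit their convergence log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(obj, FitResult):
        doc = _fit_to_doc(obj, config=config, seed=seed)
        path = out / ((stem or "fit") + ".json")
        path.write_text(json.dumps(doc, indent=2))
        written.append(path)
        eb_path = out / ((stem or "fit") + "_eb.csv")
        obj.eb.to_csv(eb_path, index=False)
        written.append(eb_path)
    elif isinstance(obj, SelectionReport):
        tab_path = out / ((stem or "binfit") + ".csv")
        obj.table.to_csv(tab_path, index=False)
        written.append(tab_path)
        doc = {
            "package_version": __version__,
            "seed": seed,
            "recommendation": obj.recommendation,
            "n_bins": obj.n_bins,
            "detail": _jsonable(obj.detail),
            "config": _jsonable(asdict(config)) if config is not None else None,
        }
        sel_path = out / ((stem or "binfit") + "_selection.json")
        sel_path.write_text(json.dumps(doc, indent=2))
        written.append(sel_path)
    elif isinstance(obj, pd.DataFrame):
        path = out / ((stem or "table") + ".csv")
        obj.to_csv(path, index=False)
        written.append(path)
    else:
        raise TypeError(f"don't know how to report a {type(obj).__name__}")
    return [str(p) for p in written]


def read_fit_json(path) -> dict:
    """Read back a fit document written by write_report."""
    with open(path) as fh:
        return json.load(fh)
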