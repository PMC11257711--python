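"""File readers/writers and the end-to-end run driver.

Cell tables are delimited text (comma or tab, auto-detected) with one row
per detected cell: columns ``sample_id, x, y, cell_type`` and optional
``roi_id``.  Clinical tables have one row per sample with the outcome
(``time``/``event`` or ``response``) and covariate columns.  Windows are
optional per-ROI rectangles; absent a window file, the bounding box of each
ROI's cells is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .association import ClinicalTable
from .combine import bh_fdr
from .cohort import build_patterns
from .model import SpotModel, SpotResults
from .pattern import PointPattern, Window

__all__ = ["RunConfig", "read_cell_table", "read_clinical_table",
           "read_windows", "run_spot"]

logger = logging.getLogger(__name__)

_REQUIRED_CELL_COLUMNS = ("sample_id", "x", "y")


def _read_delimited(path) -> pd.DataFrame:
    """Read a CSV/TSV with comma-vs-tab auto-detection, decimal point only.

    Floats are parsed with the round-trip converter so that writing and
    re-reading coordinates preserves them bit-for-bit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path} contains no rows")
    return df


def read_cell_table(path, windows=None) -> list[PointPattern]:
    """Read a cell table into one PointPattern per (sample_id, roi_id).

    Duplicate rows are kept: distinct cells may coincide in rounded
    coordinates.  Non-numeric coordinates raise with the offending row
    number; missing required columns are named in the error.
    """
    df = _read_delimited(path)
    missing = set(_REQUIRED_CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise ValueError(f"{path}: non-numeric {col!r} value at line {row}")
        df[col] = coerced
    if df[["x", "y"]].isna().any().any():
        raise ValueError(f"{path}: missing coordinate values")
    return build_patterns(df, windows)


def read_windows(path) -> dict:
    """Read per-ROI rectangular windows keyed by roi_id."""
    df = _read_delimited(path)
    required = {"roi_id", "x_min", "x_max", "y_min", "y_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing window columns {sorted(missing)}")
    return {
        row["roi_id"]: Window(row["x_min"], row["x_max"], row["y_min"], row["y_max"])
        for _, row in df.iterrows()
    }


def read_clinical_table(path, *, model: str = "cox", time_col="time",
                        event_col="event", response_col="response",
                        covariate_cols=None) -> ClinicalTable:
    df = _read_delimited(path)
    if model == "cox":
        return ClinicalTable.from_dataframe(
            df, time_col=time_col, event_col=event_col,
            covariate_cols=covariate_cols,
        )
    return ClinicalTable.from_dataframe(
        df, response_col=response_col, covariate_cols=covariate_cols,
    )


@dataclass
class RunConfig:
    """Everything one analysis run needs; mirrors the CLI flags."""

    cells: str
    clinical: str
    out_dir: str
    windows: str | None = None
    model: str = "cox"
    time_col: str = "time"
    event_col: str = "event"
    response_col: str = "response"
    covariate_cols: list[str] = field(default_factory=list)
    # each test is either a single mark, None (all cells), or a (a, b) pair
    tests: list = field(default_factory=lambda: [None])
    n_radii: int = 100
    radius_threshold: float = 0.2
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        tests = raw.pop("tests", [None])
        tests = [tuple(t) if isinstance(t, (list, tuple)) else t for t in tests]
        return cls(tests=tests, **raw)


def _test_label(test) -> str:
    if test is None:
        return "all cells"
    if isinstance(test, (tuple, list)):
        return f"{test[0]} x {test[1]}"
    return str(test)


def run_spot(config: RunConfig) -> list[SpotResults]:
    """Run the three-step pipeline for every requested test and write results.

    Steps: per-ROI Besag's L on the rule-of-thumb grid with the 20% support
    filter, per-radius Wald scan under the chosen outcome model, Cauchy
    combination.  With several tests (cell types or pairs), omnibus p-values
    get a Benjamini-Hochberg FDR adjustment across tests.  Writes
    ``results.csv``, a per-radius p-value table (unadjusted — for
    visualization only), and the cohort matrices for audit.  Input files are
    never modified.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cell_df = _read_delimited(config.cells)
    clinical_df = _read_delimited(config.clinical)
    windows = read_windows(config.windows) if config.windows else None

    results: list[SpotResults] = []
    curve_frames = []
    for test in config.tests:
        label = _test_label(test)
        mark = mark_pair = None
        if isinstance(test, (tuple, list)):
            mark_pair = tuple(test)
        elif test is not None:
            mark = test
        try:
            model = SpotModel.from_tables(
                cell_df, clinical_df, mark=mark, mark_pair=mark_pair,
                windows=windows, n_radii=config.n_radii,
                radius_threshold=config.radius_threshold, model=config.model,
                time_col=config.time_col, event_col=config.event_col,
                response_col=config.response_col,
                covariate_cols=config.covariate_cols, label=label,
            )
            res = model.fit()
        except Exception as exc:
            raise RuntimeError(f"test {label!r} failed: {exc}") from exc
        results.append(res)
        frame = res.scan_frame()
        frame.insert(0, "test", label)
        curve_frames.append(frame)
        model.cohort.to_frame().to_csv(
            out / f"cohort_{label.replace(' ', '_')}.csv", index=False
        )

    fdr = bh_fdr([r.pvalue for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    pd.DataFrame(
        {
            "test": [r.label for r in results],
            "cauchy_T": [r.statistic for r in results],
            "omnibus_pvalue": [r.pvalue for r in results],
            "fdr": [r.fdr for r in results],
        }
    ).to_csv(out / "results.csv", index=False)
    curves = pd.concat(curve_frames, ignore_index=True)
    # per-radius p-values are unadjusted and inflate type I error if read as
    # significance tests; keep them for visualization only
    curves.to_csv(out / "per_radius_pvalues_unadjusted.csv", index=False)
    logger.info("wrote %d test result(s) to %s", len(results), out)
    return results
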