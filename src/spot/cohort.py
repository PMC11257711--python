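"""Assemble per-sample summary curves across ROIs into a model-ready matrix.

A tumor sample may be imaged in several regions of interest (ROIs).  The
spatial summary is computed per ROI on a common radius grid, radii with
insufficient non-zero support are pruned, and ROI curves are then averaged
within sample, giving one row per sample aligned on the kept radii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RadiusGrid, filter_radii, ripley_rule_grid
from .pattern import (
    PointPattern,
    SummaryCurve,
    Window,
    estimate_L,
    estimate_L_bivariate,
)

__all__ = ["CohortCurves", "average_over_rois", "compute_cohort_curves", "build_patterns"]

logger = logging.getLogger(__name__)


@dataclass
class CohortCurves:
    """Per-sample spatial summary values aligned on one (filtered) radius grid."""

    sample_ids: np.ndarray
    radii: np.ndarray
    matrix: np.ndarray  # M x P, NaN where undefined
    statistic_name: str
    roi_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.radii = np.asarray(self.radii, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.sample_ids.size, self.radii.size):
            raise ValueError("matrix must be (n samples) x (n radii)")

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def to_frame(self) -> pd.DataFrame:
        """Wide audit table: sample_id plus one column per kept radius."""
        df = pd.DataFrame(self.matrix, columns=[f"r={r:g}" for r in self.radii])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def average_over_rois(curves) -> CohortCurves:
    """Average ROI-level curves within each sample.

    The mean at each radius is taken over the ROIs where the value is
    defined; a sample is undefined at a radius only when every one of its
    ROIs is undefined there.  Sample order follows first appearance.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    radii = curves[0].radii
    name = curves[0].statistic_name
    order: list = []
    by_sample: dict = {}
    for c in curves:
        if c.radii.shape != radii.shape or not np.allclose(c.radii, radii):
            raise ValueError("curves must share one radius grid")
        if c.sample_id not in by_sample:
            by_sample[c.sample_id] = []
            order.append(c.sample_id)
        by_sample[c.sample_id].append(c.values)
    rows = []
    counts = []
    for sid in order:
        stack = np.vstack(by_sample[sid])
        n_def = np.count_nonzero(~np.isnan(stack), axis=0)
        total = np.nansum(stack, axis=0)
        rows.append(np.where(n_def > 0, total / np.maximum(n_def, 1), np.nan))
        counts.append(stack.shape[0])
    return CohortCurves(
        sample_ids=np.array(order, dtype=object),
        radii=radii,
        matrix=np.vstack(rows),
        statistic_name=name,
        roi_counts=np.array(counts),
    )


def _roi_curve(pattern: PointPattern, radii, mark, mark_pair, edge_correction):
    if mark_pair is not None:
        return estimate_L_bivariate(pattern, radii, mark_pair[0], mark_pair[1],
                                    edge_correction=edge_correction)
    return estimate_L(pattern, radii, mark=mark, edge_correction=edge_correction)


def _check_marks(patterns, mark, mark_pair):
    wanted = set()
    if mark is not None:
        wanted.add(mark)
    if mark_pair is not None:
        wanted.update(mark_pair)
    if not wanted:
        return
    available = set()
    for p in patterns:
        if p.marks is not None:
            available.update(np.unique(p.marks).tolist())
    missing = wanted - available
    if missing:
        raise ValueError(
            f"unknown cell type(s) {sorted(missing)}; available: {sorted(available)}"
        )


def build_patterns(cell_table: pd.DataFrame, windows=None) -> list[PointPattern]:
    """One PointPattern per (sample_id, roi_id) group of a cell table.

    ``windows`` maps roi_id (or (sample_id, roi_id)) to a :class:`Window`;
    groups without an explicit window fall back to the bounding box of all
    their cells, with a logged warning.
    """
    required = {"sample_id", "x", "y"}
    missing = required - set(cell_table.columns)
    if missing:
        raise ValueError(f"cell table is missing columns: {sorted(missing)}")
    df = cell_table.copy()
    if "roi_id" not in df.columns:
        df["roi_id"] = "roi1"
    windows = windows or {}
    patterns = []
    fallback = 0
    for (sid, rid), grp in df.groupby(["sample_id", "roi_id"], sort=False):
        win = windows.get((sid, rid), windows.get(rid))
        if win is None:
            win = Window.bounding_box(grp["x"].to_numpy(), grp["y"].to_numpy())
            fallback += 1
        marks = grp["cell_type"].to_numpy() if "cell_type" in grp.columns else None
        patterns.append(
            PointPattern(grp[["x", "y"]].to_numpy(float), win, marks=marks,
                         sample_id=sid, roi_id=rid)
        )
    if fallback:
        logger.warning(
            "no explicit window for %d ROI(s); using point bounding boxes", fallback
        )
    return patterns


def compute_cohort_curves(
    cell_table: pd.DataFrame,
    windows=None,
    grid: RadiusGrid | None = None,
    mark=None,
    mark_pair=None,
    n_radii: int = 100,
    radius_threshold: float = 0.2,
    edge_correction: str = "isotropic",
) -> tuple[CohortCurves, RadiusGrid]:
    """Full pipeline from a cell table to an aligned cohort matrix.

    Computes Besag's L (univariate, one cell type, or bivariate for a pair)
    per ROI on the rule-of-thumb grid, prunes radii with under
    ``radius_threshold`` non-zero support across ROI curves, then averages
    within sample.  Returns the cohort matrix restricted to kept radii plus
    the filtered grid (with the support fractions recorded).
    """
    if (mark is not None) and (mark_pair is not None):
        raise ValueError("supply either mark or mark_pair, not both")
    patterns = build_patterns(cell_table, windows)
    if not patterns:
        raise ValueError("cell table contains no cells")
    _check_marks(patterns, mark, mark_pair)
    if grid is None:
        shortest = min(p.window.shortest_side for p in patterns)
        grid = ripley_rule_grid(shortest, n_radii=n_radii)
    curves = [_roi_curve(p, grid.radii, mark, mark_pair, edge_correction)
              for p in patterns]
    # filter on ROI-level support first, then average within sample
    fgrid = filter_radii(curves, grid, threshold=radius_threshold)
    cohort = average_over_rois(curves)
    cohort = CohortCurves(
        sample_ids=cohort.sample_ids,
        radii=cohort.radii[fgrid.kept_mask],
        matrix=cohort.matrix[:, fgrid.kept_mask],
        statistic_name=cohort.statistic_name,
        roi_counts=cohort.roi_counts,
    )
    return cohort, fgrid
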