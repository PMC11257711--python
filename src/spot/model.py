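"""Model / Results interface for the spatial omnibus association test.

:class:`SpotModel` bundles a cohort of per-sample spatial summary curves
with a clinical table; :meth:`SpotModel.fit` runs the per-radius Wald scan
and the Cauchy combination and returns a :class:`SpotResults` carrying the
per-radius estimates, the omnibus p-value, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import ClinicalTable, RadiusScanResult, per_radius_scan
from .cohort import CohortCurves, compute_cohort_curves
from .combine import cauchy_combine, naive_extreme_pvalue
from .grid import RadiusGrid

__all__ = ["SpotModel", "SpotResults"]


class SpotModel:
    """Omnibus test of association between spatial organization and outcome.

    Parameters
    ----------
    cohort : per-sample summary curves aligned on the kept radius grid
        (typically Besag's L for one cell type or a cell-type pair).
    clinical : per-sample outcome (survival or binary) and covariates.
    model : "cox" for a survival outcome, "logistic" for a binary response.
    weights : optional per-radius combination weights; uniform by default.
    label : human-readable test label, e.g. ``"CD4 T cell x Macrophage"``.

    Examples
    --------
    >>> model = SpotModel.from_tables(cells, clinical, mark_pair=("a", "b"),
    ...                               time_col="time", event_col="event")
    >>> res = model.fit()
    >>> res.pvalue  # omnibus p-value across radii
    """

    def __init__(self, cohort: CohortCurves, clinical: ClinicalTable,
                 model: str = "cox", weights=None, label: str | None = None,
                 grid: RadiusGrid | None = None):
        if model not in ("cox", "logistic"):
            raise ValueError(f"model must be 'cox' or 'logistic', got {model!r}")
        self.cohort = cohort
        self.clinical = clinical
        self.model = model
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.label = label or cohort.statistic_name
        self.grid = grid

    @classmethod
    def from_tables(
        cls,
        cell_table: pd.DataFrame,
        clinical_table: pd.DataFrame,
        *,
        mark=None,
        mark_pair=None,
        windows=None,
        n_radii: int = 100,
        radius_threshold: float = 0.2,
        model: str = "cox",
        sample_col: str = "sample_id",
        time_col: str | None = "time",
        event_col: str | None = "event",
        response_col: str | None = None,
        covariate_cols=None,
        label: str | None = None,
    ) -> "SpotModel":
        """Build the model straight from a cell table and a clinical table.

        The cell table has one row per cell (sample_id, x, y, cell_type,
        optional roi_id); the clinical table one row per sample.  Curves,
        grid construction, the 20% non-zero-support filter, and ROI
        averaging all happen here.
        """
        if model == "logistic":
            time_col = event_col = None
            response_col = response_col or "response"
        else:
            response_col = None
        cohort, grid = compute_cohort_curves(
            cell_table, windows=windows, mark=mark, mark_pair=mark_pair,
            n_radii=n_radii, radius_threshold=radius_threshold,
        )
        clinical = ClinicalTable.from_dataframe(
            clinical_table, sample_col=sample_col, time_col=time_col,
            event_col=event_col, response_col=response_col,
            covariate_cols=covariate_cols,
        )
        if label is None:
            if mark_pair is not None:
                label = f"{mark_pair[0]} x {mark_pair[1]}"
            elif mark is not None:
                label = str(mark)
            else:
                label = "all cells"
        return cls(cohort, clinical, model=model, label=label, grid=grid)

    def fit(self) -> "SpotResults":
        """Per-radius Wald scan, then the Cauchy combination across radii."""
        scan = per_radius_scan(self.cohort, self.clinical, model=self.model)
        T, pvalue = cauchy_combine(scan.pvalues, self.weights)
        defined = ~np.isnan(scan.pvalues)
        if self.weights is None:
            w = defined / defined.sum()
        else:
            w = np.where(defined, self.weights, 0.0)
            w = w / w.sum()
        return SpotResults(model=self, scan=scan, statistic=T, pvalue=pvalue,
                           weights=w)


@dataclass
class SpotResults:
    """Fitted results: per-radius scan plus the omnibus combination."""

    model: SpotModel
    scan: RadiusScanResult
    statistic: float  # Cauchy combination statistic T
    pvalue: float  # omnibus p-value
    weights: np.ndarray
    fdr: float | None = field(default=None)  # filled when part of a multi-test run

    @property
    def label(self) -> str:
        return self.model.label

    def naive(self, which: str = "best") -> tuple[float, float]:
        """Naive single-radius comparator: (radius, p) at the min/max p-value."""
        idx, p = naive_extreme_pvalue(self.scan.pvalues, which=which)
        return float(self.scan.radii[idx]), p

    def scan_frame(self) -> pd.DataFrame:
        df = self.scan.to_frame()
        df["weight"] = self.weights
        return df

    def summary(self) -> str:
        """Readable summary table in the spirit of regression result summaries."""
        s = self.scan
        defined = ~np.isnan(s.pvalues)
        lines = [
            "Spatial omnibus association test",
            "=" * 64,
            f"Test:            {self.label}",
            f"Statistic:       {self.model.cohort.statistic_name} (Besag-type curve)"
            if self.model.cohort.statistic_name.startswith("L")
            else f"Statistic:       {self.model.cohort.statistic_name}",
            f"Outcome model:   {s.model}",
            f"Samples:         {self.model.cohort.n_samples}",
            f"Radii combined:  {int(defined.sum())} of {s.radii.size} "
            f"(grid {s.radii.min():g} to {s.radii.max():g})",
            "-" * 64,
            f"Cauchy statistic T:  {self.statistic:.6g}",
            f"Omnibus p-value:     {self.pvalue:.4g}",
        ]
        if self.fdr is not None:
            lines.append(f"FDR (across tests):  {self.fdr:.4g}")
        best_r, best_p = self.naive("best")
        worst_r, worst_p = self.naive("worst")
        lines += [
            "-" * 64,
            f"min per-radius p:    {best_p:.4g}  (radius {best_r:g}; unadjusted, "
            "for visualization only)",
            f"max per-radius p:    {worst_p:.4g}  (radius {worst_r:g})",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_pvalue_curve(self, ax=None, alpha: float = 0.05):
        """Per-radius p-value curve on a log scale (unadjusted; visual aid only)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.scan
        ax.plot(s.radii, s.pvalues, marker=".", lw=1, label=self.label)
        ax.axhline(alpha, color="grey", ls="--", lw=0.8)
        ax.set_yscale("log")
        ax.set_xlabel("radius t")
        ax.set_ylabel("per-radius p-value (unadjusted)")
        ax.legend(frameon=False)
        return ax

    def __repr__(self) -> str:
        return (f"<SpotResults {self.label!r}: T={self.statistic:.4g}, "
                f"p={self.pvalue:.4g}>")
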