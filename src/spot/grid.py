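"""Candidate radius grids and the non-zero-support filter.

The radius range follows Ripley's rule of thumb: candidate radii run from 0
to one quarter of the shortest side of the image.  Small radii often produce
all-zero summaries (no cell pairs that close), so radii where fewer than 20%
of images have a non-zero summary value are pruned before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pattern import SummaryCurve

__all__ = ["RadiusGrid", "ripley_rule_grid", "filter_radii", "RULE_FRACTION"]

#: upper bound of the candidate range as a fraction of the shortest image side
RULE_FRACTION = 0.25


@dataclass
class RadiusGrid:
    """Equally spaced candidate radii with a kept/dropped mask after filtering."""

    radii: np.ndarray
    upper_bound: float
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    nonzero_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.ndim != 1 or self.radii.size < 1:
            raise ValueError("radii must be a non-empty vector")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.radii[0] < 0:
            raise ValueError("radii must be non-negative")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.radii.shape, dtype=bool)
        if self.nonzero_fraction is None:
            self.nonzero_fraction = np.full(self.radii.shape, np.nan)

    @property
    def kept_radii(self) -> np.ndarray:
        return self.radii[self.kept_mask]

    def __len__(self) -> int:
        return self.radii.size


def ripley_rule_grid(shortest_side: float, n_radii: int = 100) -> RadiusGrid:
    """Equally spaced radii from 0 to ``RULE_FRACTION * shortest_side``.

    Parameters
    ----------
    shortest_side : length of the shortest side of the image (for a cohort of
        heterogeneous image sizes, pass the minimum shortest side across
        images).
    n_radii : number of grid points, endpoints included.
    """
    if shortest_side <= 0:
        raise ValueError("shortest_side must be positive")
    if n_radii < 2:
        raise ValueError("n_radii must be at least 2")
    upper = RULE_FRACTION * shortest_side
    return RadiusGrid(np.linspace(0.0, upper, int(n_radii)), upper_bound=upper)


def filter_radii(
    curves: Sequence[SummaryCurve] | Iterable[SummaryCurve],
    grid: RadiusGrid,
    threshold: float = 0.2,
) -> RadiusGrid:
    """Keep radii where at least ``threshold`` of images have a non-zero value.

    The fraction is computed over image-level (ROI-level) curves, before any
    within-sample averaging.  Undefined (NaN) values count as zero support:
    they cannot contribute a non-zero summary.  The comparison is inclusive
    (a fraction exactly equal to the threshold is kept).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("cannot filter radii with an empty curve collection")
    for c in curves:
        if c.radii.shape != grid.radii.shape or not np.allclose(c.radii, grid.radii):
            raise ValueError("all curves must share the grid's radii")
    values = np.vstack([c.values for c in curves])
    nonzero = np.nan_to_num(values, nan=0.0) != 0.0
    frac = nonzero.mean(axis=0)
    return RadiusGrid(
        grid.radii,
        upper_bound=grid.upper_bound,
        kept_mask=frac >= threshold,
        nonzero_fraction=frac,
    )
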