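"""Synthetic image cohorts and Monte-Carlo operating characteristics.

The generator emulates a multiplexed-imaging cohort: each sample contributes
one or more 1000 x 1000 images holding 50-100 cells, laid out either under
complete spatial randomness (CSR) or as a clustered pattern (one Gaussian
cluster per image by default; Matern-cluster and Strauss alternatives are
available).  Survival follows a two-group exponential model — the
low-survival half of the cohort has median 12 (hazard log(2)/12), the
high-survival half median 30 (hazard 0.4*log(2)/12) — with 10-20% of event
times randomly censored per group.  A binary-response outcome is available
as an alternative.

Under the *null* design the image pattern is assigned independently of the
outcome group; under the *alternative* (power) design the low-survival
group's images are clustered and the high-survival group's are CSR, so the
spatial summary carries outcome signal.  ``run_operating_characteristics``
replays the full pipeline over many replications and reports rejection
fractions for the omnibus test, the naive best/worst-radius procedures, and
every fixed single radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import ClinicalTable, per_radius_scan
from .cohort import average_over_rois, CohortCurves
from .combine import cauchy_combine, naive_extreme_pvalue
from .grid import filter_radii, ripley_rule_grid
from .pattern import PointPattern, Window, estimate_L, estimate_L_bivariate

__all__ = [
    "SimConfig",
    "simulate_csr_image",
    "simulate_gaussian_cluster_image",
    "simulate_matern_cluster_image",
    "simulate_strauss_image",
    "assign_marks",
    "simulate_survival_outcome",
    "simulate_binary_outcome",
    "simulate_cohort",
    "run_operating_characteristics",
    "OperatingCharacteristics",
]

logger = logging.getLogger(__name__)

LOG2 = float(np.log(2.0))


@dataclass
class SimConfig:
    """Generative constants for the simulated cohorts.

    Defaults are the stated study conditions: M=100 samples, 1000x1000
    windows, 50-100 cells per image, Gaussian-clustered alternative with
    cluster centers uniform on [100, 900]^2 and covariance
    [[100^2, 50*100], [50*100, 100^2]], exponential survival with hazards
    log(2)/12 (low-survival group) and 0.4*log(2)/12 (high-survival group),
    and 10-20% censoring per group.
    """

    m_samples: int = 100
    window: Window = field(default_factory=lambda: Window(0.0, 1000.0, 0.0, 1000.0))
    n_cells_range: tuple[int, int] = (50, 100)
    pattern: str = "gaussian_cluster"  # clustered-image generator
    n_cell_types: int = 1
    rois_per_sample: int = 1
    clustered_image_probability: float = 0.75  # multi-ROI low-survival group
    outcome: str = "survival"
    hazard_low: float = LOG2 / 12.0
    hazard_high: float = 0.4 * LOG2 / 12.0
    censor_range: tuple[float, float] = (0.10, 0.20)
    cluster_mu_range: tuple[float, float] = (100.0, 900.0)
    gaussian_centers: str = "per_cell"  # "per_cell" or "shared"; see the generator
    cluster_sigma: tuple[tuple[float, float], tuple[float, float]] = (
        (100.0 ** 2, 50.0 * 100.0),
        (50.0 * 100.0, 100.0 ** 2),
    )
    # Matern-cluster parameters (supplement values unavailable; chosen to
    # match the Gaussian cluster's spatial scale — see the methods note)
    matern_mean_parents: float = 5.0
    matern_cluster_radius: float = 100.0
    # Strauss (inhibition) parameters; configurable extra, no default target
    strauss_gamma: float = 0.5
    strauss_radius: float = 50.0
    strauss_sweeps: int = 30
    # binary-outcome response probabilities (alternative design)
    binary_p_clustered: float = 0.8
    binary_p_csr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_low <= 0 or self.hazard_high <= 0:
            raise ValueError("hazards must be positive")
        lo, hi = self.censor_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("censor_range must be within [0, 1]")
        if not 0 <= self.clustered_image_probability <= 1:
            raise ValueError("clustered_image_probability must be in [0, 1]")
        if self.n_cell_types not in (1, 2):
            raise ValueError("n_cell_types must be 1 or 2")
        if self.outcome not in ("survival", "binary"):
            raise ValueError("outcome must be 'survival' or 'binary'")
        if self.gaussian_centers not in ("per_cell", "shared"):
            raise ValueError("gaussian_centers must be 'per_cell' or 'shared'")


def _draw_n_cells(config: SimConfig, rng) -> int:
    lo, hi = config.n_cells_range
    return int(rng.integers(lo, hi + 1))


def simulate_csr_image(config: SimConfig, rng, n: int | None = None) -> PointPattern:
    """Uniformly random cell positions: complete spatial randomness."""
    if n is None:
        n = _draw_n_cells(config, rng)
    w = config.window
    x = rng.uniform(w.x_min, w.x_max, n)
    y = rng.uniform(w.y_min, w.y_max, n)
    return PointPattern(np.column_stack([x, y]), w)


def simulate_gaussian_cluster_image(config: SimConfig, rng,
                                    n: int | None = None) -> PointPattern:
    """The Gaussian "clustered" image condition.

    Mean locations are drawn uniform on ``cluster_mu_range`` squared and
    cells are bivariate normal with covariance ``cluster_sigma`` around
    them.  ``config.gaussian_centers`` selects the geometry:

    - ``"per_cell"`` (default): every cell gets its own mean location.  The
      pattern is then a uniform pattern blurred by Gaussian displacement and
      softly confined to the inner region — close to CSR locally but
      aggregated at the image scale, so Besag's L exceeds t moderately and
      noisily.  This is the weak-signal regime the Monte-Carlo operating
      characteristics of the omnibus and naive-radius procedures were
      established in (the strong-signal alternative below saturates every
      per-radius test and makes the naive comparisons degenerate).
    - ``"shared"``: all cells share one mean — a single tight cluster per
      image, an unambiguous strong-clustering pattern.

    Points landing outside the window are resampled (truncation), keeping
    the cell count in range.
    """
    if n is None:
        n = _draw_n_cells(config, rng)
    w = config.window
    lo, hi = config.cluster_mu_range
    sigma = np.asarray(config.cluster_sigma, dtype=float)
    per_cell = config.gaussian_centers == "per_cell"
    mu_shared = rng.uniform(lo, hi, 2)
    pts = np.empty((0, 2))
    while pts.shape[0] < n:
        m = n - pts.shape[0]
        mu = rng.uniform(lo, hi, (m, 2)) if per_cell else mu_shared
        draw = mu + rng.multivariate_normal(np.zeros(2), sigma, size=m,
                                            method="cholesky")
        keep = w.contains(draw[:, 0], draw[:, 1])
        pts = np.vstack([pts, draw[keep]])
    return PointPattern(pts, w)


def simulate_matern_cluster_image(config: SimConfig, rng,
                                  n: int | None = None) -> PointPattern:
    """Matern cluster process conditioned to a 50-100 cell total.

    Poisson-many parent points (mean ``matern_mean_parents``, regenerated
    until at least one) uniform in the window; offspring uniform in a disc
    of ``matern_cluster_radius`` around a parent, resampled until inside the
    window.  The total is fixed at the drawn target by assigning each
    offspring to a uniformly chosen parent (the conditional form of thinning
    or repeating until the count lands in range).
    """
    if config.matern_mean_parents <= 0 or config.matern_cluster_radius <= 0:
        raise ValueError("Matern parameters must be positive")
    if n is None:
        n = _draw_n_cells(config, rng)
    w = config.window
    n_parents = 0
    regenerations = 0
    while n_parents == 0:
        n_parents = int(rng.poisson(config.matern_mean_parents))
        if n_parents == 0:
            regenerations += 1
    if regenerations:
        logger.debug("regenerated parent count %d time(s)", regenerations)
    px = rng.uniform(w.x_min, w.x_max, n_parents)
    py = rng.uniform(w.y_min, w.y_max, n_parents)
    parent_idx = rng.integers(0, n_parents, n)
    pts = np.empty((n, 2))
    todo = np.arange(n)
    r_max = config.matern_cluster_radius
    while todo.size:
        m = todo.size
        r = r_max * np.sqrt(rng.uniform(size=m))
        theta = rng.uniform(0, 2 * np.pi, m)
        cand = np.column_stack([
            px[parent_idx[todo]] + r * np.cos(theta),
            py[parent_idx[todo]] + r * np.sin(theta),
        ])
        ok = w.contains(cand[:, 0], cand[:, 1])
        pts[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return PointPattern(pts, w)


def simulate_strauss_image(config: SimConfig, rng,
                           n: int | None = None) -> PointPattern:
    """Fixed-n Strauss (pairwise-inhibition) pattern via Metropolis moves.

    Density proportional to gamma^{s(x)} with s the number of point pairs
    closer than ``strauss_radius``; ``strauss_gamma`` < 1 gives inhibition.
    Single-point relocation Metropolis, ``strauss_sweeps`` sweeps from a CSR
    start.  Parameters are configurable extras: no published values back
    the defaults.
    """
    gamma, r = config.strauss_gamma, config.strauss_radius
    if not (0 < gamma <= 1) or r <= 0:
        raise ValueError("require 0 < gamma <= 1 and a positive radius")
    if n is None:
        n = _draw_n_cells(config, rng)
    w = config.window
    pts = np.column_stack([
        rng.uniform(w.x_min, w.x_max, n), rng.uniform(w.y_min, w.y_max, n)
    ])
    log_gamma = np.log(gamma)
    for _ in range(config.strauss_sweeps):
        for i in rng.permutation(n):
            prop = np.array([rng.uniform(w.x_min, w.x_max),
                             rng.uniform(w.y_min, w.y_max)])
            others = np.delete(pts, i, axis=0)
            s_old = np.count_nonzero(np.hypot(*(others - pts[i]).T) < r)
            s_new = np.count_nonzero(np.hypot(*(others - prop).T) < r)
            if np.log(rng.uniform()) < log_gamma * (s_new - s_old):
                pts[i] = prop
    return PointPattern(pts, w)


_PATTERN_GENERATORS = {
    "csr": simulate_csr_image,
    "gaussian_cluster": simulate_gaussian_cluster_image,
    "matern_cluster": simulate_matern_cluster_image,
    "strauss": simulate_strauss_image,
}

#: cell-type labels used when marks are simulated
MARK_LABELS = ("a", "b")


def assign_marks(pattern: PointPattern, n_cell_types: int, rng) -> PointPattern:
    """Random equal-probability cell-type labels, independent of position."""
    if n_cell_types == 1:
        return pattern
    if n_cell_types != 2:
        raise ValueError("n_cell_types must be 1 or 2")
    marks = rng.choice(np.array(MARK_LABELS, dtype=object), size=pattern.n)
    return PointPattern(pattern.coordinates, pattern.window, marks=marks,
                        sample_id=pattern.sample_id, roi_id=pattern.roi_id)


def simulate_survival_outcome(m_samples: int, config: SimConfig, rng) -> ClinicalTable:
    """Two-group exponential survival with per-group random censoring.

    The first half of the cohort is the low-survival group (hazard
    ``hazard_low``, median 12 by default); the second half the high-survival
    group (``hazard_high``, median 30).  Per group, a censored fraction is
    drawn uniform on ``censor_range``; that share of samples, chosen at
    random, keeps its drawn time but is flagged event = 0.
    """
    half = m_samples // 2
    rates = np.where(np.arange(m_samples) < half, config.hazard_low,
                     config.hazard_high)
    times = rng.exponential(1.0 / rates)
    event = np.ones(m_samples)
    for group in (np.arange(half), np.arange(half, m_samples)):
        frac = rng.uniform(*config.censor_range)
        n_cens = int(round(frac * group.size))
        censored = rng.choice(group, size=n_cens, replace=False)
        event[censored] = 0.0
    return ClinicalTable(
        sample_ids=np.array([f"s{i + 1}" for i in range(m_samples)], dtype=object),
        time=times, event=event,
    )


def simulate_binary_outcome(m_samples: int, config: SimConfig, rng,
                            clustered_group: np.ndarray | None = None) -> ClinicalTable:
    """Binary response linked to the clustered-image group.

    ``clustered_group`` flags samples whose images are clustered; they
    respond with probability ``binary_p_clustered`` and the rest with
    ``binary_p_csr``.  Passing None (the null design) uses ``binary_p_csr``
    for everyone, so response is independent of the images.
    """
    if clustered_group is None:
        probs = np.full(m_samples, config.binary_p_csr)
    else:
        clustered_group = np.asarray(clustered_group, dtype=bool)
        probs = np.where(clustered_group, config.binary_p_clustered,
                         config.binary_p_csr)
    response = (rng.uniform(size=m_samples) < probs).astype(float)
    return ClinicalTable(
        sample_ids=np.array([f"s{i + 1}" for i in range(m_samples)], dtype=object),
        response=response,
    )


def _clustered_flags(config: SimConfig, design: str, rng) -> np.ndarray:
    """Per-image clustered indicator, shape (m_samples, rois_per_sample)."""
    m, R = config.m_samples, config.rois_per_sample
    half = m // 2
    low = np.arange(m) < half  # low-survival / responder-linked group
    if design == "null":
        return rng.uniform(size=(m, R)) < 0.5
    if design != "power":
        raise ValueError(f"design must be 'null' or 'power', got {design!r}")
    if R == 1:
        return np.tile(low[:, None], (1, 1))
    flags = np.zeros((m, R), dtype=bool)
    flags[low] = rng.uniform(size=(half, R)) < config.clustered_image_probability
    return flags


def simulate_cohort(config: SimConfig, design: str, rng):
    """One replication: marked point patterns plus the linked clinical table.

    Returns ``(patterns, clinical, flags)`` where ``patterns`` holds one
    pattern per (sample, ROI) and ``flags`` the per-image clustered
    indicators.
    """
    flags = _clustered_flags(config, design, rng)
    gen_clustered = _PATTERN_GENERATORS[config.pattern]
    patterns = []
    for i in range(config.m_samples):
        for r in range(config.rois_per_sample):
            gen = gen_clustered if flags[i, r] else simulate_csr_image
            pat = gen(config, rng)
            pat.sample_id = f"s{i + 1}"
            pat.roi_id = f"roi{r + 1}"
            pat = assign_marks(pat, config.n_cell_types, rng)
            patterns.append(pat)
    if config.outcome == "survival":
        clinical = simulate_survival_outcome(config.m_samples, config, rng)
    else:
        group = None if design == "null" else flags.any(axis=1)
        clinical = simulate_binary_outcome(config.m_samples, config, rng, group)
    return patterns, clinical, flags


@dataclass
class OperatingCharacteristics:
    """Rejection fractions (with Monte-Carlo standard errors) over replications."""

    design: str
    alpha: float
    n_reps: int
    rejection: dict
    mc_se: dict
    per_radius: pd.DataFrame | None
    omnibus_pvalues: np.ndarray
    n_failures: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"method": m, "rejection": self.rejection[m], "mc_se": self.mc_se[m]}
            for m in self.rejection
        ]
        return pd.DataFrame(rows)


def _rep_pvalues(config: SimConfig, design: str, grid, threshold: float, rng):
    """Per-radius Cox/logistic p-values for one replication, on the full grid."""
    patterns, clinical, _ = simulate_cohort(config, design, rng)
    if config.n_cell_types == 2:
        curves = [estimate_L_bivariate(p, grid.radii, *MARK_LABELS) for p in patterns]
    else:
        curves = [estimate_L(p, grid.radii) for p in patterns]
    fgrid = filter_radii(curves, grid, threshold=threshold)
    if not fgrid.kept_mask.any():
        raise RuntimeError("radius filter removed every radius")
    cohort = average_over_rois(curves)
    cohort = CohortCurves(
        sample_ids=cohort.sample_ids,
        radii=cohort.radii[fgrid.kept_mask],
        matrix=cohort.matrix[:, fgrid.kept_mask],
        statistic_name=cohort.statistic_name,
        roi_counts=cohort.roi_counts,
    )
    model = "cox" if config.outcome == "survival" else "logistic"
    scan = per_radius_scan(cohort, clinical, model=model)
    full = np.full(grid.radii.size, np.nan)
    full[fgrid.kept_mask] = scan.pvalues
    return full


def run_operating_characteristics(
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    methods=("spot", "naive_best", "naive_worst", "fixed_radius"),
    design: str = "power",
    n_radii: int = 26,
    radius_threshold: float = 0.2,
) -> OperatingCharacteristics:
    """Monte-Carlo rejection fractions for the omnibus test and comparators.

    Per replication, a cohort is generated under ``design`` ("null": image
    pattern independent of outcome; "power": pattern linked to outcome), the
    full pipeline runs on the rule-of-thumb grid (0 to a quarter of the
    shortest window side, ``n_radii`` points, 20% support filter), and each
    method's p-value is compared with ``alpha``:

    - ``spot``: equally weighted Cauchy combination across kept radii;
    - ``naive_best`` / ``naive_worst``: min / max per-radius p-value;
    - ``fixed_radius``: every single radius separately (reported as a
      per-radius rejection-fraction table, the power-versus-radius curve).

    Replication streams are spawned from ``config.seed`` by replication
    index, so earlier replications are unchanged when ``n_reps`` grows.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    grid = ripley_rule_grid(config.window.shortest_side, n_radii=n_radii)
    P = grid.radii.size
    pmat = np.full((n_reps, P), np.nan)
    spot_p = np.full(n_reps, np.nan)
    best_p = np.full(n_reps, np.nan)
    worst_p = np.full(n_reps, np.nan)
    failures = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(rep,))
        )
        try:
            pvals = _rep_pvalues(config, design, grid, radius_threshold, rng)
        except Exception as exc:
            failures += 1
            logger.warning("replication %d failed: %s", rep, exc)
            continue
        pmat[rep] = pvals
        _, spot_p[rep] = cauchy_combine(pvals)
        best_p[rep] = naive_extreme_pvalue(pvals, "best")[1]
        worst_p[rep] = naive_extreme_pvalue(pvals, "worst")[1]

    ok = ~np.isnan(spot_p)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise RuntimeError("every replication failed")

    def frac(p):
        return float(np.mean(p[ok] < alpha))

    rejection, mc_se = {}, {}
    by_method = {"spot": spot_p, "naive_best": best_p, "naive_worst": worst_p}
    for m in methods:
        if m == "fixed_radius":
            continue
        if m not in by_method:
            raise ValueError(f"unknown method {m!r}")
        r = frac(by_method[m])
        rejection[m] = r
        mc_se[m] = float(np.sqrt(r * (1 - r) / n_ok))

    per_radius = None
    if "fixed_radius" in methods:
        defined = ~np.isnan(pmat[ok])
        n_def = defined.sum(axis=0)
        with np.errstate(invalid="ignore"):
            rej = np.where(
                n_def > 0,
                np.nansum(pmat[ok] < alpha, axis=0) / np.maximum(n_def, 1),
                np.nan,
            )
        per_radius = pd.DataFrame(
            {"radius": grid.radii, "rejection": rej, "n_defined": n_def}
        )
    return OperatingCharacteristics(
        design=design, alpha=alpha, n_reps=n_ok, rejection=rejection,
        mc_se=mc_se, per_radius=per_radius, omnibus_pvalues=spot_p[ok],
        n_failures=failures,
    )


def patterns_to_cell_table(patterns) -> pd.DataFrame:
    """Flatten simulated patterns into the on-disk cell-table format."""
    frames = []
    for p in patterns:
        df = pd.DataFrame({
            "sample_id": p.sample_id,
            "roi_id": p.roi_id,
            "x": p.coordinates[:, 0],
            "y": p.coordinates[:, 1],
        })
        if p.marks is not None:
            df["cell_type"] = p.marks
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def clinical_to_table(clinical: ClinicalTable) -> pd.DataFrame:
    """Flatten a clinical table into the on-disk format."""
    df = pd.DataFrame({"sample_id": clinical.sample_ids})
    if clinical.is_survival:
        df["time"] = clinical.time
        df["event"] = clinical.event
    else:
        df["response"] = clinical.response
    for j, name in enumerate(clinical.covariate_names):
        df[name] = clinical.covariates[:, j]
    return df
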