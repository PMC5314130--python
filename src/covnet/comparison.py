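"""Permutation-based group comparison of network metric curves.

The comparison framework is nonparametric: group labels are shuffled
(preserving group sizes), BOTH association matrices are recomputed, graphs
are re-thresholded across the fixed density grid, and every requested
metric is recomputed, yielding a permutation distribution of between-group
differences per density and as a functional-density (area-under-curve)
statistic.  Two-tailed p-values are positional with the add-one (never
zero) convention; Benjamini-Hochberg FDR corrects within each family of
tests (the global measures; all nodes per nodal metric).

The density grid is fixed at the observed-data minimum connected density
for all permutations; fragmented permutation graphs fall back to
reachable-pair path length (flagged via the unreachable-pair diagnostics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .construction import adjacency_stack, edge_count, pair_order
from .data import SubjectVolumeTable
from .exceptions import DegenerateDataError, InputValidationError
from .grid import DensityGrid
from .metrics import (betweenness_from_adjacency, clustering_mean_curve,
                      path_length_from_adjacency)
from .nulls import hqs_draw_from_r

logger = logging.getLogger(__name__)

GLOBAL_RAW_METRICS = ("clustering", "path_length")
GLOBAL_NORM_METRICS = ("norm_clustering", "norm_path_length", "small_worldness")
GLOBAL_METRICS = GLOBAL_RAW_METRICS + GLOBAL_NORM_METRICS
NODAL_METRICS = ("degree", "betweenness")


@dataclass
class MetricCurve:
    """A metric evaluated across the density grid for one group."""

    grid: DensityGrid
    values: np.ndarray
    metric_name: str
    group_label: str
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.grid):
            raise InputValidationError(
                f"curve has {self.values.shape[0]} values for "
                f"{len(self.grid)} grid points")
        if not np.all(np.isfinite(self.values)):
            raise InputValidationError(f"non-finite values in {self.metric_name} curve")

    def auc(self) -> float:
        return fda_auc(self.values, self.grid)


@dataclass
class ComparisonResult:
    """Observed group difference with its permutation-based significance."""

    metric_name: str
    node: str | None
    observed_diff: np.ndarray          # per density, group A minus group B
    observed_auc_diff: float
    p_per_density: np.ndarray
    p_auc: float
    n_permutations: int
    q_auc: float | None = None

    @property
    def direction(self) -> str:
        return "A>B" if self.observed_auc_diff > 0 else (
            "A<B" if self.observed_auc_diff < 0 else "A=B")


@dataclass
class PermutationDistributions:
    """Full permutation difference distributions (group A minus group B)."""

    grid: DensityGrid
    n_perm: int
    global_diffs: dict = field(default_factory=dict)      # name -> (n_perm, D)
    global_auc_diffs: dict = field(default_factory=dict)  # name -> (n_perm,)
    nodal_diffs: dict = field(default_factory=dict)       # name -> (n_perm, D, N)
    nodal_auc_diffs: dict = field(default_factory=dict)   # name -> (n_perm, N)
    n_redraws: int = 0


# ----------------------------------------------------------------------
# elementary statistics

def two_tailed_p(observed, perm_diffs) -> float | np.ndarray:
    """Positional two-tailed p: (#{|perm| >= |obs|} + 1) / (n_perm + 1)."""
    perms = np.abs(np.asarray(perm_diffs, dtype=float))
    if perms.shape[0] < 1:
        raise InputValidationError("empty permutation distribution")
    obs = np.abs(np.asarray(observed, dtype=float))
    count = (perms >= obs).sum(axis=0)
    p = (count + 1) / (perms.shape[0] + 1)
    return float(p) if np.isscalar(observed) or np.ndim(observed) == 0 else p


def fda_auc(values, grid) -> float | np.ndarray:
    """Trapezoidal area under a metric-vs-density curve.

    ``values`` may be (D,) or (..., D, N) (AUC taken along the density
    axis); ``grid`` a DensityGrid or array of densities.
    """
    x = grid.as_array() if isinstance(grid, DensityGrid) else np.asarray(grid, float)
    if x.size < 2:
        raise InputValidationError("functional density analysis needs >= 2 grid points")
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        return float(np.trapezoid(v, x))
    # density axis is -2 for stacked nodal curves (D, N)
    axis = -2 if v.shape[-2] == x.size else -1
    return np.trapezoid(v, x, axis=axis)


def _auc_stat(arr, grid_values, axis: int = 0):
    """Functional-density statistic along the density axis.

    Trapezoidal AUC for grids of >= 2 points; on a single-point grid the
    statistic degenerates to the value at that density, so the functional
    comparison coincides with the density-wise one.
    """
    arr = np.asarray(arr, dtype=float)
    if grid_values.size == 1:
        return np.take(arr, 0, axis=axis)
    return np.trapezoid(arr, grid_values, axis=axis)


def fdr_correct(pvals, family: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone) for one test family.

    ``family`` is a descriptive label for the correction family (e.g.
    "global" or "nodal degree"); it does not change the computation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise InputValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def normalize_nodal_by_group_mean(values):
    """Divide each node's value by the network-wide mean of that metric.

    ``values`` is (..., N) with nodes on the last axis (the mean is taken
    per leading index, e.g. per density), or a NodalMetrics whose degree
    and betweenness are each normalized.
    """
    from .metrics import NodalMetrics
    if isinstance(values, NodalMetrics):
        return NodalMetrics(
            degree=normalize_nodal_by_group_mean(values.degree),
            betweenness=normalize_nodal_by_group_mean(values.betweenness),
            region_names=list(values.region_names))
    v = np.asarray(values, dtype=float)
    mean = v.mean(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        raise DegenerateDataError("cannot normalize: network mean is not positive")
    return v / mean


# ----------------------------------------------------------------------
# per-group curve computation (used for observed data and every permutation)

def _corr_from_values(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return r


def compute_group_curves(r: np.ndarray, e_counts: np.ndarray,
                         grid_values: np.ndarray,
                         global_metrics=GLOBAL_RAW_METRICS,
                         nodal_metrics=(),
                         n_null: int = 5,
                         hqs_seed=None,
                         normalize_nodal: bool = True) -> dict:
    """All requested metric curves for one group's association matrix.

    Returns a dict mapping metric name to a (D,) array (global) or (D, N)
    array (nodal).  Normalized global metrics (norm_clustering,
    norm_path_length, small_worldness) use a fresh HQS null ensemble of
    ``n_null`` matrices seeded from ``hqs_seed``.
    """
    unknown = [m for m in list(global_metrics) + list(nodal_metrics)
               if m not in GLOBAL_METRICS + NODAL_METRICS]
    if unknown:
        raise InputValidationError(
            f"unknown metrics {unknown}; available: {GLOBAL_METRICS + NODAL_METRICS}")
    need_norm = any(m in GLOBAL_NORM_METRICS for m in global_metrics)
    need_c = need_norm or "clustering" in global_metrics
    need_l = need_norm or "path_length" in global_metrics
    out = {}
    stack = adjacency_stack(r, e_counts)
    c = clustering_mean_curve(stack) if need_c else None
    if need_l:
        l = np.array([path_length_from_adjacency(a)[0] for a in stack])
    if "clustering" in global_metrics:
        out["clustering"] = c
    if "path_length" in global_metrics:
        out["path_length"] = l
    if need_norm:
        rng = np.random.default_rng(hqs_seed)
        null_c = np.zeros_like(c)
        null_l = np.zeros_like(l)
        for _ in range(n_null):
            null_mat = hqs_draw_from_r(r, rng)
            np.fill_diagonal(null_mat, 0.0)
            null_stack = adjacency_stack(null_mat, e_counts)
            null_c += clustering_mean_curve(null_stack)
            null_l += np.array([path_length_from_adjacency(a)[0] for a in null_stack])
        null_c /= n_null
        null_l /= n_null
        if np.any(null_c <= 0) or np.any(null_l <= 0):
            raise DegenerateDataError("degenerate HQS null ensemble")
        gamma, lam = c / null_c, l / null_l
        if "norm_clustering" in global_metrics:
            out["norm_clustering"] = gamma
        if "norm_path_length" in global_metrics:
            out["norm_path_length"] = lam
        if "small_worldness" in global_metrics:
            out["small_worldness"] = gamma / lam
    if "degree" in nodal_metrics:
        deg = stack.sum(axis=2).astype(float)
        out["degree"] = normalize_nodal_by_group_mean(deg) if normalize_nodal else deg
    if "betweenness" in nodal_metrics:
        btw = np.stack([betweenness_from_adjacency(a) for a in stack])
        if normalize_nodal:
            mean = btw.mean(axis=-1, keepdims=True)
            # a density where no shortest path has interior nodes carries no signal
            btw = np.where(mean > 0, btw / np.where(mean > 0, mean, 1.0), 0.0)
        out["betweenness"] = btw
    return out


# ----------------------------------------------------------------------
# the permutation framework

def permutation_null(table: SubjectVolumeTable, grid: DensityGrid,
                     n_perm: int = 1000, seed=None,
                     global_metrics=GLOBAL_RAW_METRICS,
                     nodal_metrics=(),
                     n_null_perm: int = 5,
                     max_redraw_frac: float = 0.05) -> PermutationDistributions:
    """Permutation distributions of between-group metric differences.

    For every permutation the subject labels are shuffled with group sizes
    preserved, both association matrices recomputed, graphs re-thresholded
    across the fixed grid, and all requested metrics recomputed (including
    fresh HQS null normalization with ``n_null_perm`` matrices when
    normalized measures are requested).  Differences are recorded per
    density and as AUC.  Permutations producing a constant region within a
    group are redrawn (logged); more than ``max_redraw_frac`` redraws is an
    error.
    """
    if n_perm < 1:
        raise InputValidationError("n_perm must be >= 1")
    labels = table.group_labels
    group_a, group_b = table.groups
    idx_a = np.flatnonzero(labels == group_a)
    idx_b = np.flatnonzero(labels == group_b)
    n_a = idx_a.size
    values = table.values
    n_regions = values.shape[1]
    grid_values = grid.as_array()
    e_counts = np.array([edge_count(n_regions, d) for d in grid.values])

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    perm_ss, hqs_ss = ss.spawn(2)
    rng = np.random.default_rng(perm_ss)
    need_hqs = any(m in GLOBAL_NORM_METRICS for m in global_metrics)
    hqs_children = iter(hqs_ss.spawn(2 * n_perm)) if need_hqs else None

    dist = PermutationDistributions(grid=grid, n_perm=n_perm)
    n_density = len(grid)
    for m in global_metrics:
        dist.global_diffs[m] = np.empty((n_perm, n_density))
        dist.global_auc_diffs[m] = np.empty(n_perm)
    for m in nodal_metrics:
        dist.nodal_diffs[m] = np.empty((n_perm, n_density, n_regions))
        dist.nodal_auc_diffs[m] = np.empty((n_perm, n_regions))

    max_redraws = max(1, int(np.ceil(max_redraw_frac * n_perm)))
    redraws = 0
    n_total = values.shape[0]
    for k in range(n_perm):
        while True:
            perm = rng.permutation(n_total)
            xa, xb = values[perm[:n_a]], values[perm[n_a:]]
            if xa.std(axis=0).min() > 0 and xb.std(axis=0).min() > 0:
                break
            redraws += 1
            logger.warning("permutation %d produced a constant region; redrawn", k)
            if redraws > max_redraws:
                raise DegenerateDataError(
                    f"more than {max_redraw_frac:.0%} of permutations produced "
                    "constant regions")
        seed_a = next(hqs_children) if need_hqs else None
        seed_b = next(hqs_children) if need_hqs else None
        curves_a = compute_group_curves(_corr_from_values(xa), e_counts, grid_values,
                                        global_metrics, nodal_metrics,
                                        n_null=n_null_perm, hqs_seed=seed_a)
        curves_b = compute_group_curves(_corr_from_values(xb), e_counts, grid_values,
                                        global_metrics, nodal_metrics,
                                        n_null=n_null_perm, hqs_seed=seed_b)
        for m in global_metrics:
            diff = curves_a[m] - curves_b[m]
            dist.global_diffs[m][k] = diff
            dist.global_auc_diffs[m][k] = _auc_stat(diff, grid_values)
        for m in nodal_metrics:
            diff = curves_a[m] - curves_b[m]
            dist.nodal_diffs[m][k] = diff
            dist.nodal_auc_diffs[m][k] = _auc_stat(diff, grid_values, axis=0)
        if k and k % 200 == 0:
            logger.info("permutation %d / %d", k, n_perm)
    dist.n_redraws = redraws
    return dist


def assemble_comparisons(observed_a: dict, observed_b: dict,
                         dist: PermutationDistributions,
                         region_names=None) -> list:
    """Turn observed curves plus permutation distributions into results.

    FDR families: all requested global measures form one family (applied
    to the AUC p-values); each nodal metric's nodes form one family.
    Per-density p-values are diagnostics.
    """
    grid_values = dist.grid.as_array()
    results = []
    global_group = []
    for m, diffs in dist.global_diffs.items():
        obs = observed_a[m] - observed_b[m]
        res = ComparisonResult(
            metric_name=m, node=None, observed_diff=obs,
            observed_auc_diff=float(_auc_stat(obs, grid_values)),
            p_per_density=two_tailed_p(obs, diffs),
            p_auc=float(two_tailed_p(
                _auc_stat(obs, grid_values), dist.global_auc_diffs[m])),
            n_permutations=dist.n_perm)
        results.append(res)
        global_group.append(res)
    if global_group:
        qs = fdr_correct([r.p_auc for r in global_group])
        for r, q in zip(global_group, qs):
            r.q_auc = float(q)
    for m, diffs in dist.nodal_diffs.items():
        obs = observed_a[m] - observed_b[m]           # (D, N)
        obs_auc = _auc_stat(obs, grid_values, axis=0)
        p_auc = two_tailed_p(obs_auc, dist.nodal_auc_diffs[m])
        q_auc = fdr_correct(p_auc)
        n_nodes = obs.shape[1]
        names = region_names or [f"N{i}" for i in range(n_nodes)]
        for j in range(n_nodes):
            results.append(ComparisonResult(
                metric_name=m, node=names[j], observed_diff=obs[:, j],
                observed_auc_diff=float(obs_auc[j]),
                p_per_density=two_tailed_p(obs[:, j], diffs[:, :, j]),
                p_auc=float(p_auc[j]), q_auc=float(q_auc[j]),
                n_permutations=dist.n_perm))
    return results
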