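"""Random covariance null models (Hirschberger-Qi-Steuer construction).

Observed covariance graphs are benchmarked against random matrices whose
off-diagonal mean and variance match the observed association matrix.
The HQS construction draws an N x m matrix X with i.i.d. normal(mu, s2)
entries and returns the Gram matrix C = X X', with

    m  = max(2, round((dbar^2 - ebar^2) / vbar))
    mu = sqrt(ebar / m)
    s2 = -mu^2 + sqrt(mu^4 + vbar / m)

where ebar and vbar are the mean and variance of the observed off-diagonal
entries and dbar the mean diagonal (1 for a correlation matrix).  C is PSD
by construction; only the ordering of its off-diagonal entries matters
downstream, so it is thresholded directly without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .construction import AssociationMatrix, adjacency_stack, edge_count
from .exceptions import DegenerateDataError
from .grid import DensityGrid
from .metrics import clustering_mean_curve, path_length_from_adjacency


def hqs_parameters(ebar: float, vbar: float, dbar: float = 1.0) -> tuple[int, float, float]:
    """(m, mu, s2) of the HQS construction for given observed moments."""
    if ebar <= 0:
        raise DegenerateDataError(
            f"HQS undefined: off-diagonal mean {ebar:.4g} <= 0")
    if vbar <= 0:
        raise DegenerateDataError(
            "HQS undefined: observed off-diagonal variance is zero")
    m = max(2, int(np.floor((dbar ** 2 - ebar ** 2) / vbar + 0.5)))
    mu = np.sqrt(ebar / m)
    s2 = -mu ** 2 + np.sqrt(mu ** 4 + vbar / m)
    return m, float(mu), float(s2)


def _offdiag_moments(r: np.ndarray) -> tuple[float, float]:
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = r[iu, ju]
    return float(vals.mean()), float(vals.var())


def hqs_random_covariance(assoc, seed=None) -> np.ndarray:
    """Draw one HQS random covariance matrix matched to ``assoc``.

    ``assoc`` may be an AssociationMatrix (diagonal taken as 1) or a raw
    square covariance matrix (diagonal taken as stored).  ``seed`` may be
    an int, SeedSequence, or Generator.
    """
    if isinstance(assoc, AssociationMatrix):
        r, dbar = assoc.r, 1.0
    else:
        r = np.asarray(assoc, dtype=float)
        dbar = float(np.diagonal(r).mean())
    ebar, vbar = _offdiag_moments(r)
    m, mu, s2 = hqs_parameters(ebar, vbar, dbar)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.normal(mu, np.sqrt(s2), size=(r.shape[0], m))
    return x @ x.T


def hqs_draw_from_r(r: np.ndarray, rng: np.random.Generator,
                    dbar: float = 1.0) -> np.ndarray:
    """Fast-path HQS draw for a correlation matrix stored with zero diagonal."""
    ebar, vbar = _offdiag_moments(r)
    m, mu, s2 = hqs_parameters(ebar, vbar, dbar)
    x = rng.normal(mu, np.sqrt(s2), size=(r.shape[0], m))
    return x @ x.T


@dataclass
class NullEnsemble:
    """An ensemble of null covariance matrices with per-density metric means."""

    n_null: int
    matrices: list
    grid: DensityGrid
    null_clustering: np.ndarray   # per-density ensemble mean
    null_path_length: np.ndarray
    seed: object = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "density": self.grid.as_array(),
            "null_mean_clustering": self.null_clustering,
            "null_mean_path_length": self.null_path_length,
            "n_null": self.n_null,
        })

    @classmethod
    def from_matrices(cls, matrices, grid: DensityGrid, seed=None) -> "NullEnsemble":
        """Build an ensemble (with metric curves) from explicit matrices."""
        n = matrices[0].shape[0]
        e_counts = np.array([edge_count(n, d) for d in grid.values])
        c_curves, l_curves = [], []
        for mat in matrices:
            c, l = _metric_curves_for_matrix(np.asarray(mat, dtype=float), e_counts)
            c_curves.append(c)
            l_curves.append(l)
        return cls(n_null=len(matrices), matrices=list(matrices), grid=grid,
                   null_clustering=np.mean(c_curves, axis=0),
                   null_path_length=np.mean(l_curves, axis=0), seed=seed)


def _metric_curves_for_matrix(mat: np.ndarray, e_counts: np.ndarray):
    work = mat.copy()
    np.fill_diagonal(work, 0.0)  # thresholding uses off-diagonal ordering only
    stack = adjacency_stack(work, e_counts)
    clustering = clustering_mean_curve(stack)
    lengths = np.array([path_length_from_adjacency(a)[0] for a in stack])
    return clustering, lengths


def null_metric_curves(assoc: AssociationMatrix, grid: DensityGrid,
                       n_null: int = 20, seed=None) -> NullEnsemble:
    """Generate ``n_null`` HQS matrices and their mean metric curves.

    Per-matrix seeds are spawned deterministically from the master seed.
    """
    if n_null < 1:
        raise DegenerateDataError("n_null must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(n_null)
    matrices = [hqs_random_covariance(assoc, ss) for ss in children]
    ens = NullEnsemble.from_matrices(matrices, grid, seed=seed)
    return ens


def normalized_curves(clustering: np.ndarray, path_length: np.ndarray,
                      ensemble: NullEnsemble):
    """gamma, lambda and sigma curves from raw curves and a null ensemble."""
    if np.any(ensemble.null_clustering <= 0) or np.any(ensemble.null_path_length <= 0):
        raise DegenerateDataError("degenerate null ensemble: non-positive null means")
    gamma = np.asarray(clustering) / ensemble.null_clustering
    lam = np.asarray(path_length) / ensemble.null_path_length
    return gamma, lam, gamma / lam
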