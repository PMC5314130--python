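"""Synthetic two-group regional-volume data with planted covariance structure.

The generator emulates the study design the pipeline targets: two groups
(defaults n=34 and n=28) of 92 correlated regional gray-matter volumes whose
inter-regional correlation structure differs between groups.  Volumes are
multivariate normal around a block (modular) correlation matrix: regions are
partitioned into modules; within-module correlation is ``rho_within_a`` /
``rho_within_b`` per group, between-module correlation is a shared
``rho_between`` baseline.  Optionally one module is "planted" as a hub set
in group A by elevating its correlation with all other regions.

Volumes carry no global-scaling confound (real inputs are already
normalized for total brain volume) and no age/sex covariate effects: the
downstream analysis consumes correlations only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .construction import BinaryGraph
from .data import SubjectVolumeTable
from .exceptions import ConfigurationError

PSD_TOL = -1e-10


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-group block-correlation volume generator.

    Defaults mirror the emulated study design: 92 regions, groups of 34
    and 28 subjects, 8 modules, strong background correlation (the study
    reports >93% of regional covariances significant at P<0.05, implying
    typical r above ~0.36 at n~30).
    """

    n_regions: int = 92
    n_subjects_a: int = 34
    n_subjects_b: int = 28
    n_modules: int = 8
    rho_within_a: float = 0.65
    rho_within_b: float = 0.55
    rho_between: float = 0.35
    volume_mean: float = 5.0
    volume_sd: float = 0.5
    seed: int = 0
    hub_module: int | None = None
    hub_rho: float = 0.55
    group_a_label: str = "A"
    group_b_label: str = "B"

    def __post_init__(self):
        if self.n_regions < 2 or self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ConfigurationError(
                f"need 2 <= n_modules <= n_regions, got n_regions={self.n_regions}, "
                f"n_modules={self.n_modules}")
        if self.n_subjects_a < 1 or self.n_subjects_b < 1:
            raise ConfigurationError("group sizes must be positive")
        for name in ("rho_within_a", "rho_within_b", "rho_between"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        if self.volume_sd <= 0:
            raise ConfigurationError("volume_sd must be > 0")
        if self.hub_module is not None and not 0 <= self.hub_module < self.n_modules:
            raise ConfigurationError(
                f"hub_module {self.hub_module} out of range for {self.n_modules} modules")
        # reject configurations whose implied correlation matrix is not PSD
        for group in ("a", "b"):
            sigma = self.correlation_matrix(group)
            lam = float(np.linalg.eigvalsh(sigma)[0])
            if lam < PSD_TOL:
                raise ConfigurationError(
                    f"implied group-{group.upper()} correlation matrix is not positive "
                    f"semi-definite (min eigenvalue {lam:.3e}); offending parameters: "
                    f"rho_within_{group}={getattr(self, 'rho_within_' + group)}, "
                    f"rho_between={self.rho_between}, hub_module={self.hub_module}, "
                    f"hub_rho={self.hub_rho}")

    # ------------------------------------------------------------------
    def module_sizes(self) -> list[int]:
        """Floor division with the remainder spread over the first modules."""
        base, rem = divmod(self.n_regions, self.n_modules)
        return [base + (1 if m < rem else 0) for m in range(self.n_modules)]

    def module_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_modules), self.module_sizes())

    def region_names(self) -> list[str]:
        width = max(3, len(str(self.n_regions)))
        return [f"R{i + 1:0{width}d}" for i in range(self.n_regions)]

    def correlation_matrix(self, group: str) -> np.ndarray:
        """The generating region x region correlation matrix for one group."""
        rho_w = {"a": self.rho_within_a, "b": self.rho_within_b}[group.lower()]
        modules = self.module_assignment()
        same = modules[:, None] == modules[None, :]
        sigma = np.where(same, rho_w, self.rho_between).astype(float)
        if self.hub_module is not None and group.lower() == "a":
            planted = modules == self.hub_module
            cross = planted[:, None] ^ planted[None, :]
            sigma[cross] = self.hub_rho
            # positive-definiteness (single-factor bound): regions correlated
            # hub_rho with a rho_between-coupled background need within-module
            # correlation >= hub_rho^2 / rho_between
            if self.rho_between > 0:
                floor = min(self.hub_rho ** 2 / self.rho_between + 0.02, 0.95)
                within = planted[:, None] & planted[None, :]
                sigma[within] = max(rho_w, floor)
        np.fill_diagonal(sigma, 1.0)
        return sigma


def _mvn_factor(sigma: np.ndarray) -> np.ndarray:
    """Factor F with F F' = sigma (eigendecomposition, tiny negatives clipped)."""
    w, v = np.linalg.eigh(sigma)
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_volume_table(config: SyntheticConfig) -> SubjectVolumeTable:
    """Draw a two-group volume table from the configured block model.

    Each group uses an independent RNG substream spawned from the master
    seed, so changing one group's size never perturbs the other's draws.
    """
    ss_a, ss_b = np.random.SeedSequence(config.seed).spawn(2)
    blocks, labels = [], []
    for group, n_sub, ss in (("a", config.n_subjects_a, ss_a),
                             ("b", config.n_subjects_b, ss_b)):
        factor = _mvn_factor(config.correlation_matrix(group))
        z = np.random.default_rng(ss).standard_normal((n_sub, config.n_regions))
        blocks.append(config.volume_mean + config.volume_sd * (z @ factor.T))
        label = config.group_a_label if group == "a" else config.group_b_label
        labels.extend([label] * n_sub)
    values = np.vstack(blocks)
    names = config.region_names()
    metadata = pd.DataFrame(
        {"region": names, "module": config.module_assignment()}).set_index("region")
    return SubjectVolumeTable(
        values=values,
        subject_ids=[f"S{i + 1:03d}" for i in range(values.shape[0])],
        region_names=names,
        group_labels=np.asarray(labels),
        node_metadata=metadata)


# ----------------------------------------------------------------------
# tiny canonical graphs used as oracle substrates in metric tests

_FIXTURES = ("triangle", "path3", "ring4", "star4", "complete(n)",
             "lattice(n,k)", "erdos_renyi(n,p,seed)")

_PARAM_RE = re.compile(r"^(\w+)\(([^)]*)\)$")


def fixture_graph(name: str) -> BinaryGraph:
    """Return a named canonical graph as a BinaryGraph.

    Available: triangle, path3, ring4, star4, complete(n), lattice(n,k)
    (ring lattice, each node tied to its k nearest neighbours), and
    erdos_renyi(n,p,seed).
    """
    name = name.strip()
    simple = {
        "triangle": lambda: nx.complete_graph(3),
        "path3": lambda: nx.path_graph(3),
        "ring4": lambda: nx.cycle_graph(4),
        "star4": lambda: nx.star_graph(3),
    }
    if name in simple:
        g = simple[name]()
    else:
        m = _PARAM_RE.match(name)
        if not m:
            raise ConfigurationError(
                f"unknown fixture graph {name!r}; available: {', '.join(_FIXTURES)}")
        kind, raw = m.group(1), m.group(2)
        args = [a.strip() for a in raw.split(",") if a.strip()]
        args = [a.split("=", 1)[1] if "=" in a else a for a in args]
        if kind == "complete" and len(args) == 1:
            g = nx.complete_graph(int(args[0]))
        elif kind == "lattice" and len(args) == 2:
            g = nx.watts_strogatz_graph(int(args[0]), int(args[1]), p=0.0)
        elif kind == "erdos_renyi" and len(args) == 3:
            g = nx.gnp_random_graph(int(args[0]), float(args[1]), seed=int(args[2]))
        else:
            raise ConfigurationError(
                f"unknown fixture graph {name!r}; available: {', '.join(_FIXTURES)}")
    adj = nx.to_numpy_array(g, dtype=np.uint8)
    return BinaryGraph.from_adjacency(adj)
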