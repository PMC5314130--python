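"""Model/Results interface for two-group structural covariance analysis.

``StructuralCovarianceModel`` is built from a subjects x regions volume
table with two group labels; ``fit`` runs the whole pipeline — group
association matrices, minimum connected density, density sweep, raw and
HQS-null-normalized global metric curves, permutation group comparison
with functional-density (AUC) statistics and FDR correction, and hub
classification — and returns a ``StructuralCovarianceResults`` carrying
the estimates, p/q-values and diagnostics, with ``summary()``, ``save()``
and plotting attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .comparison import (GLOBAL_METRICS, NODAL_METRICS, assemble_comparisons,
                         compute_group_curves, permutation_null)
from .construction import (AssociationMatrix, compute_association_matrix,
                           edge_count, min_connected_density,
                           threshold_to_density)
from .data import SubjectVolumeTable
from .exceptions import InputValidationError
from .grid import DensityGrid
from .hubs import HubComparison, HubTable, compare_hub_sets, identify_hubs

_FLOAT_FMT = "%.10g"


class StructuralCovarianceModel:
    """Two-group structural covariance network comparison.

    Parameters
    ----------
    table : SubjectVolumeTable
        Subjects x regions gray-matter volumes with a two-level group label.
    grid : DensityGrid, optional
        Candidate density grid; truncated at the minimum density of full
        connectivity during ``fit``.  Defaults to 0.02:0.02:0.50.

    Examples
    --------
    >>> from covnet import SyntheticConfig, generate_volume_table
    >>> from covnet.model import StructuralCovarianceModel
    >>> table = generate_volume_table(SyntheticConfig(seed=7))
    >>> res = StructuralCovarianceModel(table).fit(n_perm=200, seed=7)
    >>> print(res.summary())            # doctest: +SKIP
    """

    def __init__(self, table: SubjectVolumeTable, grid: DensityGrid | None = None):
        self.table = table
        self.grid = grid if grid is not None else DensityGrid.regular()

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid: DensityGrid | None = None,
                       subject_col: str = "subject_id", group_col: str = "group",
                       node_metadata: pd.DataFrame | None = None
                       ) -> "StructuralCovarianceModel":
        table = SubjectVolumeTable.from_dataframe(
            df, subject_col=subject_col, group_col=group_col,
            node_metadata=node_metadata)
        return cls(table, grid=grid)

    @classmethod
    def from_csv(cls, path, grid: DensityGrid | None = None, **kwargs
                 ) -> "StructuralCovarianceModel":
        return cls(SubjectVolumeTable.read_csv(path, **kwargs), grid=grid)

    # ------------------------------------------------------------------
    def fit(self, n_perm: int = 1000, seed=None,
            global_metrics=GLOBAL_METRICS,
            nodal_metrics=NODAL_METRICS,
            n_null: int = 20, n_null_perm: int = 5,
            hub_density: float | None = None) -> "StructuralCovarianceResults":
        """Run the full comparison pipeline.

        ``n_null`` HQS null matrices normalize the observed curves; inside
        permutations a reduced ensemble of ``n_null_perm`` keeps the
        permutation framework tractable (set ``n_null_perm=n_null`` for a
        fully matched scheme).  All randomness flows from ``seed`` through
        named substreams (observed nulls A/B, permutations).
        """
        table = self.table
        group_a, group_b = table.groups
        assoc_a = compute_association_matrix(table, group_a)
        assoc_b = compute_association_matrix(table, group_b)
        d_min = min_connected_density(assoc_a, assoc_b, self.grid)
        grid_used = self.grid.truncate_from(d_min)
        e_counts = np.array([edge_count(table.n_regions, d) for d in grid_used.values])

        ss = np.random.SeedSequence(seed)
        ss_obs_a, ss_obs_b, ss_perm = ss.spawn(3)
        curves = {}
        for assoc, ss_obs in ((assoc_a, ss_obs_a), (assoc_b, ss_obs_b)):
            curves[assoc.group_label] = compute_group_curves(
                assoc.r, e_counts, grid_used.as_array(),
                global_metrics=global_metrics, nodal_metrics=nodal_metrics,
                n_null=n_null, hqs_seed=ss_obs)
        dist = permutation_null(table, grid_used, n_perm=n_perm, seed=ss_perm,
                                global_metrics=global_metrics,
                                nodal_metrics=nodal_metrics,
                                n_null_perm=n_null_perm)
        comparisons = assemble_comparisons(curves[group_a], curves[group_b], dist,
                                           region_names=table.region_names)

        hub_d = hub_density if hub_density is not None else d_min
        hub_tables = {}
        for assoc in (assoc_a, assoc_b):
            g = threshold_to_density(assoc, hub_d)
            hub_tables[assoc.group_label] = identify_hubs(
                g.degree(), table.region_names, group_label=assoc.group_label)
        hub_cmp = compare_hub_sets(hub_tables[group_a], hub_tables[group_b])

        config = {
            "groups": [group_a, group_b],
            "n_subjects": {group_a: table.group_size(group_a),
                           group_b: table.group_size(group_b)},
            "n_regions": table.n_regions,
            "grid": {"d_min": self.grid.d_min, "step": self.grid.step,
                     "d_max": self.grid.d_max},
            "n_perm": n_perm, "n_null": n_null, "n_null_perm": n_null_perm,
            "global_metrics": list(global_metrics),
            "nodal_metrics": list(nodal_metrics),
            "hub_density": hub_d,
            "seed": seed if seed is None or isinstance(seed, int) else repr(seed),
        }
        return StructuralCovarianceResults(
            model=self, association_a=assoc_a, association_b=assoc_b,
            d_min=d_min, grid=grid_used, curves=curves,
            comparisons=comparisons, permutation_distributions=dist,
            hub_tables=hub_tables, hub_comparison=hub_cmp, config=config)


@dataclass
class StructuralCovarianceResults:
    """Fitted results: curves, comparisons, hubs and run metadata."""

    model: StructuralCovarianceModel
    association_a: AssociationMatrix
    association_b: AssociationMatrix
    d_min: float
    grid: DensityGrid
    curves: dict                       # group label -> metric name -> array
    comparisons: list
    permutation_distributions: object = field(repr=False, default=None)
    hub_tables: dict = field(default_factory=dict)
    hub_comparison: HubComparison | None = None
    config: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def global_comparisons(self) -> list:
        return [c for c in self.comparisons if c.node is None]

    @property
    def nodal_comparisons(self) -> list:
        return [c for c in self.comparisons if c.node is not None]

    def global_comparison_frame(self) -> pd.DataFrame:
        rows = [{"metric": c.metric_name, "auc_diff": c.observed_auc_diff,
                 "p": c.p_auc, "q": c.q_auc, "direction": c.direction}
                for c in self.global_comparisons]
        return pd.DataFrame(rows)

    def nodal_comparison_frame(self) -> pd.DataFrame:
        rows = [{"metric": c.metric_name, "region": c.node,
                 "auc_diff": c.observed_auc_diff, "p": c.p_auc, "q": c.q_auc,
                 "direction": c.direction}
                for c in self.nodal_comparisons]
        return pd.DataFrame(rows)

    def curve_frame(self) -> pd.DataFrame:
        """Tidy (group, density, metric, node, value) table of all curves."""
        rows = []
        dens = self.grid.as_array()
        names = self.model.table.region_names
        for group, metrics in self.curves.items():
            for metric, arr in metrics.items():
                if arr.ndim == 1:
                    for d, v in zip(dens, arr):
                        rows.append((group, d, metric, "", v))
                else:
                    for di, d in enumerate(dens):
                        for j, nm in enumerate(names):
                            rows.append((group, d, metric, nm, arr[di, j]))
        return pd.DataFrame(rows, columns=["group", "density", "metric",
                                           "node", "value"])

    # ------------------------------------------------------------------
    def summary(self, alpha: float = 0.05) -> str:
        ga, gb = self.config["groups"]
        n = self.config["n_subjects"]
        lines = [
            "Structural covariance network comparison",
            "=" * 72,
            f"Groups:        A = {ga} (n={n[ga]}), B = {gb} (n={n[gb]})",
            f"Regions:       {self.config['n_regions']}",
            f"Density grid:  {self.grid.values[0]:.2f}:{self.grid.step:.2f}:"
            f"{self.grid.values[-1]:.2f}  (D_min of full connectivity = "
            f"{self.d_min:.2f})",
            f"Permutations:  {self.config['n_perm']}   "
            f"HQS nulls: {self.config['n_null']} observed / "
            f"{self.config['n_null_perm']} per permutation",
            "",
            "Global measures (functional density / AUC statistics)",
            "-" * 72,
        ]
        gdf = self.global_comparison_frame()
        if not gdf.empty:
            lines.append(gdf.to_string(index=False,
                                       float_format=lambda v: f"{v:.4f}"))
        ndf = self.nodal_comparison_frame()
        sig = ndf[ndf["q"] < alpha] if not ndf.empty else ndf
        lines += ["", f"Nodal measures with q < {alpha} "
                      f"({0 if ndf.empty else len(sig)} of {len(ndf)} tests)",
                  "-" * 72]
        if len(sig):
            lines.append(sig.to_string(index=False,
                                       float_format=lambda v: f"{v:.4f}"))
        else:
            lines.append("(none)")
        if self.hub_comparison is not None:
            hc = self.hub_comparison
            lines += ["", "Hubs (degree >= mean + 1 s.d., at D_min)",
                      "-" * 72,
                      f"{ga}: {self.hub_tables[ga].n_hubs} hubs; "
                      f"{gb}: {self.hub_tables[gb].n_hubs} hubs; "
                      f"common {len(hc.common)}, unique-{ga} {len(hc.unique_a)}, "
                      f"unique-{gb} {len(hc.unique_b)}",
                      f"unique to {ga}: {', '.join(hc.unique_a) or '-'}",
                      f"unique to {gb}: {', '.join(hc.unique_b) or '-'}"]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, outdir, input_path=None) -> list:
        """Write the reproducible result bundle; returns written paths."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ga, gb = self.config["groups"]
        written = []

        def _csv(df, name, index=False):
            p = out / name
            df.to_csv(p, index=index, float_format=_FLOAT_FMT)
            written.append(p)

        _csv(self.association_a.to_dataframe(), f"association_{ga}.csv", index=True)
        _csv(self.association_b.to_dataframe(), f"association_{gb}.csv", index=True)
        _csv(self.curve_frame(), "metric_curves.csv")
        _csv(self.global_comparison_frame(), "global_comparison.csv")
        _csv(self.nodal_comparison_frame(), "nodal_comparison.csv")
        _csv(pd.concat([t.to_dataframe() for t in self.hub_tables.values()]),
             "hubs.csv")
        hub_summary = self.hub_comparison.to_dict() if self.hub_comparison else {}
        manifest = {
            "covnet_version": __version__,
            "config": self.config,
            "d_min": self.d_min,
            "grid_values": list(self.grid.values),
            "input": str(input_path) if input_path else None,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()).hexdigest(),
        }
        for name, payload in (("hub_summary.json", hub_summary),
                              ("manifest.json", manifest)):
            p = out / name
            p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            written.append(p)
        return written

    # ------------------------------------------------------------------
    def plot_global_curves(self, metric: str = "clustering", ax=None):
        """Metric-vs-density curves for both groups (matplotlib axes)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        dens = self.grid.as_array()
        for group, metrics in self.curves.items():
            if metric not in metrics:
                raise InputValidationError(
                    f"metric {metric!r} was not computed; available: "
                    f"{sorted(metrics)}")
            ax.plot(dens, metrics[metric], marker="o", markersize=3, label=group)
        ax.set_xlabel("network density")
        ax.set_ylabel(metric)
        ax.legend(title="group")
        return ax
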