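"""End-to-end run configuration and orchestration.

``RunConfig`` captures everything needed to reproduce a run (input path,
grid, permutation and null-ensemble sizes, master seed, metric selection);
``run_pipeline`` reads the table, fits the model and writes the result
bundle.  Defaults follow the conventional analysis parameters: density
grid 0.02:0.02:0.50, 1000 permutations, 20 HQS nulls for the observed
curves and 5 inside permutations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comparison import GLOBAL_METRICS, NODAL_METRICS
from .data import MIN_GROUP_SIZE, SubjectVolumeTable
from .exceptions import InputValidationError
from .grid import DensityGrid
from .model import StructuralCovarianceModel, StructuralCovarianceResults

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible description of one pipeline run."""

    input: str = None
    output_dir: str = "covnet_results"
    d_start: float = 0.02
    step: float = 0.02
    d_max: float = 0.50
    n_perm: int = 1000
    n_null: int = 20
    n_null_perm: int = 5
    seed: int = 0
    global_metrics: list = field(default_factory=lambda: list(GLOBAL_METRICS))
    nodal_metrics: list = field(default_factory=lambda: list(NODAL_METRICS))
    hub_density: float | None = None
    log_level: str = "INFO"

    def grid(self) -> DensityGrid:
        return DensityGrid(d_min=self.d_start, step=self.step, d_max=self.d_max)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InputValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_manifest(cls, path) -> "RunConfig":
        """Rebuild a RunConfig from a saved result-bundle manifest."""
        manifest = json.loads(Path(path).read_text())
        cfg = manifest["config"]
        return cls(input=manifest.get("input"),
                   d_start=cfg["grid"]["d_min"], step=cfg["grid"]["step"],
                   d_max=cfg["grid"]["d_max"], n_perm=cfg["n_perm"],
                   n_null=cfg["n_null"], n_null_perm=cfg["n_null_perm"],
                   seed=cfg["seed"], global_metrics=cfg["global_metrics"],
                   nodal_metrics=cfg["nodal_metrics"],
                   hub_density=cfg.get("hub_density"))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_pipeline(config: RunConfig, table: SubjectVolumeTable | None = None
                 ) -> StructuralCovarianceResults:
    """Read inputs, fit the model, write the result bundle.

    ``table`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is read from ``config.input``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if table is None:
        if not config.input:
            raise InputValidationError("no input table: set config.input")
        table = SubjectVolumeTable.read_csv(config.input)
    model = StructuralCovarianceModel(table, grid=config.grid())
    logger.info("fitting: %d subjects, %d regions, %d permutations",
                table.n_subjects, table.n_regions, config.n_perm)
    results = model.fit(n_perm=config.n_perm, seed=config.seed,
                        global_metrics=tuple(config.global_metrics),
                        nodal_metrics=tuple(config.nodal_metrics),
                        n_null=config.n_null, n_null_perm=config.n_null_perm,
                        hub_density=config.hub_density)
    if config.output_dir:
        results.save(config.output_dir, input_path=config.input)
        logger.info("bundle written to %s", config.output_dir)
    return results


# ----------------------------------------------------------------------

def validate_input(path) -> dict:
    """Schema/sanity report for a volume-table CSV; machine readable.

    Returns ``{"ok": bool, "errors": [...], "summary": {...}}`` without
    raising on content problems (I/O and parse failures still raise).
    """
    path = Path(path)
    report = {"ok": False, "errors": [], "summary": {}}
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise InputValidationError(f"cannot parse {path}: {exc}") from exc
    for col in ("subject_id", "group"):
        if col not in df.columns:
            report["errors"].append(f"required column {col!r} missing")
    if report["errors"]:
        return report
    region_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    report["summary"]["n_regions"] = len(region_cols)
    groups = sorted(df["group"].astype(str).unique())
    report["summary"]["groups"] = {
        g: int((df["group"].astype(str) == g).sum()) for g in groups}
    if len(groups) != 2:
        report["errors"].append(
            f"exactly two groups required, found {len(groups)}: {groups}")
    vals = df[region_cols].apply(pd.to_numeric, errors="coerce")
    n_missing = int(vals.isna().sum().sum())
    if n_missing:
        bad = vals.columns[vals.isna().any()][0]
        row = int(vals[bad].isna().idxmax())
        report["errors"].append(
            f"{n_missing} missing/non-numeric values (first at row {row}, "
            f"region {bad!r})")
    if len(groups) == 2 and not n_missing:
        for g in groups:
            mask = df["group"].astype(str) == g
            if mask.sum() < MIN_GROUP_SIZE:
                report["errors"].append(
                    f"group {g!r} has {int(mask.sum())} subjects; need >= "
                    f"{MIN_GROUP_SIZE}")
                continue
            sds = vals[mask].std(ddof=0)
            for region in sds.index[sds == 0]:
                report["errors"].append(
                    f"region {region!r} is constant within group {g!r}")
    report["ok"] = not report["errors"]
    if report["ok"]:
        # full contract check (raises only on internal inconsistency)
        SubjectVolumeTable.from_dataframe(df)
    return report
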