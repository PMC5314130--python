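"""The subject-volume table: the pipeline's sole empirical input.

A rectangular table of regional gray-matter volumes (rows = subjects,
columns = named regions) plus a two-level group label per subject.  On
disk this is a CSV/TSV whose first two columns are ``subject_id`` and
``group`` followed by one column per region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputValidationError

MIN_GROUP_SIZE = 4  # Pearson r is degenerate below this


@dataclass
class SubjectVolumeTable:
    """Subjects x regions volume matrix with group labels.

    Attributes
    ----------
    values : (n_subjects, n_regions) float array
        Regional volumes, arbitrary units, assumed already normalized for
        total brain volume.
    subject_ids : list of str
    region_names : list of str
    group_labels : (n_subjects,) array of str
        Exactly two distinct labels; each group needs >= 4 subjects.
    node_metadata : pandas.DataFrame, optional
        Per-region annotations (e.g. module or functional-network
        assignment), indexed by region name.
    """

    values: np.ndarray
    subject_ids: list
    region_names: list
    group_labels: np.ndarray
    node_metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        self.subject_ids = list(self.subject_ids)
        self.region_names = list(self.region_names)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n_sub, n_reg = self.values.shape
        if len(self.subject_ids) != n_sub:
            raise InputValidationError(
                f"{len(self.subject_ids)} subject ids for {n_sub} rows")
        if len(self.region_names) != n_reg:
            raise InputValidationError(
                f"{len(self.region_names)} region names for {n_reg} columns")
        if len(self.group_labels) != n_sub:
            raise InputValidationError(
                f"{len(self.group_labels)} group labels for {n_sub} rows")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise InputValidationError(
                f"missing/non-finite volume at subject "
                f"{self.subject_ids[bad[0]]!r}, region {self.region_names[bad[1]]!r}")
        groups = self.groups
        if len(groups) != 2:
            raise InputValidationError(
                f"exactly two groups required, found {len(groups)}: {groups}")
        for g in groups:
            mask = self.group_labels == g
            if mask.sum() < MIN_GROUP_SIZE:
                raise InputValidationError(
                    f"group {g!r} has {int(mask.sum())} subjects; "
                    f"need >= {MIN_GROUP_SIZE}")
            sds = self.values[mask].std(axis=0)
            if np.any(sds == 0):
                region = self.region_names[int(np.argmin(sds))]
                raise InputValidationError(
                    f"region {region!r} is constant within group {g!r}")

    # ------------------------------------------------------------------
    @property
    def groups(self) -> list:
        """The two group labels in sorted order (group A first)."""
        return sorted(set(str(g) for g in self.group_labels))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def group_values(self, group: str) -> np.ndarray:
        mask = self.group_labels == group
        if not mask.any():
            raise InputValidationError(
                f"unknown group {group!r}; available: {self.groups}")
        return self.values[mask]

    def group_size(self, group: str) -> int:
        return int((self.group_labels == group).sum())

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject_col: str = "subject_id",
                       group_col: str = "group",
                       node_metadata: pd.DataFrame | None = None) -> "SubjectVolumeTable":
        for col in (subject_col, group_col):
            if col not in df.columns:
                raise InputValidationError(f"required column {col!r} missing")
        region_cols = [c for c in df.columns if c not in (subject_col, group_col)]
        if not region_cols:
            raise InputValidationError("no region columns found")
        try:
            values = df[region_cols].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise InputValidationError(f"non-numeric volume data: {exc}") from exc
        return cls(values=values,
                   subject_ids=[str(s) for s in df[subject_col]],
                   region_names=region_cols,
                   group_labels=df[group_col].astype(str).to_numpy(),
                   node_metadata=node_metadata)

    @classmethod
    def read_csv(cls, path, sep: str | None = None, **kwargs) -> "SubjectVolumeTable":
        """Read a volume table from CSV/TSV (separator sniffed by default)."""
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        return cls.from_dataframe(df, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.copy(), columns=self.region_names)
        df.insert(0, "group", self.group_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")
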