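"""Hub classification and between-group hub-set comparison.

A node is a hub if its degree is at least one standard deviation above the
mean network degree (sample s.d., N-1 denominator).  Hubs are classified
per group at the minimum density of full connectivity (configurable), and
the two groups' hub sets are compared as common / unique-to-A /
unique-to-B partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputValidationError

logger = logging.getLogger(__name__)


@dataclass
class HubTable:
    """Per-node hub classification for one group's network."""

    group_label: str
    region_names: list
    degree: np.ndarray
    hub_flag: np.ndarray
    threshold_used: float

    @property
    def hubs(self) -> list:
        return [n for n, f in zip(self.region_names, self.hub_flag) if f]

    @property
    def n_hubs(self) -> int:
        return int(self.hub_flag.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group_label,
            "region": self.region_names,
            "degree": self.degree.astype(int),
            "threshold": self.threshold_used,
            "is_hub": self.hub_flag,
        })


@dataclass
class HubComparison:
    """Partition of the union of both groups' hubs, in stable region order."""

    common: list
    unique_a: list
    unique_b: list

    def to_dict(self) -> dict:
        return {"hubs_common": self.common, "hubs_unique_a": self.unique_a,
                "hubs_unique_b": self.unique_b}


def identify_hubs(degree, region_names=None, group_label: str = "",
                  ) -> HubTable:
    """Flag nodes whose degree is >= mean + 1 sample s.d. of network degree.

    With zero degree variance no node is a hub (a warning is logged): the
    rule is meant to pick out the upper tail, which a flat distribution
    does not have.
    """
    degree = np.asarray(degree, dtype=float)
    if degree.size < 2:
        raise InputValidationError("hub classification needs >= 2 nodes")
    names = list(region_names) if region_names is not None else [
        f"N{i}" for i in range(degree.size)]
    mean = float(degree.mean())
    sd = float(degree.std(ddof=1))
    threshold = mean + sd
    if sd == 0:
        logger.warning("degree distribution has zero variance; no hubs flagged")
        flags = np.zeros(degree.size, dtype=bool)
    else:
        flags = degree >= threshold
    return HubTable(group_label=group_label, region_names=names,
                    degree=degree, hub_flag=flags, threshold_used=threshold)


def compare_hub_sets(hubs_a: HubTable, hubs_b: HubTable) -> HubComparison:
    """Common and group-unique hubs, ordered by region position."""
    if hubs_a.region_names != hubs_b.region_names:
        raise InputValidationError("hub tables cover different region sets")
    set_a, set_b = set(hubs_a.hubs), set(hubs_b.hubs)
    order = hubs_a.region_names
    return HubComparison(
        common=[r for r in order if r in set_a and r in set_b],
        unique_a=[r for r in order if r in set_a and r not in set_b],
        unique_b=[r for r in order if r in set_b and r not in set_a])
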