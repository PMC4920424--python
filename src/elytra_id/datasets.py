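"""Fragment feature tables grouped by specimen for leakage-safe CV."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features_global import GLOBAL_NAMES
from .features_local import LOCAL_NAMES

#: Feature-set definitions: global_1 excludes the key-object (DoG) block,
#: global_2 is exactly that block, local is the window-descriptor block.
FEATURE_SET_PREFIXES = {
    "global1": ("stat_", "spec_", "col_", "gab_"),
    "global2": ("dog_",),
    "local": ("loc_",),
    "all": ("stat_", "spec_", "col_", "gab_", "dog_", "loc_"),
}
_ALIASES = {"global_1": "global1", "global_2": "global2"}

ALL_FEATURE_NAMES = list(GLOBAL_NAMES) + list(LOCAL_NAMES)


def feature_set_columns(columns, feature_set: str) -> list[str]:
    """Columns of ``columns`` belonging to the named feature set."""
    name = _ALIASES.get(feature_set, feature_set)
    try:
        prefixes = FEATURE_SET_PREFIXES[name]
    except KeyError:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"choose from {sorted(FEATURE_SET_PREFIXES)}") from None
    return [c for c in columns if c.startswith(prefixes)]


@dataclass
class SpecimenDataset:
    """Fragment features with species labels and specimen groups.

    ``features`` has one row per fragment; ``labels`` holds the species
    index and ``groups`` the source specimen id, both aligned with the
    feature rows.  Holding out whole specimens (groups) prevents
    specimen-level leakage between training and test fragments.
    """

    features: pd.DataFrame
    labels: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        n = len(self.features)
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("labels and groups must align with feature rows")

    def matrix(self, feature_set: str = "all") -> pd.DataFrame:
        return self.features[feature_set_columns(self.features.columns, feature_set)]

    def specimens_by_species(self) -> dict[int, np.ndarray]:
        table = pd.DataFrame({"species": self.labels.values, "specimen": self.groups.values})
        return {int(sp): grp["specimen"].unique()
                for sp, grp in table.groupby("species")}

    def to_csv(self, path: str | Path) -> None:
        out = self.features.copy()
        out["species_index"] = self.labels.values
        out["specimen_id"] = self.groups.values
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpecimenDataset":
        table = pd.read_csv(path)
        labels = table.pop("species_index")
        groups = table.pop("specimen_id")
        return cls(features=table, labels=labels, groups=groups)
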