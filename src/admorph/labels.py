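"""Label-definition tables for the Neuromorphometrics-style protocol.

A label table maps integer label ids in a segmentation to named brain
structures, their hemisphere, tissue class and left/right pairing.  The
shipped default encodes the protocol's split of 40 non-cortical and 98
cortical regions; five non-cortical labels (vessels, cerebral exterior,
optic chiasm) are carried in the table but flagged ``in_features=False``
so that raw volumes are still reported while the merged feature set stays
at the published size.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

TISSUE_CLASSES = frozenset(
    {"cortical_gm", "deep_gm", "wm", "ventricle_csf", "other_csf", "other"}
)
HEMISPHERES = frozenset({"left", "right", "none"})

#: structures whose left/right volumes are kept as separate features in
#: addition to their merged sum
EXCEPTION_STRUCTURES = ("Amygdala", "Hippocampus", "InfLatVent", "LateralVentricle")

_REQUIRED_COLUMNS = [
    "label_id",
    "structure_name",
    "merged_name",
    "hemisphere",
    "tissue_class",
    "paired_partner",
    "in_features",
]


@dataclass(frozen=True)
class LabelTable:
    """Validated label-definition table.

    Parameters
    ----------
    df
        One row per label with columns ``label_id`` (positive int, unique),
        ``structure_name`` (unique), ``merged_name`` (feature name after
        left/right merging), ``hemisphere`` (left/right/none),
        ``tissue_class``, ``paired_partner`` (empty for unpaired) and
        ``in_features`` (bool).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"label table missing columns: {missing}")
        if df.empty:
            raise ValueError("label table is empty")
        if df["label_id"].duplicated().any():
            dupes = sorted(df.loc[df["label_id"].duplicated(), "label_id"])
            raise ValueError(f"duplicate label ids: {dupes}")
        if (df["label_id"] <= 0).any():
            raise ValueError("label ids must be positive (0 is background)")
        if df["structure_name"].duplicated().any():
            raise ValueError("duplicate structure names")
        bad_h = set(df["hemisphere"]) - HEMISPHERES
        if bad_h:
            raise ValueError(f"unknown hemisphere values: {sorted(bad_h)}")
        bad_t = set(df["tissue_class"]) - TISSUE_CLASSES
        if bad_t:
            raise ValueError(f"unknown tissue classes: {sorted(bad_t)}")
        # pairing symmetry; hemisphere=none iff unpaired
        by_name = df.set_index("structure_name")
        for name, row in by_name.iterrows():
            partner = row["paired_partner"]
            if partner == "":
                if row["hemisphere"] != "none":
                    raise ValueError(f"{name}: hemisphere set but no partner")
                continue
            if row["hemisphere"] == "none":
                raise ValueError(f"{name}: partner set but hemisphere is none")
            if partner not in by_name.index:
                raise ValueError(f"{name}: partner {partner!r} not in table")
            if by_name.loc[partner, "paired_partner"] != name:
                raise ValueError(f"asymmetric pairing: {name} / {partner}")

    # -- convenience views -------------------------------------------------

    @property
    def label_ids(self) -> pd.Series:
        return self.df["label_id"]

    @property
    def structure_names(self) -> pd.Series:
        return self.df["structure_name"]

    def id_to_name(self) -> dict[int, str]:
        return dict(zip(self.df["label_id"], self.df["structure_name"]))

    def feature_rows(self) -> pd.DataFrame:
        """Rows contributing to the merged feature set."""
        return self.df[self.df["in_features"].astype(bool)]

    def merged_names(self) -> list[str]:
        """Merged feature names (one per pair, one per unpaired), table order."""
        seen: dict[str, None] = {}
        for name in self.feature_rows()["merged_name"]:
            seen.setdefault(name, None)
        return list(seen)

    def write_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["in_features"] = out["in_features"].astype(int)
        out.to_csv(path, index=False)


def load_label_table(path: str | Path) -> LabelTable:
    """Read and validate a label table CSV."""
    df = pd.read_csv(Path(path), dtype={"structure_name": str, "merged_name": str})
    if df.empty:
        raise ValueError(f"label table {path} contains no rows")
    df["paired_partner"] = df["paired_partner"].fillna("").astype(str)
    df["in_features"] = df["in_features"].astype(bool)
    return LabelTable(df)


def default_label_table() -> LabelTable:
    """The shipped 138-region table (40 non-cortical + 98 cortical labels)."""
    with resources.as_file(
        resources.files("admorph.data").joinpath("nmm_labels.csv")
    ) as p:
        return load_label_table(p)
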