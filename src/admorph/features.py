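"""Assembly of the 86-feature morphometric representation.

Per-structure volumes are reduced to one feature per merged (left+right)
structure, with left/right kept additionally for four structures known to
be informative (amygdala, hippocampus, inferior lateral ventricle, lateral
ventricle), six surrogate aggregates (ventricles, cortical grey matter,
deep grey matter, white matter, brain tissue, total brain) and the two
covariates age and gender.  With the default label table that is
49 merged cortical + 21 merged non-cortical + 8 hemisphere exceptions
+ 6 surrogates + age + gender = 86 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .labels import EXCEPTION_STRUCTURES, LabelTable

SURROGATE_FEATURES = (
    "Ventricles",
    "CorticalGreyMatter",
    "DeepGreyMatter",
    "WhiteMatter",
    "BrainTissue",
    "Brain",
)
COVARIATE_FEATURES = ("Age", "Gender")

#: gender coding used throughout the package
GENDER_FEMALE, GENDER_MALE = 0, 1


@dataclass
class FeatureMatrix:
    """Subjects x named features with a raw/corrected provenance flag.

    ``data`` holds volumes in mm^3 (or deviations from the control norm once
    corrected), ``Age`` in years and ``Gender`` as 0=female / 1=male.
    """

    data: pd.DataFrame
    status: str = "raw"
    visit: str = "bl"
    meta: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def volumetric_features(self) -> list[str]:
        return [c for c in self.data.columns if c not in COVARIATE_FEATURES]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.data.copy(), self.status, self.visit, dict(self.meta))

    def write_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "status", self.status)
        out.insert(0, "visit", self.visit)
        out.to_csv(path, index=True, index_label="subject")


def merge_paired(wide: pd.DataFrame, table: LabelTable) -> pd.DataFrame:
    """Merge left/right volumes into one feature per structure.

    Returns one column per merged structure (left + right, exact sum) and per
    unpaired structure, plus separate ``Left*``/``Right*`` columns for the
    exception structures.  Raises if a hemisphere counterpart is missing.
    """
    rows = table.feature_rows()
    out = {}
    for merged_name, group in rows.groupby("merged_name", sort=False):
        names = list(group["structure_name"])
        missing = [n for n in names if n not in wide.columns]
        if missing:
            raise ValueError(
                f"structure {merged_name}: missing hemisphere volumes {missing}"
            )
        out[merged_name] = wide[names].sum(axis=1)
    # preserve table order of merged names
    merged = pd.DataFrame({name: out[name] for name in table.merged_names()})
    for structure in EXCEPTION_STRUCTURES:
        for side in ("Left", "Right"):
            col = f"{side}{structure}"
            if structure in merged.columns:
                if col not in wide.columns:
                    raise ValueError(f"missing hemisphere volume {col}")
                merged[col] = wide[col]
    merged.index = wide.index
    return merged


def aggregate_surrogates(wide: pd.DataFrame, table: LabelTable) -> pd.DataFrame:
    """The six surrogate aggregate features.

    Membership follows the table's ``tissue_class`` column: ventricles,
    cortical GM, deep GM and white matter are class sums; brain tissue is
    all feature structures excluding ventricular and other CSF; total brain
    is brain tissue plus ventricles/CSF (and doubles as the head-size
    approximation downstream).
    """
    rows = table.feature_rows()
    missing = [n for n in rows["structure_name"] if n not in wide.columns]
    if missing:
        raise ValueError(f"volumes missing for structures: {missing}")

    def class_sum(*classes: str) -> pd.Series:
        names = rows.loc[rows["tissue_class"].isin(classes), "structure_name"]
        if len(names) == 0:
            return pd.Series(0.0, index=wide.index)
        return wide[list(names)].sum(axis=1)

    tissue_classes = ("cortical_gm", "deep_gm", "wm", "other")
    out = pd.DataFrame(index=wide.index)
    out["Ventricles"] = class_sum("ventricle_csf")
    out["CorticalGreyMatter"] = class_sum("cortical_gm")
    out["DeepGreyMatter"] = class_sum("deep_gm")
    out["WhiteMatter"] = class_sum("wm")
    out["BrainTissue"] = class_sum(*tissue_classes)
    # single direct sum so Brain is bit-identical to the head-size covariate
    out["Brain"] = class_sum(*tissue_classes, "ventricle_csf", "other_csf")
    return out


def build_feature_matrix(
    wide: pd.DataFrame,
    table: LabelTable,
    subjects: pd.DataFrame | None = None,
    visit: str = "bl",
) -> FeatureMatrix:
    """Full feature matrix: merged structures, surrogates, age and gender.

    ``subjects`` must carry ``age`` and ``gender`` columns indexed (or
    indexable) by subject id; omit it to build a purely volumetric matrix.
    """
    merged = merge_paired(wide, table)
    surrogates = aggregate_surrogates(wide, table)
    data = pd.concat([merged, surrogates], axis=1)
    if subjects is not None:
        meta = subjects.set_index("subject") if "subject" in subjects.columns else subjects
        missing = [s for s in data.index if s not in meta.index]
        if missing:
            raise ValueError(f"subjects missing from metadata: {missing[:5]}")
        data["Age"] = meta.loc[data.index, "age"].astype(float)
        data["Gender"] = meta.loc[data.index, "gender"].astype(int)
    return FeatureMatrix(data, status="raw", visit=visit)


def load_feature_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="subject")
    visit = str(df.pop("visit").iloc[0]) if "visit" in df.columns else "bl"
    status = str(df.pop("status").iloc[0]) if "status" in df.columns else "raw"
    return FeatureMatrix(df, status=status, visit=visit)
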