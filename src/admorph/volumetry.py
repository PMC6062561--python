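"""Regional volumetry from integer label maps.

Volumes are plain voxel counts times the voxel volume, with no
partial-volume weighting: the inputs are hard label maps.  Only voxel
spacing is read from NIfTI headers; orientation is irrelevant for counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .labels import LabelTable

VOLUME_COLUMNS = ["subject", "visit", "structure", "volume_mm3"]


@dataclass(frozen=True)
class LabelMap:
    """3D integer label image with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(np.mod(self.data, 1) == 0):
                raise ValueError("label map must be integer-valued")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values: {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def load_label_map(path: str | Path) -> LabelMap:
    """Load a NIfTI-1 label map, taking spacing from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.rint(data).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(data, spacing)


def save_label_map(label_map: LabelMap, path: str | Path) -> None:
    affine = np.diag(list(label_map.spacing) + [1.0])
    img = nib.Nifti1Image(label_map.data.astype(np.int16), affine)
    img.header.set_zooms(label_map.spacing)
    nib.save(img, str(path))


def compute_label_volumes(
    label_map: LabelMap,
    table: LabelTable,
    subject: str = "",
    visit: str = "bl",
) -> pd.DataFrame:
    """Per-structure volumes in mm^3 for one label map.

    Every structure in the table is reported; labels absent from the map get
    volume 0.  Label 0 is background and never reported.  Labels present in
    the map but missing from the table raise ``ValueError`` listing the ids.
    """
    data = np.asarray(label_map.data).astype(np.int64, copy=False)
    if data.min() < 0:
        raise ValueError("label map contains negative labels")
    counts = np.bincount(data.ravel())
    present = np.nonzero(counts)[0]
    known = set(int(i) for i in table.label_ids)
    unknown = sorted(int(i) for i in present if i != 0 and int(i) not in known)
    if unknown:
        raise ValueError(f"labels present in map but missing from table: {unknown}")
    vv = label_map.voxel_volume
    records = []
    for lid, name in zip(table.df["label_id"], table.df["structure_name"]):
        n = counts[lid] if lid < len(counts) else 0
        records.append((subject, visit, name, float(n) * vv))
    return pd.DataFrame(records, columns=VOLUME_COLUMNS)


def volumes_from_directory(
    directory: str | Path,
    table: LabelTable,
    visit: str = "bl",
    pattern: str = "*.nii*",
) -> pd.DataFrame:
    """Run volumetry over a directory of label maps (one map per subject)."""
    frames = []
    for path in sorted(Path(directory).glob(pattern)):
        subject = path.name.split(".")[0]
        frames.append(compute_label_volumes(load_label_map(path), table, subject, visit))
    if not frames:
        raise ValueError(f"no label maps matching {pattern!r} in {directory}")
    return pd.concat(frames, ignore_index=True)


def load_volume_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format volume CSV (subject, visit, structure, volume_mm3)."""
    df = pd.read_csv(Path(path))
    missing = [c for c in VOLUME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"volume CSV missing columns: {missing}")
    if df.empty:
        raise ValueError(f"volume CSV {path} contains no rows")
    if not pd.api.types.is_numeric_dtype(df["volume_mm3"]):
        raise ValueError("volume_mm3 column is not numeric")
    if (df["volume_mm3"] < 0).any():
        raise ValueError("negative volumes in volume CSV")
    key = ["subject", "visit", "structure"]
    if df.duplicated(subset=key).any():
        dupes = df.loc[df.duplicated(subset=key), key].drop_duplicates()
        raise ValueError(
            "duplicate (subject, visit, structure) rows: "
            + "; ".join(map(str, dupes.itertuples(index=False, name=None)))
        )
    return df[VOLUME_COLUMNS].copy()


def write_volume_csv(volumes: pd.DataFrame, path: str | Path) -> None:
    volumes[VOLUME_COLUMNS].to_csv(path, index=False)


def volumes_to_wide(volumes: pd.DataFrame, visit: str | None = None) -> pd.DataFrame:
    """Pivot long volume records to a subjects x structures matrix."""
    df = volumes if visit is None else volumes[volumes["visit"] == visit]
    wide = df.pivot(index="subject", columns="structure", values="volume_mm3")
    wide.columns.name = None
    wide.index.name = "subject"
    return wide
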