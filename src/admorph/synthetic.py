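"""Synthetic ADNI-like cohorts for end-to-end testing of the pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, not brain anatomy: per-structure baseline volumes with linear
age/gender/head-size dependence plus group-specific offsets and Gaussian
noise, and follow-up volumes obtained by applying a log-scale volume-change
draw per interval.  Head size is drawn first and structures are
conditioned on it, mirroring the size-as-covariate design of the nuisance
correction.  Structures are independent given head size (real covariances
among regions are not modelled).

Baseline volume of structure s for subject i in group g:

    v_si = b_s + c_age_s * age_i + c_gender_s * gender_i
           + c_size_s * head_i + offset_s(g) + eps,   eps ~ N(0, sd_s(g))

Follow-up volume per interval:  v' = v * exp(r / 100),
r ~ N(mu_s(g, interval), sd_s(g, interval)).

Non-positive baseline draws are resampled (not clipped) so group SDs are
not distorted.  Gender is coded 0=female, 1=male.  The default parameter
file anchors group offsets, noise SDs and volume-change rates to published
ADNI-scale summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .labels import LabelTable, default_label_table
from .volumetry import LabelMap

GROUPS = ("HC", "sMCI", "pMCI", "AD")
INTERVALS = ("m12", "m24")

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass
class StructureParams:
    """Generating parameters of one structure (label-level)."""

    name: str
    b: float
    c_age: float = 0.0
    c_gender: float = 0.0
    c_size: float = 0.0
    offsets: dict[str, float] = field(default_factory=dict)  # group -> mm^3
    sds: dict[str, float] = field(default_factory=dict)  # group -> mm^3
    #: interval -> group -> (mean %, SD %) on the log scale
    atrophy: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    structures: list[StructureParams]
    n_per_group: dict[str, int]
    age_range: tuple[float, float] = (55.0, 90.0)
    p_male: float = 0.5
    head_size_mean: float = 1_200_000.0
    head_size_sd: float = 110_000.0
    intervals: tuple[str, ...] = INTERVALS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("spec contains no structures")
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"n_per_group[{g!r}] must be >= 2, got {n}")
        if not 0 <= self.p_male <= 1:
            raise ValueError(f"p_male must lie in [0, 1], got {self.p_male}")
        if self.head_size_sd < 0:
            raise ValueError("head_size_sd must be non-negative")
        for sp in self.structures:
            for g, sd in sp.sds.items():
                if sd < 0:
                    raise ValueError(f"{sp.name}: SD for {g} is negative")
            for interval, per_group in sp.atrophy.items():
                for g, (_, sd) in per_group.items():
                    if sd < 0:
                        raise ValueError(
                            f"{sp.name}: atrophy SD for {g}/{interval} is negative"
                        )
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range upper bound below lower bound")
        if self.age_range[1] == self.age_range[0]:
            warnings.warn("degenerate age range: age covariate is constant")
        if self.p_male in (0.0, 1.0):
            warnings.warn("degenerate p_male: gender covariate is constant")

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if g in self.n_per_group]

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_per_group": dict(self.n_per_group),
            "age_range": list(self.age_range),
            "p_male": self.p_male,
            "head_size": {"mean": self.head_size_mean, "sd": self.head_size_sd},
            "intervals": list(self.intervals),
            "seed": self.seed,
            "structures": [
                {
                    "name": sp.name, "b": sp.b, "c_age": sp.c_age,
                    "c_gender": sp.c_gender, "c_size": sp.c_size,
                    "offsets": dict(sp.offsets), "sds": dict(sp.sds),
                    "atrophy": {
                        i: {g: list(v) for g, v in per.items()}
                        for i, per in sp.atrophy.items()
                    },
                }
                for sp in self.structures
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text())
        structures = [
            StructureParams(
                name=s["name"], b=s["b"], c_age=s.get("c_age", 0.0),
                c_gender=s.get("c_gender", 0.0), c_size=s.get("c_size", 0.0),
                offsets=dict(s.get("offsets", {})), sds=dict(s.get("sds", {})),
                atrophy={
                    i: {g: tuple(v) for g, v in per.items()}
                    for i, per in s.get("atrophy", {}).items()
                },
            )
            for s in doc["structures"]
        ]
        return cls(
            structures=structures,
            n_per_group=dict(doc["n_per_group"]),
            age_range=tuple(doc.get("age_range", (55.0, 90.0))),
            p_male=float(doc.get("p_male", 0.5)),
            head_size_mean=float(doc.get("head_size", {}).get("mean", 1_200_000.0)),
            head_size_sd=float(doc.get("head_size", {}).get("sd", 110_000.0)),
            intervals=tuple(doc.get("intervals", INTERVALS)),
            seed=int(doc.get("seed", 0)),
        )


def _load_default_params() -> dict:
    with resources.as_file(
        resources.files("admorph.data").joinpath("default_cohort.yaml")
    ) as p:
        return yaml.safe_load(p.read_text())


def default_cohort_spec(
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    table: LabelTable | None = None,
) -> CohortSpec:
    """Expand the shipped parameter file into a per-label CohortSpec.

    Anchored structures carry published offsets/SDs; every other label gets
    tissue-class-level defaults scaled to its reference volume.  Volume
    change rates are resolved per label first by merged structure name,
    then by tissue class.
    """
    cfg = _load_default_params()
    if table is None:
        table = default_label_table()
    if n_per_group is None:
        n_per_group = dict(cfg["n_per_group"])
    head_mean = float(cfg["head_size"]["mean"])
    size_fraction = float(cfg["size_fraction"])
    offset_scale = cfg["group_offset_scale"]
    sd_scale = cfg["group_sd_scale"]
    tissue_defaults = cfg["tissue_defaults"]
    baseline_volumes = cfg.get("baseline_volumes", {})
    overrides = cfg.get("structure_overrides", {})
    atrophy_cfg = cfg["atrophy"]
    ref_age, ref_gender = 75.0, 0.5

    structures = []
    for _, row in table.df.iterrows():
        name = row["structure_name"]
        merged = row["merged_name"]
        tissue = row["tissue_class"]
        td = tissue_defaults[tissue]
        ov = overrides.get(name, {})
        baseline = float(ov.get("baseline", baseline_volumes.get(name, td["baseline"])))
        hc_sd = float(ov.get("hc_sd", td["sd_frac"] * baseline))
        ad_offset = float(ov.get("ad_offset", td["ad_offset_frac"] * baseline))
        c_age = td["age_frac"] * baseline
        c_gender = td["gender_frac"] * baseline
        c_size = size_fraction * baseline / head_mean
        b = baseline - (c_age * ref_age + c_gender * ref_gender + c_size * head_mean)
        offsets = {g: ad_offset * float(offset_scale[g]) for g in GROUPS}
        sds = {g: hc_sd * float(sd_scale[g]) for g in GROUPS}
        if "ad_sd" in ov:
            sds["AD"] = float(ov["ad_sd"])
        atrophy: dict[str, dict[str, tuple[float, float]]] = {}
        for interval, blocks in atrophy_cfg.items():
            per = blocks["by_structure"].get(merged) or blocks["by_tissue"][tissue]
            atrophy[interval] = {g: (float(v[0]), float(v[1])) for g, v in per.items()}
        structures.append(
            StructureParams(
                name=name, b=b, c_age=c_age, c_gender=c_gender, c_size=c_size,
                offsets=offsets, sds=sds, atrophy=atrophy,
            )
        )
    return CohortSpec(
        structures=structures,
        n_per_group=dict(n_per_group),
        age_range=tuple(float(a) for a in cfg["age_range"]),
        p_male=float(cfg["p_male"]),
        head_size_mean=head_mean,
        head_size_sd=float(cfg["head_size"]["sd"]),
        seed=seed,
    )


def _positive_normal(rng, mean: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian draws resampled (not clipped) until strictly positive."""
    values = rng.normal(mean, sd)
    if sd == 0:
        if (values <= 0).any():
            raise ValueError("deterministic non-positive volume; check parameters")
        return values
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = values <= 0
        if not bad.any():
            return values
        values[bad] = rng.normal(np.asarray(mean)[bad] if np.ndim(mean) else mean, sd,
                                 size=int(bad.sum()))
    raise ValueError("could not draw positive volumes; mean too close to zero")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw a cohort from the spec.

    Returns ``(subjects, baseline, followups)``: a subject table with
    columns subject/diagnosis/age/gender/head_size, a subjects x structures
    baseline volume table, and one follow-up volume table per interval.
    The same spec (including its seed) yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for group in spec.groups:
        n = spec.n_per_group[group]
        ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
        genders = (rng.random(n) < spec.p_male).astype(int)
        heads = _positive_normal(
            rng, np.full(n, spec.head_size_mean), spec.head_size_sd
        )
        for a, g, h in zip(ages, genders, heads):
            records.append((group, float(a), int(g), float(h)))
    subjects = pd.DataFrame(records, columns=["diagnosis", "age", "gender", "head_size"])
    subjects.insert(0, "subject", [f"S{i:05d}" for i in range(len(subjects))])

    index = pd.Index(subjects["subject"], name="subject")
    group_masks = {g: (subjects["diagnosis"] == g).to_numpy() for g in spec.groups}
    age = subjects["age"].to_numpy()
    gender = subjects["gender"].to_numpy(float)
    head = subjects["head_size"].to_numpy()
    baseline_cols = {}
    for sp in spec.structures:
        mean = sp.b + sp.c_age * age + sp.c_gender * gender + sp.c_size * head
        values = np.empty(len(subjects))
        for group, mask in group_masks.items():
            mu = mean[mask] + sp.offsets.get(group, 0.0)
            sd = sp.sds.get(group, 0.0)
            values[mask] = _positive_normal(rng, mu, sd)
        baseline_cols[sp.name] = values
    baseline = pd.DataFrame(baseline_cols, index=index)

    followups: dict[str, pd.DataFrame] = {}
    for interval in spec.intervals:
        follow_cols = {}
        for sp in spec.structures:
            rates = np.zeros(len(subjects))
            per_group = sp.atrophy.get(interval, {})
            for group, mask in group_masks.items():
                mu, sd = per_group.get(group, (0.0, 0.0))
                rates[mask] = rng.normal(mu, sd, size=int(mask.sum()))
            follow_cols[sp.name] = baseline_cols[sp.name] * np.exp(rates / 100.0)
        followups[interval] = pd.DataFrame(follow_cols, index=index)
    return subjects, baseline, followups


def cohort_to_long(
    baseline: pd.DataFrame, followups: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Stack wide baseline/follow-up tables into long volume records."""
    frames = []
    for visit, wide in [("bl", baseline)] + sorted(followups.items()):
        long = wide.reset_index().melt(
            id_vars="subject", var_name="structure", value_name="volume_mm3"
        )
        long.insert(1, "visit", visit)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def generate_label_maps(
    volumes: pd.Series,
    table: LabelTable,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelMap:
    """Pack requested per-structure volumes into a toy label map.

    Each structure occupies a contiguous block of voxels in raster order;
    the per-label voxel count times the voxel volume matches the requested
    volume to within one voxel volume.  Background is 0.
    """
    voxel_volume = float(np.prod(spacing))
    name_to_id = {n: i for i, n in zip(table.df["label_id"], table.df["structure_name"])}
    unknown = [n for n in volumes.index if n not in name_to_id]
    if unknown:
        raise ValueError(f"structures not in label table: {unknown}")
    counts = {}
    for name, vol in volumes.items():
        if vol < 0:
            raise ValueError(f"negative volume requested for {name}")
        if vol == 0:
            continue
        if vol < voxel_volume:
            raise ValueError(
                f"{name}: requested volume {vol} below one voxel ({voxel_volume})"
            )
        counts[name] = int(round(vol / voxel_volume))
    total = sum(counts.values())
    grid = int(np.prod(shape))
    if total > grid:
        raise ValueError(
            f"grid of {grid} voxels too small for {total} requested voxels"
        )
    flat = np.zeros(grid, dtype=np.int16)
    cursor = 0
    for name, count in counts.items():
        flat[cursor : cursor + count] = name_to_id[name]
        cursor += count
    return LabelMap(flat.reshape(shape), tuple(float(s) for s in spacing))
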