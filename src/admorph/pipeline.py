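"""End-to-end orchestration: simulate (or load), correct, compare, report.

``run_all`` chains every stage and writes report tables shaped like the
published summary tables: baseline group comparisons with per-feature LDA
and all-feature SVM/RF metrics, volume-change summaries with trial sample
sizes (uncorrected and normal-aging-corrected), longitudinal group
comparisons per follow-up interval, and a nuisance-correction ablation
grid.  All randomness derives from one config seed through named stage
seeds, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atrophy as atr
from . import classify as clf
from . import stats as gstats
from .cohort import stratify
from .features import COVARIATE_FEATURES, FeatureMatrix, build_feature_matrix
from .labels import LabelTable, default_label_table, load_label_table
from .nuisance import DEFAULT_EXEMPT, fit_nuisance_model, apply_correction
from .synthetic import cohort_to_long, default_cohort_spec, generate_cohort
from .volumetry import load_volume_csv, volumes_to_wide, write_volume_csv

log = logging.getLogger("admorph")

#: structures reported in the volume-change / sample-size table
RATE_REPORT_FEATURES = [
    "Hippocampus", "InfLatVent", "LateralVentricle", "MTG",
    "BrainTissue", "Ventricles", "WhiteMatter", "CorticalGreyMatter",
    "DeepGreyMatter",
]
#: structures in the correction-ablation grid
ABLATION_FEATURES = [
    "Ventricles", "CorticalGreyMatter", "Amygdala", "Hippocampus",
    "EntA", "InfLatVent", "ITG", "MTG",
]
ABLATION_VARIANTS = {
    "none": (),
    "age": ("age",),
    "brain_size": ("size",),
    "gender": ("gender",),
    "all": ("age", "gender", "size"),
}
SURROGATE_REPORT = [
    "BrainTissue", "CorticalGreyMatter", "Ventricles",
    "WhiteMatter", "DeepGreyMatter", "Brain",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    outdir: str = "admorph_out"
    seed: int = 0
    # input paths; when None a synthetic cohort is generated
    volumes_csv: str | None = None
    metadata_csv: str | None = None
    label_table: str | None = None
    n_per_group: dict[str, int] | None = None
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("AD", "HC"), ("pMCI", "sMCI")]
    )
    intervals: list[str] = field(default_factory=lambda: ["m12", "m24"])
    bonferroni_m: int | None = None  # default: number of tested features
    n_top: int = 10
    lda_runs: int = 10
    ml_runs: int = 5
    n_folds: int = 6
    effect_fraction: float = 0.25
    power: float = 0.80
    alpha: float = 0.05
    z_convention: str = "paper"
    exempt: list[str] = field(default_factory=lambda: sorted(DEFAULT_EXEMPT))
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in doc:
            doc["contrasts"] = [tuple(c) for c in doc["contrasts"]]
        return cls(**doc)


def stage_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# formatting helpers (report layer only; full precision kept internally)

def _fmt_p(p: float) -> str:
    return "<0.00001" if p < 1e-5 else f"{p:.5f}"


def _fmt_mean_sd(mean: float, sd: float, nd: int = 1) -> str:
    return f"{mean:.{nd}f} ({sd:.{nd}f})"


def comparison_report(
    fm: FeatureMatrix,
    labels: pd.Series,
    group_pos: str,
    group_neg: str,
    cfg: RunConfig,
    seed: int,
    value_decimals: int = 1,
) -> pd.DataFrame:
    """One published-style comparison table: classifiers + per-feature rows.

    All-feature RF/SVM rows first, then the surrogate rows, then the
    ``cfg.n_top`` individual structures with the largest effect sizes, each
    with single-feature LDA metrics, group mean (SD), Cohen's d, p and
    significance codes.
    """
    comp = gstats.compare_groups(fm, labels, group_pos, group_neg, m=cfg.bonferroni_m)
    labels = pd.Series(labels)
    ids = labels.index[labels.isin([group_pos, group_neg])].intersection(fm.data.index)
    y = labels.loc[ids].to_numpy()
    volumetric = [c for c in fm.data.columns if c not in COVARIATE_FEATURES]

    rows = []
    X_all = fm.data.loc[ids, volumetric].to_numpy(float)
    for kind, label in (("rf", "RandomForest (all features)"),
                        ("svm", "SVM (all features)")):
        res = clf.run_cv(
            X_all, y, classifier_kind=kind, n_folds=cfg.n_folds,
            n_runs=cfg.ml_runs, seed=stage_seed(seed, f"{kind}:{group_pos}:{group_neg}"),
            positive_label=group_pos,
        )
        rows.append({
            "structure": label,
            "acc_bacc": f"{res.acc:.0f} ({res.bacc:.0f})",
            "sens": f"{res.sens:.0f}", "spec": f"{res.spec:.0f}",
            "mean_sd_pos": "", "mean_sd_neg": "", "d": "", "p": "", "sig": "",
        })

    surrogates = comp[comp["feature"].isin(SURROGATE_REPORT)]
    individual = comp[~comp["feature"].isin(SURROGATE_REPORT)].head(cfg.n_top)
    for _, r in pd.concat([surrogates, individual]).iterrows():
        res = clf.run_cv(
            fm.data.loc[ids, r["feature"]].to_numpy(float), y,
            classifier_kind="lda", n_folds=cfg.n_folds, n_runs=cfg.lda_runs,
            seed=stage_seed(seed, f"lda:{r['feature']}:{group_pos}:{group_neg}"),
            positive_label=group_pos,
        )
        rows.append({
            "structure": r["feature"],
            "acc_bacc": f"{res.acc:.0f} ({res.bacc:.0f})",
            "sens": f"{res.sens:.0f}", "spec": f"{res.spec:.0f}",
            "mean_sd_pos": _fmt_mean_sd(r["mean_pos"], r["sd_pos"], value_decimals),
            "mean_sd_neg": _fmt_mean_sd(r["mean_neg"], r["sd_neg"], value_decimals),
            "d": f"{r['d']:.3f}",
            "p": _fmt_p(r["p"]),
            "sig": f"{r['sig_raw']} ({r['sig_bonferroni']})",
        })
    return pd.DataFrame(rows)


def rate_report(
    rates: dict[str, pd.DataFrame],
    labels: pd.Series,
    cfg: RunConfig,
    groups: list[str] = ("HC", "sMCI", "pMCI", "AD"),
) -> pd.DataFrame:
    """Volume-change summary plus sample sizes per interval.

    One block per interval: per-group mean (SD) rate rows, then per-group
    uncorrected and HC-corrected sample-size rows, per structure.
    """
    blocks = []
    for interval, rate_df in rates.items():
        cols = [c for c in RATE_REPORT_FEATURES if c in rate_df.columns]
        summary = atr.summarize_atrophy(rate_df[cols], labels, groups=list(groups))
        n_table = atr.sample_size_table(
            summary, healthy_group="HC",
            effect_fraction=cfg.effect_fraction, power=cfg.power,
            alpha=cfg.alpha, z_convention=cfg.z_convention,
        )
        for group in groups:
            sub = summary[summary["group"] == group].set_index("structure")
            blocks.append(
                {"interval": interval, "row": f"{group} rate",
                 **{c: _fmt_mean_sd(sub.loc[c, "mean"], sub.loc[c, "sd"]) for c in cols}}
            )
        for group in [g for g in groups if g != "HC"]:
            sub = n_table[n_table["group"] == group].set_index("structure")
            blocks.append(
                {"interval": interval, "row": f"{group} N (uncor.)",
                 **{c: f"{sub.loc[c, 'n_uncorrected']:.0f}" for c in cols}}
            )
            blocks.append(
                {"interval": interval, "row": f"{group} N (HC-cor.)",
                 **{c: f"{sub.loc[c, 'n_corrected']:.0f}" for c in cols}}
            )
    return pd.DataFrame(blocks)


def ablate_corrections(
    fm_raw: FeatureMatrix,
    control_ids,
    labels: pd.Series,
    group_pos: str,
    group_neg: str,
    cfg: RunConfig,
    seed: int,
    structures: list[str] | None = None,
    variants: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Ablation grid: per correction variant x structure, LDA bACC and d.

    Variant ``none`` uses the raw features (identical to skipping the
    nuisance stage); each other variant refits the control regression on
    its covariate subset before correcting.
    """
    if structures is None:
        structures = [s for s in ABLATION_FEATURES if s in fm_raw.data.columns]
    if variants is None:
        variants = ABLATION_VARIANTS
    unknown = set(variants) - set(ABLATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")
    labels = pd.Series(labels)
    ids = labels.index[labels.isin([group_pos, group_neg])].intersection(fm_raw.data.index)
    y = labels.loc[ids].to_numpy()
    rows = []
    for variant, covs in variants.items():
        if covs:
            model = fit_nuisance_model(fm_raw, control_ids, covariates=covs)
            fm = apply_correction(fm_raw, model, exempt=set(cfg.exempt))
        else:
            fm = fm_raw
        row: dict[str, str] = {"correction": variant}
        for structure in structures:
            x_pos = fm.data.loc[ids[y == group_pos], structure]
            x_neg = fm.data.loc[ids[y == group_neg], structure]
            d = gstats.cohens_d(x_pos, x_neg)
            res = clf.run_cv(
                fm.data.loc[ids, structure].to_numpy(float), y,
                classifier_kind="lda", n_folds=cfg.n_folds, n_runs=cfg.lda_runs,
                seed=stage_seed(seed, f"ablate:{variant}:{structure}"),
                positive_label=group_pos,
            )
            row[structure] = f"{res.bacc:.0f} ({d:.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def _load_inputs(cfg: RunConfig, table: LabelTable):
    """Either load user CSVs or generate the default synthetic cohort."""
    if cfg.volumes_csv is not None:
        if cfg.metadata_csv is None:
            raise ValueError("volumes_csv given without metadata_csv")
        volumes = load_volume_csv(cfg.volumes_csv)
        subjects = pd.read_csv(cfg.metadata_csv)
        required = {"subject", "diagnosis", "age", "gender"}
        missing = required - set(subjects.columns)
        if missing:
            raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
        baseline = volumes_to_wide(volumes, visit="bl")
        followups = {
            v: volumes_to_wide(volumes, visit=v)
            for v in volumes["visit"].unique() if v != "bl"
        }
        return subjects, baseline, followups, volumes
    spec = default_cohort_spec(
        n_per_group=cfg.n_per_group, seed=stage_seed(cfg.seed, "simulate"), table=table
    )
    subjects, baseline, followups = generate_cohort(spec)
    volumes = cohort_to_long(baseline, followups)
    return subjects, baseline, followups, volumes


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of everything written."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level)
    outputs: dict[str, Path] = {}

    def emit(name: str, fname: str, df: pd.DataFrame, sep: str = "\t") -> None:
        path = outdir / fname
        df.to_csv(path, sep=sep, index=False)
        outputs[name] = path
        log.info("wrote %s (%d rows)", path, len(df))

    try:
        table = (
            load_label_table(cfg.label_table) if cfg.label_table
            else default_label_table()
        )
        log.info("label table: %d labels", len(table.df))
        subjects, baseline, followups, volumes = _load_inputs(cfg, table)
        followups = {k: v for k, v in followups.items() if k in cfg.intervals}
        log.info("cohort: %d subjects, intervals %s",
                 len(subjects), sorted(followups))
        labels = subjects.set_index("subject")["diagnosis"]

        # validate contrasts before any expensive stage
        for pos, neg in cfg.contrasts:
            for g in (pos, neg):
                n_g = int((labels == g).sum())
                if n_g < cfg.n_folds:
                    raise ValueError(
                        f"contrast group {g!r} has {n_g} subjects, fewer than "
                        f"{cfg.n_folds} folds"
                    )

        emit("subjects", "subjects.csv", subjects, sep=",")
        path = outdir / "volumes.csv"
        write_volume_csv(volumes, path)
        outputs["volumes"] = path

        fm_raw = build_feature_matrix(baseline, table, subjects, visit="bl")
        control_ids = labels.index[labels == "HC"]
        model = fit_nuisance_model(fm_raw, control_ids)
        fm_cor = apply_correction(fm_raw, model, exempt=set(cfg.exempt))
        model.write_csv(outdir / "nuisance_model.csv")
        outputs["nuisance_model"] = outdir / "nuisance_model.csv"
        fm_raw.write_csv(outdir / "features_bl_raw.csv")
        fm_cor.write_csv(outdir / "features_bl_corrected.csv")
        outputs["features_raw"] = outdir / "features_bl_raw.csv"
        outputs["features_corrected"] = outdir / "features_bl_corrected.csv"

        for pos, neg in cfg.contrasts:
            rep = comparison_report(
                fm_cor, labels, pos, neg, cfg, seed=stage_seed(cfg.seed, f"bl:{pos}{neg}")
            )
            emit(f"baseline_{pos}_vs_{neg}", f"baseline_{pos}_vs_{neg}.tsv", rep)

        # longitudinal: rates on raw merged/surrogate features
        fm_follow = {
            v: build_feature_matrix(wide, table, subjects, visit=v)
            for v, wide in followups.items()
        }
        volumetric = [c for c in fm_raw.data.columns if c not in COVARIATE_FEATURES]
        rates = {
            v: atr.rates_from_volumes(fm_raw.data[volumetric], fmv.data[volumetric])
            for v, fmv in fm_follow.items()
        }
        if rates:
            emit("rates_sample_sizes", "rates_sample_sizes.tsv",
                 rate_report(rates, labels, cfg))
            for v, rate_df in rates.items():
                rate_fm = FeatureMatrix(rate_df, status="raw", visit=v)
                for pos, neg in cfg.contrasts:
                    rep = comparison_report(
                        rate_fm, labels, pos, neg, cfg,
                        seed=stage_seed(cfg.seed, f"{v}:{pos}{neg}"),
                    )
                    emit(f"longitudinal_{v}_{pos}_vs_{neg}",
                         f"longitudinal_{v}_{pos}_vs_{neg}.tsv", rep)

        grid = ablate_corrections(
            fm_raw, control_ids, labels, cfg.contrasts[0][0], cfg.contrasts[0][1],
            cfg, seed=stage_seed(cfg.seed, "ablation"),
        )
        emit("correction_ablation", "correction_ablation.tsv", grid)
        log.info("run complete: %d outputs", len(outputs))
        return outputs
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


__all__ = [
    "RunConfig", "run_all", "comparison_report", "rate_report",
    "ablate_corrections", "stage_seed", "stratify",
]
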