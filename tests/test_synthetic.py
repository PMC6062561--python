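"""Synthetic cohort generator: determinism, configured-vs-empirical, maps."""

import numpy as np
import pandas as pd
import pytest

from admorph.stats import cohens_d
from admorph.synthetic import (
    CohortSpec,
    StructureParams,
    default_cohort_spec,
    generate_cohort,
    generate_label_maps,
)
from admorph.volumetry import compute_label_volumes


def one_structure_spec(name="Amygdala", offsets=None, sds=None, n=100, seed=0, **kw):
    sp = StructureParams(
        name=name, b=kw.pop("b", 2260.0),
        offsets=offsets or {"HC": 0.0, "AD": -452.0},
        sds=sds or {"HC": 250.5, "AD": 332.0},
        **kw,
    )
    groups = set(sp.offsets) | set(sp.sds)
    return CohortSpec([sp], {g: n for g in groups}, seed=seed, intervals=())


class TestSpecValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            one_structure_spec(sds={"HC": -1.0, "AD": 1.0})

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n_per_group"):
            one_structure_spec(n=1)

    def test_unknown_group_rejected(self):
        sp = StructureParams(name="A", b=100.0, offsets={"XX": 0.0}, sds={"XX": 1.0})
        with pytest.raises(ValueError, match="unknown group"):
            CohortSpec([sp], {"XX": 10})

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="p_male"):
            CohortSpec(
                [StructureParams(name="A", b=1.0, offsets={"HC": 0.0}, sds={"HC": 0.0})],
                {"HC": 5}, p_male=1.5,
            )

    def test_degenerate_covariates_warn(self):
        sp = StructureParams(name="A", b=100.0, offsets={"HC": 0.0}, sds={"HC": 1.0})
        with pytest.warns(UserWarning, match="age range"):
            CohortSpec([sp], {"HC": 5}, age_range=(70.0, 70.0))
        with pytest.warns(UserWarning, match="p_male"):
            CohortSpec([sp], {"HC": 5}, p_male=1.0)


def test_seed_determinism():
    spec = one_structure_spec(seed=11)
    out1 = generate_cohort(spec)
    out2 = generate_cohort(one_structure_spec(seed=11))
    for a, b in zip(out1[:2], out2[:2]):
        pd.testing.assert_frame_equal(a, b)
    out3 = generate_cohort(one_structure_spec(seed=12))
    assert not out1[1].equals(out3[1])


def test_pure_size_structure_equals_head_size():
    """c_size=1, no offsets/noise: every volume is exactly the head size."""
    sp = StructureParams(
        name="A", b=0.0, c_size=1.0, offsets={"HC": 0.0}, sds={"HC": 0.0},
    )
    spec = CohortSpec([sp], {"HC": 20}, seed=3, intervals=())
    subjects, baseline, _ = generate_cohort(spec)
    assert np.array_equal(baseline["A"].to_numpy(), subjects["head_size"].to_numpy())


def test_amygdala_effect_size_matches_published_parameters():
    """Offsets/SDs from the printed AD-vs-HC amygdala row -> d ~= 1.561."""
    spec = one_structure_spec(n=10000, seed=21)
    subjects, baseline, _ = generate_cohort(spec)
    ad = baseline.loc[(subjects["diagnosis"] == "AD").to_numpy(), "Amygdala"]
    hc = baseline.loc[(subjects["diagnosis"] == "HC").to_numpy(), "Amygdala"]
    assert cohens_d(ad, hc) == pytest.approx(1.561, abs=0.05)


def test_configured_group_moments_recovered_at_large_n():
    spec = one_structure_spec(n=10000, seed=8)
    subjects, baseline, _ = generate_cohort(spec)
    sp = spec.structures[0]
    for group in ("HC", "AD"):
        x = baseline.loc[(subjects["diagnosis"] == group).to_numpy(), "Amygdala"]
        se = sp.sds[group] / np.sqrt(len(x))
        assert abs(x.mean() - (sp.b + sp.offsets[group])) < 3 * se
        assert x.std(ddof=1) == pytest.approx(sp.sds[group], rel=0.05)


def test_configured_atrophy_rates_recovered():
    """Mean log rates converge to the configured group means (LLN)."""
    sp = StructureParams(
        name="Hippocampus", b=6500.0,
        offsets={"HC": 0.0, "AD": -1100.0}, sds={"HC": 300.0, "AD": 300.0},
        atrophy={"m12": {"HC": (-1.1, 1.7), "AD": (-4.8, 3.7)}},
    )
    spec = CohortSpec([sp], {"HC": 5000, "AD": 5000}, seed=9, intervals=("m12",))
    subjects, baseline, followups = generate_cohort(spec)
    rates = 100 * np.log(followups["m12"]["Hippocampus"] / baseline["Hippocampus"])
    for group, mu in (("HC", -1.1), ("AD", -4.8)):
        got = rates[(subjects["diagnosis"] == group).to_numpy()].mean()
        assert got == pytest.approx(mu, abs=0.1)


def test_volumes_always_positive():
    """Means near zero still yield positive draws via resampling."""
    sp = StructureParams(name="Tiny", b=30.0, offsets={"HC": 0.0}, sds={"HC": 40.0})
    spec = CohortSpec([sp], {"HC": 2000}, seed=13, intervals=("m12",))
    subjects, baseline, followups = generate_cohort(spec)
    assert (baseline["Tiny"] > 0).all()
    assert (followups["m12"]["Tiny"] > 0).all()


def test_default_spec_covers_label_table(table):
    spec = default_cohort_spec(n_per_group={"HC": 4, "AD": 4}, seed=0, table=table)
    assert {sp.name for sp in spec.structures} == set(table.df["structure_name"])
    subjects, baseline, followups = generate_cohort(spec)
    assert baseline.shape == (8, 138)
    assert set(followups) == {"m12", "m24"}
    assert (baseline > 0).all().all()


def test_spec_yaml_round_trip(tmp_path):
    spec = one_structure_spec(seed=5)
    spec.to_yaml(tmp_path / "spec.yaml")
    back = CohortSpec.from_yaml(tmp_path / "spec.yaml")
    out1 = generate_cohort(spec)
    out2 = generate_cohort(back)
    pd.testing.assert_frame_equal(out1[1], out2[1])


class TestLabelMaps:
    def test_exact_voxel_count(self, toy_table):
        vols = pd.Series({"SomeVentricle": 80.0})
        lm = generate_label_maps(vols, toy_table, (8, 8, 8), (2.0, 2.0, 2.0))
        assert (lm.data == 3).sum() == 10  # 80 mm^3 / 8 mm^3

    def test_round_trip_volumetry(self, toy_table, rng):
        vols = pd.Series(
            {"LeftThing": 123.0, "RightThing": 140.0, "SomeVentricle": 57.5,
             "SomeWM": 301.0}
        )
        spacing = (1.5, 1.0, 1.0)
        lm = generate_label_maps(vols, toy_table, (12, 12, 12), spacing)
        voxel = float(np.prod(spacing))
        out = compute_label_volumes(lm, toy_table).set_index("structure")["volume_mm3"]
        for name, requested in vols.items():
            assert abs(out[name] - requested) <= voxel

    def test_labels_form_contiguous_blocks(self, toy_table):
        vols = pd.Series({"LeftThing": 10.0, "SomeWM": 12.0})
        lm = generate_label_maps(vols, toy_table, (3, 3, 3), (1.0, 1.0, 1.0))
        flat = lm.data.ravel()
        nz = flat[flat > 0]
        # runs of a single label, no interleaving
        changes = np.sum(nz[1:] != nz[:-1])
        assert changes == len(np.unique(nz)) - 1

    def test_empty_request_gives_all_zero(self, toy_table):
        lm = generate_label_maps(pd.Series(dtype=float), toy_table, (4, 4, 4))
        assert (lm.data == 0).all()

    def test_grid_too_small_is_error(self, toy_table):
        with pytest.raises(ValueError, match="too small"):
            generate_label_maps(pd.Series({"SomeWM": 1000.0}), toy_table, (2, 2, 2))

    def test_subvoxel_request_is_error(self, toy_table):
        with pytest.raises(ValueError, match="below one voxel"):
            generate_label_maps(
                pd.Series({"SomeWM": 1.0}), toy_table, (4, 4, 4), (2.0, 2.0, 2.0)
            )
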