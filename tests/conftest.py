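import numpy as np
import pandas as pd
import pytest

from admorph.labels import LabelTable, default_label_table
from admorph.synthetic import CohortSpec, StructureParams, generate_cohort


@pytest.fixture(scope="session")
def table():
    return default_label_table()


@pytest.fixture(scope="session")
def toy_table():
    """Four labels: one paired deep-GM pair, one ventricle, one WM label."""
    df = pd.DataFrame(
        {
            "label_id": [1, 2, 3, 4],
            "structure_name": ["LeftThing", "RightThing", "SomeVentricle", "SomeWM"],
            "merged_name": ["Thing", "Thing", "SomeVentricle", "SomeWM"],
            "hemisphere": ["left", "right", "none", "none"],
            "tissue_class": ["deep_gm", "deep_gm", "ventricle_csf", "wm"],
            "paired_partner": ["RightThing", "LeftThing", "", ""],
            "in_features": [True, True, True, True],
        }
    )
    return LabelTable(df)


def make_spec(structures, n_per_group, seed=0, **kwargs):
    return CohortSpec(structures=structures, n_per_group=n_per_group, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def hc_ad_cohort():
    """Small two-structure cohort with covariate dependence, both groups."""
    structures = [
        StructureParams(
            name="Hippo", b=1000.0, c_age=-8.0, c_gender=50.0, c_size=2e-3,
            offsets={"HC": 0.0, "AD": -600.0}, sds={"HC": 300.0, "AD": 360.0},
            atrophy={"m12": {"HC": (-1.1, 1.7), "AD": (-4.8, 3.7)}},
        ),
        StructureParams(
            name="Vent", b=2000.0, c_age=100.0, c_gender=200.0, c_size=8e-3,
            offsets={"HC": 0.0, "AD": 8000.0}, sds={"HC": 4000.0, "AD": 5000.0},
            atrophy={"m12": {"HC": (2.8, 3.0), "AD": (7.2, 4.6)}},
        ),
    ]
    spec = make_spec(structures, {"HC": 150, "AD": 150}, seed=42, intervals=("m12",))
    subjects, baseline, followups = generate_cohort(spec)
    return spec, subjects, baseline, followups


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
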