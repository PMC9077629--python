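import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import insuladiv as iv

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_gd_csv(tmp_path):
    """Minimal three-study GD table: one passing unit, two failing ones."""
    path = tmp_path / "gd.csv"
    path.write_text(
        "study,taxon,pop,insular,metric,value\n"
        "A,birds,p1,0,heterozygosity,0.61\n"
        "A,birds,p2,0,heterozygosity,0.58\n"
        "A,birds,p3,1,heterozygosity,0.40\n"
        "B,fish,p1,0,heterozygosity,0.52\n"
        "B,fish,p2,1,heterozygosity,0.47\n"
        "C,plants,p1,0,heterozygosity,0.70\n"
        "C,plants,p2,0,heterozygosity,0.72\n"
        "C,plants,p3,0,heterozygosity,0.68\n"
    )
    return path


@pytest.fixture
def schema_config():
    return {
        "gd_columns": {
            "study_id": "study",
            "taxon_group": "taxon",
            "population_id": "pop",
            "insular": "insular",
            "metric_type": "metric",
            "value": "value",
        }
    }


@pytest.fixture
def synth_null_recordset():
    cfg = iv.SynthConfig(regime="null", seed=11)
    rs, truth = iv.generate_metadataset(cfg)
    return rs, truth


def random_points(rng, n=12, taxon=False, seed_sigma=1.0):
    """Random paired-point frame on the post-shift scale (x, y >= 1)."""
    x = rng.uniform(1.0, 5.0, n)
    y = 0.5 + 0.8 * x + rng.normal(0.0, seed_sigma, n)
    y = y - y.min() + 1.0
    taxa = rng.choice(["birds", "fish", "plants"], n) if taxon else [""] * n
    return pd.DataFrame({"x": x, "y": y, "taxon_group": taxa})


@pytest.fixture
def points_factory(rng):
    def make(n=12, taxon=False, sigma=1.0):
        return random_points(rng, n=n, taxon=taxon, seed_sigma=sigma)

    return make
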