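import numpy as np
import pandas as pd
import pytest

from gpbreed import MultiTraitGBLUP, SyntheticScenario, TraitSpec
from gpbreed.normalization import GoalNormalizer
from gpbreed.synthetic_data import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """40 inbred founders x 100 mapped markers on 2 chromosomes, 2 traits."""
    scenario = SyntheticScenario(
        n_founders=40, n_chromosomes=2, markers_per_chrom=50, seed=3
    )
    geno, lmap, founders, phenos, tbv = generate_dataset(scenario)
    return {
        "scenario": scenario,
        "geno": geno,
        "lmap": lmap,
        "founders": founders,
        "phenos": phenos,
        "tbv": tbv,
    }


@pytest.fixture(scope="session")
def two_trait_specs():
    return [
        TraitSpec("trait1", "larger", index_weight=0.6),
        TraitSpec("trait2", "smaller", index_weight=0.4),
    ]


@pytest.fixture(scope="session")
def fitted_model(small_dataset, two_trait_specs):
    normalizer = GoalNormalizer(two_trait_specs).fit(small_dataset["phenos"])
    W = normalizer.transform(small_dataset["phenos"])
    model = MultiTraitGBLUP().fit(small_dataset["geno"], W)
    return {"model": model, "normalizer": normalizer, "W": W}
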