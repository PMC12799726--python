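import numpy as np
import pandas as pd
import pytest

import wheatqg as w


def make_obs(records):
    """Long-format observation table from (genotype, year, treatment, rep,
    trait, value) tuples."""
    return pd.DataFrame(
        records, columns=["genotype", "year", "treatment", "rep", "trait", "value"]
    )


@pytest.fixture(scope="session")
def single_trait_trial():
    """Ng=200 trial with known components (10, 2, 3, 4), one fixed seed."""
    design = w.TrialDesign(n_genotypes=200, trait_names=("X",))
    truth = w.TrueComponents.diagonal(
        1, mu=50.0, sigma2_g=10.0, sigma2_gy=2.0, sigma2_gt=3.0, sigma2_e=4.0
    )
    obs = w.simulate_trial(design, truth, seed=11)
    return design, truth, obs


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """Small self-consistent phenotype + marker fixture with ground truth."""
    import json

    directory = tmp_path_factory.mktemp("demo")
    paths = w.make_demo_dataset(directory, n_genotypes=60, n_markers=300, seed=7)
    with open(paths["truth"]) as fh:
        truth = json.load(fh)
    return paths, truth
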