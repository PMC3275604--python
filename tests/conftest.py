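import warnings

import numpy as np
import pandas as pd
import pytest

import raidnet as rn
import raidnet.association as assoc


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default design (seed 7)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rn.generate_dataset(rn.PopulationConfig(seed=7))


@pytest.fixture(scope="session")
def focal_features(default_dataset):
    """(features, attributes, matrix, ranks, network) on the filtered males."""
    ds = default_dataset
    matrix = assoc.build_association_matrix(ds.sightings, ds.attributes)
    focal = assoc.filter_focal_males(matrix)
    matrix = matrix.subset(focal)
    ranks = assoc.rank_associates(matrix)
    attributes = ds.attributes[ds.attributes["male_id"].isin(focal)].reset_index(drop=True)
    network = assoc.build_top_k_network(ranks, matrix, k=2, attributes=attributes)
    features = assoc.make_features(ranks, attributes, k=5)
    return features, attributes, matrix, ranks, network


def toy_sightings(groups):
    """Long-format sightings table from a list of member iterables."""
    rows = [
        (f"S{k:03d}", "2006-07-01", m)
        for k, members in enumerate(groups)
        for m in members
    ]
    return pd.DataFrame(rows, columns=["sighting_id", "date", "male_id"])


def toy_attributes(ids, ages=None, raiders=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "male_id": list(ids),
            "age_years": list(ages) if ages is not None else [20] * n,
            "raider": list(raiders) if raiders is not None else [0] * n,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
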