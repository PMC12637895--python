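import datetime as dt

import dendropy
import numpy as np
import pandas as pd
import pytest

from dielact.grid import SSCYSample


@pytest.fixture(scope="session")
def toy_tree() -> dendropy.Tree:
    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def bm_tree64():
    """64-tip unit-height tree with its Brownian covariance factor."""
    from dielact.phylo import phylo_vcv
    from dielact.synthetic import simulate_phylogeny_and_traits

    tree, _ = simulate_phylogeny_and_traits(64, seed=11)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    C = phylo_vcv(tree, taxa)
    L = np.linalg.cholesky(C)
    return tree, taxa, C, L


@pytest.fixture
def occurrence_csv(tmp_path):
    """Factory writing a small occurrence CSV and returning its path."""

    def make(rows: list[dict]) -> str:
        defaults = {
            "id": "x",
            "species": "Pieris rapae",
            "eventDateTime": "2020-06-15T18:00:00+00:00",
            "decimalLatitude": 40.0,
            "decimalLongitude": -90.0,
            "lifeStage": "adult",
            "project": "",
        }
        frame = pd.DataFrame([{**defaults, **r} for r in rows])
        path = tmp_path / "occ.csv"
        frame.to_csv(path, index=False)
        return str(path)

    return make


@pytest.fixture
def sample_factory():
    def make(hours, species="Pieris rapae", season="summer", cell=(2, 3), year=2020):
        return SSCYSample(species, season, cell, year, tuple(int(h) for h in hours))

    return make


@pytest.fixture
def utc():
    def make(y, m, d, h, minute=0):
        return dt.datetime(y, m, d, h, minute, tzinfo=dt.timezone.utc)

    return make
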