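import numpy as np
import pandas as pd
import pytest

from preyscale.data_io import TraitTable
from preyscale.treekit import Phylogeny


def make_frame(n=8, seed=0, zero_range_rows=()):
    """Small valid canonical trait frame; selected rows get prey_min == prey_max."""
    rng = np.random.default_rng(seed)
    genera = [f"G{i:02d}" for i in range(n)]
    prey_min = np.round(10.0 ** rng.uniform(-3, 1, n), 6)
    prey_max = np.round(prey_min * 10.0 ** rng.uniform(0.5, 2, n), 6)
    for i in zero_range_rows:
        prey_max[i] = prey_min[i]
    return pd.DataFrame(
        {
            "species": [f"{g}_sp{i}" for i, g in enumerate(genera)],
            "order": [f"O{i // 4}" for i in range(n)],
            "family": [f"F{i // 2}" for i in range(n)],
            "genus": genera,
            "environment": ["aquatic" if i % 2 else "terrestrial" for i in range(n)],
            "predator_mass": np.round(10.0 ** rng.uniform(-1, 3, n), 6),
            "prey_min": prey_min,
            "prey_max": prey_max,
        }
    )


@pytest.fixture
def small_frame():
    return make_frame(n=8, seed=1)


@pytest.fixture
def small_table(small_frame):
    return TraitTable.from_frame(small_frame)


@pytest.fixture
def toy_tree():
    # ((A,B),C) with depths 2 everywhere
    return Phylogeny.from_newick("((A_a:1,B_b:1):1,C_c:2);")


@pytest.fixture
def trichotomy():
    return Phylogeny.from_newick("(A_a:3,B_b:3,C_c:3);")


def star_tree(labels, depth=1.0):
    return Phylogeny.from_newick(
        "(" + ",".join(f"{l}:{depth}" for l in labels) + ");"
    )
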