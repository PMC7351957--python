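import numpy as np
import pandas as pd
import pytest

from phylostage import ExpressionTable, SimulationConfig, SpeciesTree


def make_table(species, groups, stages, reps, values=None, seed=0):
    """Small expression table with optional explicit values."""
    cols = pd.MultiIndex.from_tuples(
        [(st, r) for st in stages for r in reps], names=["stage", "replicate"]
    )
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 50.0, size=(len(groups), len(cols)))
    df = pd.DataFrame(values, index=pd.Index(groups, name="group_id"), columns=cols)
    return ExpressionTable(species=species, data=df)


@pytest.fixture
def four_species_stages():
    return {sp: [f"st{i + 1:02d}" for i in range(10)] for sp in ["Anj", "Apj", "Sp", "Lv"]}


@pytest.fixture
def small_config(four_species_stages):
    """Quick hourglass dataset: 4 species x 10 stages, 200 groups."""
    return SimulationConfig(
        seed=11,
        n_groups=200,
        n_replicates=2,
        dropout_rate=0.0,
        stages_per_species=four_species_stages,
    )


@pytest.fixture
def default_tree():
    return SpeciesTree.from_newick("(Anj:1,(Apj:1,(Sp:1,Lv:1):1):1);")
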