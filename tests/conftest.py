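import numpy as np
import pytest

from phyloresist import GeneratorConfig, generate_dataset
from phyloresist.survey import PlotSurvey, SpeciesRecord
from phyloresist.tree import Phylogeny

#: the default synthetic gradient reused across recovery tests
DEFAULT_SEED = 20251021


@pytest.fixture(scope="session")
def default_dataset():
    """Default 16-plot synthetic gradient with ground truth."""
    return generate_dataset(GeneratorConfig(seed=DEFAULT_SEED))


@pytest.fixture()
def three_tip_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def caterpillar_tree():
    # fully pectinate: A,B closest; every further tip adds depth
    return Phylogeny.from_newick(
        "(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);"
    )


def make_plot(plot_id, stage, cover, records, soil=None):
    return PlotSurvey(
        plot_id=plot_id,
        stage=stage,
        invader_cover=cover,
        soil=soil or {},
        records=records,
    )


def rec(species, layer="shrub", count=1, dominance=1.0, hits=1, n_subplots=5):
    return SpeciesRecord(
        species=species, layer=layer, count=count, dominance=dominance,
        subplot_hits=hits, n_subplots=n_subplots,
    )
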