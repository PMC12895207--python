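import dendropy
import numpy as np
import pandas as pd
import pytest

import grassdiv as g


@pytest.fixture(scope="session")
def small_tree() -> g.PhylogeneticTree:
    """20-tip ultrametric Yule tree, depth 10."""
    return g.simulate_tree(20, seed=11, depth=10.0)


@pytest.fixture(scope="session")
def small_traits(small_tree) -> g.TraitTable:
    return g.simulate_traits(small_tree, n_traits=6, signal=0.5, seed=12)


def star_tree(n: int, depth: float = 1.0) -> g.PhylogeneticTree:
    nwk = "(" + ",".join(f"T{i}:{depth}" for i in range(n)) + "):0;"
    tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return g.PhylogeneticTree(tree)


@pytest.fixture(scope="session")
def mini_study() -> g.SimulatedStudy:
    """60-species, 5x6-plot study with the default per-category regimes."""
    cfg = g.StudyConfig(
        n_species=60,
        n_plots_per_category={c: 6 for c in g.LAND_USE_CATEGORIES},
        scenarios=g.default_scenarios(richness=10),
        seed=21,
    )
    return g.simulate_study(cfg)


@pytest.fixture(scope="session")
def mini_grafted(mini_study) -> g.GraftedTreeSet:
    """The mini study's tree as a 1-topology grafted set (nothing missing)."""
    return g.GraftedTreeSet([mini_study.tree], [], [], seed=0)


@pytest.fixture(scope="session")
def mini_profile(mini_study, mini_grafted) -> g.DiversityProfile:
    return g.diversity_profile(
        mini_study.community, mini_study.traits, mini_grafted, mini_study.design
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_abundances(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.lognormal(0, 1, size=n)
    a[rng.uniform(size=n) < 0.3] = 0.0
    if a.sum() == 0:
        a[0] = 1.0
    return a
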