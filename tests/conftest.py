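import pytest

import topoess as tp


@pytest.fixture(scope="session")
def quartets():
    """The three unrooted quartet topologies on leaves A-D."""
    t_ab = tp.topology_from_newick("((A,B),(C,D));")
    t_ac = tp.topology_from_newick("((A,C),(B,D));")
    t_ad = tp.topology_from_newick("((A,D),(B,C));")
    return t_ab, t_ac, t_ad


@pytest.fixture(scope="session")
def iid_sample():
    """A chain whose samples are effectively independent draws."""
    return tp.simulate_bimodal(
        tp.BimodalSpec(n_taxa=20, n_samples=400, switch_prob=0.5, seed=123)
    )


@pytest.fixture(scope="session")
def sticky_sample():
    """A strongly autocorrelated chain (1 SPR move per step, 50 taxa)."""
    return tp.simulate_unimodal(
        tp.UnimodalSpec(n_taxa=50, n_samples=400, sprs_per_step=1, seed=42)
    )


@pytest.fixture(scope="session")
def identical_sample():
    """Thirty copies of one topology."""
    t = tp.random_topology(12, seed=5)
    return tp.TreeSample([t] * 30, source="identical")
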