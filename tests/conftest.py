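import numpy as np
import pytest

import nemus as nm


@pytest.fixture(scope="session")
def five_leaf_tree() -> nm.Phylogeny:
    return nm.read_newick("(((A:0.5,B:0.5):0.5,(C:0.6,D:0.4):0.5):1.0,E:2.0);")


@pytest.fixture(scope="session")
def small_profile() -> nm.FitnessProfile:
    return nm.draw_fitness_profile(seed=1234)


def tiny_alignment(tree, profile, codons, seed, **kw):
    cfg = nm.ShiftConfiguration(profile)
    return nm.simulate_alignment(tree, cfg, codons, seed=seed, **kw)
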