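import itertools
import math

import numpy as np
import pytest

from paralogsel.ctmc import TraitModel, transition_matrix
from paralogsel.simulate import TreeSpec, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_tree(n_tips, seed, delta_fraction=None, scale=1.0):
    return simulate_tree(
        TreeSpec(n_tips=n_tips, delta_fraction=delta_fraction, scale=scale), seed=seed
    )


def enumeration_loglik(tree, traits, model: TraitModel) -> float:
    """Brute-force trait likelihood: sum over all ancestral-state assignments.

    Independent of the pruning implementation (explicit products over every
    branch for every joint assignment of internal nodes and unknown tips).
    """
    nodes = tree.nodes
    internals = [n.id for n in nodes if not n.is_tip]
    tips = tree.tips()
    prior = {
        0: model.q10 / (model.q01 + model.q10),
        1: model.q01 / (model.q01 + model.q10),
    }
    if model.root_prior == "uniform":
        prior = {0: 0.5, 1: 0.5}
    tip_states = {
        t: {"0": [0], "1": [1], "unknown": [0, 1]}[traits[nodes[t].label]] for t in tips
    }
    P = {}
    for n in nodes:
        if n.parent is None:
            continue
        loss = model.q10
        if model.q10_delta is not None and n.branch_class in model.delta_classes:
            loss = model.q10_delta
        P[n.id] = transition_matrix(model.q01, loss, n.length)
    total = 0.0
    for internal_assign in itertools.product([0, 1], repeat=len(internals)):
        amap = dict(zip(internals, internal_assign))
        for tip_assign in itertools.product(*[tip_states[t] for t in tips]):
            amap.update(zip(tips, tip_assign))
            p = prior[amap[tree.root]]
            for n in nodes:
                if n.parent is None:
                    continue
                p *= P[n.id][amap[n.parent], amap[n.id]]
            total += p
    return math.log(total)
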