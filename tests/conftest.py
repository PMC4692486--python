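import numpy as np
import pytest

import hopscape as hs


@pytest.fixture
def single_node():
    """Self-coupled single node with unit weight (already unit Frobenius norm)."""
    c = hs.Connectome(np.array([[1.0]]), allow_self_coupling=True)
    return hs.normalize(c)


@pytest.fixture
def two_node():
    """Symmetric 2-node coupling, unit Frobenius norm."""
    c = hs.Connectome(np.array([[0.0, 1.0], [1.0, 0.0]]))
    return hs.normalize(c)


@pytest.fixture
def small_net():
    """30-node modular synthetic connectome, normalized."""
    c = hs.synthetic_connectome(30, n_modules=3, p_intra=0.5, p_inter=0.05, seed=1)
    return hs.normalize(c)


@pytest.fixture
def planted_patterns():
    """Planted-prototype fixture: 4 disjoint 100-node prototypes in 1000
    nodes, 15 noisy copies each with 10% of the active nodes flipped."""
    return make_planted(seed=0)


def make_planted(n_proto=4, n_copies=15, n_total=1000, size=100, flip=0.1, seed=0):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    protos = [frozenset(perm[i * size:(i + 1) * size].tolist())
              for i in range(n_proto)]
    pats = []
    for p in protos:
        plist = sorted(p)
        outside = sorted(set(range(n_total)) - p)
        for _ in range(n_copies):
            k = int(round(flip * size))
            drop = rng.choice(len(plist), k, replace=False)
            add = rng.choice(len(outside), k, replace=False)
            act = (p - {plist[i] for i in drop}) | {outside[i] for i in add}
            pats.append(hs.BinaryPattern(frozenset(act), n_total))
    return protos, pats
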