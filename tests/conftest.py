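import itertools

import numpy as np
import pytest

from crnosc.census import enumerate_complexes
from crnosc.classify import (
    IVANOVA,
    LOTKA,
    LVA,
    NETWORK_4,
    NETWORK_27,
    family12,
    lifted_lva,
)
from crnosc.dynamics import MassActionSystem, positive_equilibria
from crnosc.network import (
    kernel_sign_vector,
    network_from_arrays,
    network_rank,
)


@pytest.fixture(scope="session")
def lotka():
    return LOTKA


@pytest.fixture(scope="session")
def ivanova():
    return IVANOVA


@pytest.fixture(scope="session")
def lva():
    return LVA


@pytest.fixture(scope="session")
def net4():
    return NETWORK_4


@pytest.fixture(scope="session")
def net27():
    return NETWORK_27


@pytest.fixture(scope="session")
def lifted():
    return lifted_lva(1)


@pytest.fixture(scope="session")
def fam12():
    return family12(1, 1)


def random_n32_equilibrium_systems(rng, n, count, max_target_mol=4, max_tries=500000):
    """Random dynamically nontrivial (n, 3, 2) systems together with a
    positive equilibrium (unique for n=2, one point of the family else).

    Yields (system, equilibrium_point).  Used by the stability property
    tests; both positive- and negative-kernel (saddle) systems occur.
    """
    sources = enumerate_complexes(n, 2)
    targets = enumerate_complexes(n, max_target_mol)
    produced = 0
    for _ in range(max_tries):
        if produced >= count:
            return
        srcs = [sources[i] for i in rng.choice(len(sources), 3, replace=False)]
        tgts = []
        ok = True
        for s in srcs:
            cand = [t for t in targets if t != s]
            tgts.append(cand[rng.integers(len(cand))])
        try:
            net = network_from_arrays(srcs, tgts)
        except Exception:
            continue  # some species appears in no complex
        if network_rank(net) != 2:
            continue
        try:
            u = kernel_sign_vector(net)
        except Exception:
            continue
        signs = {(v > 0) - (v < 0) for v in u}
        if signs not in ({1}, {-1}):
            continue
        kappa = tuple(np.exp(rng.uniform(-1.0, 1.0, 3)))
        sys = MassActionSystem(net, kappa)
        eqs = positive_equilibria(sys)
        if eqs.empty:
            continue
        if eqs.unique:
            pt = eqs.point_at()
        else:
            x0 = np.exp(rng.uniform(-0.7, 0.7, n))
            pts = eqs.intersect_class(x0)
            if not pts:
                continue
            pt = pts[0]
        if pt.residual > 1e-8 * max(1.0, float(np.max(sys.monomials(np.array(pt.x))))):
            continue
        produced += 1
        yield sys, pt
    raise RuntimeError(f"could only generate {produced}/{count} systems")
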