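import numpy as np
import pytest

from polembed.system import (AtomSite, ClassicalSystem, ElementParams,
                             FQParameters, MolecularFragment)


@pytest.fixture
def water_params():
    """Plausible-magnitude FQ(Fμ) parameters for O and H (a.u.)."""
    return FQParameters({
        "O": ElementParams(chi=0.52, eta=0.58, alpha=5.8, r_q=1.2, r_mu=0.9),
        "H": ElementParams(chi=0.17, eta=0.625, alpha=2.6, r_q=0.9, r_mu=0.7),
    })


@pytest.fixture
def water_dimer(water_params):
    from polembed.fixtures import make_water_cluster
    frags = make_water_cluster(2, "shell", seed=11, r_min=2.5, r_max=4.5)
    return ClassicalSystem(frags, water_params, kernel="ohno", model="FQ")


def random_small_system(rng: np.random.Generator, kernel: str, model: str
                        ) -> ClassicalSystem:
    """Random 2-6 site system split into 1-2 fragments, unique per-site
    parameters; used for solver-vs-oracle comparisons."""
    n = int(rng.integers(2, 7))
    pos = rng.uniform(-2.5, 2.5, size=(n, 3))
    # enforce pairwise separation >= 1.2 A by resampling clashing sites
    for _ in range(200):
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        bad = np.where(d.min(axis=1) < 1.2)[0]
        if not len(bad):
            break
        pos[bad] = rng.uniform(-2.5, 2.5, size=(len(bad), 3))
    table = {}
    sites = []
    for i in range(n):
        el = f"E{i}"
        table[el] = ElementParams(
            chi=float(rng.uniform(0.05, 0.6)),
            eta=float(rng.uniform(0.4, 0.9)),
            alpha=float(rng.uniform(1.5, 6.0)),
            r_q=float(rng.uniform(0.7, 1.4)),
            r_mu=float(rng.uniform(0.5, 1.1)))
        sites.append(AtomSite(el, pos[i], 1))
    if n >= 4 and rng.random() < 0.6:
        split = int(rng.integers(2, n - 1))
        frags = [MolecularFragment(tuple(sites[:split]),
                                   float(rng.integers(-1, 2))),
                 MolecularFragment(tuple(sites[split:]),
                                   float(rng.integers(-1, 2)))]
    else:
        frags = [MolecularFragment(tuple(sites), float(rng.integers(-1, 2)))]
    return ClassicalSystem(frags, FQParameters(table), kernel=kernel, model=model)
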