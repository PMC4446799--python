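import numpy as np
import pytest

from yrescue import AnalysisConfig
from yrescue.fixtures import load_curated_fixture


@pytest.fixture(scope="session")
def curated():
    """(HomologTable, SpeciesTree, synteny records, evidence records)."""
    return load_curated_fixture()


@pytest.fixture(scope="session")
def tree(curated):
    return curated[1]


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20150528)


def random_ultrametric_newick(labels, rng, max_age=100.0):
    """Random rooted binary ultrametric tree over the given labels."""
    nodes = [(lbl, 0.0) for lbl in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, aa), (nb, ab) = nodes[i], nodes[j]
        age = max(aa, ab) + float(rng.uniform(1.0, 10.0))
        merged = (f"({na}:{age - aa:.6f},{nb}:{age - ab:.6f})", age)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0][0] + ";"
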