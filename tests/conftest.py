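import numpy as np
import pytest

from ecomorph import LandmarkSet, SpecimenRecord
from ecomorph.phylo import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


def make_landmarks(coords, roles=None, prefix="s"):
    """Wrap an (n, k, 2) array as a LandmarkSet with generated ids."""
    coords = np.asarray(coords, float)
    records = [SpecimenRecord(specimen_id=f"{prefix}{i}") for i in range(coords.shape[0])]
    return LandmarkSet(records=records, coords=coords, roles=roles or [])


def random_similarity(rng, scale_range=(0.2, 5.0)):
    """A random rotation / scale / translation, applied as x -> s*x@R + t."""
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    s = rng.uniform(*scale_range)
    t = rng.uniform(-10, 10, size=2)
    return lambda x: s * x @ rot.T + t


def random_tree(rng, n_tips, length_range=(0.2, 2.0)):
    """Random topology by successive pairwise joins, random branch lengths."""
    labels = [f"t{i}" for i in range(n_tips)]
    # node records: (subtree newick, )
    subtrees = [f"{lab}:{rng.uniform(*length_range):.6f}" for lab in labels]
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b}):{rng.uniform(*length_range):.6f}")
    newick = f"({subtrees[0]},{subtrees[1]});"
    return Phylogeny.from_newick(newick)
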