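import itertools

import numpy as np
import pytest

from ankevo import DistanceMatrix, Sequence, make_ankyrin_calpha
from ankevo.tree import Tree


@pytest.fixture(scope="session")
def ankyrin2():
    """Small (2-repeat, 66-residue) ideal ankyrin trace."""
    return make_ankyrin_calpha(2)


@pytest.fixture(scope="session")
def ankyrin7():
    """Full-size (7-repeat, 231-residue) ideal ankyrin trace."""
    return make_ankyrin_calpha(7)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Exact additive distances read off a tree's path lengths."""
    taxa = sorted(tree.leaf_names)
    n = len(taxa)
    pl = tree.path_lengths()
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = taxa[i], taxa[j]
        d[i, j] = d[j, i] = pl[(a, b) if a < b else (b, a)]
    return DistanceMatrix(taxa, d)


def brute_force_global_score(a: str, b: str, mat, gap_open=10.0, gap_extend=0.5):
    """Optimal global alignment score by exhaustive enumeration of every
    gapped alignment (affine gaps: first gap position costs `gap_open`,
    each subsequent one `gap_extend`)."""
    best = [-np.inf]

    def rec(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + float(mat[a[i], b[j]]), "D")
        if i < len(a):
            pen = gap_extend if prev == "U" else gap_open
            rec(i + 1, j, score - pen, "U")
        if j < len(b):
            pen = gap_extend if prev == "L" else gap_open
            rec(i, j + 1, score - pen, "L")

    rec(0, 0, 0.0, None)
    return best[0]
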