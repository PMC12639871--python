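import numpy as np
import pytest

from cahlrs.kb import default_kb
from cahlrs.locus import build_toy_locus
from cahlrs.pipeline import RunConfig
from cahlrs.simulate import ErrorModel, cohort73_specs, table1_specs

ERROR_FREE = ErrorModel(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def locus():
    return build_toy_locus()


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture(scope="session")
def cases12():
    return table1_specs()


@pytest.fixture(scope="session")
def cohort73():
    return cohort73_specs()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


def hap_truth(spec):
    """Truth (variant set, structure, bin) for one HaplotypeSpec."""
    return (frozenset(spec.variants), spec.structure, spec.bin_label)


def python_gotoh(query, ref, match=2, mismatch=-4, gap_open=-6, gap_extend=-1):
    """Independent quadratic-space full-matrix affine-gap glocal DP.

    Score-only oracle for the banded production aligner: the query must be
    fully aligned, reference flanks are free.  A gap of length L costs
    gap_open + gap_extend * L.
    """
    m, n = len(query), len(ref)
    NEG = float("-inf")
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0.0
    for i in range(1, m + 1):
        F[i][0] = gap_open + gap_extend * i
        H[i][0] = F[i][0]
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend,
                          H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend,
                          H[i - 1][j] + gap_open + gap_extend)
            s = match if qi == ref[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(H[m])


def brute_force_changepoint(states):
    """Exhaustive minimum-mismatch single-changepoint search.

    states: list over PSV sites with 1 = GENE, 2 = PSEUDO, 0 = MISSING.
    Returns (leftmost_best_cut, best_cost).
    """
    n = len(states)
    best = None
    for c in range(n + 1):
        cost = sum(1 for i in range(c) if states[i] == 1) \
            + sum(1 for i in range(c, n) if states[i] == 2)
        if best is None or cost < best[1]:
            best = (c, cost)
    return best
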