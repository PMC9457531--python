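import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from orthopath import alignment

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def b62() -> alignment.ScoringMatrix:
    return alignment.blosum62()


@pytest.fixture(scope="session")
def brute_force_local_score():
    """Independent local-alignment oracle by exhaustive enumeration.

    Every local alignment is a strictly increasing set of aligned column
    pairs; between consecutive pairs the skipped residues form one gap
    per sequence (any interleaving opens at least as many gaps, so the
    optimum is attained on these arrangements). Enumerating all pair
    sets therefore yields the exact optimal score for tiny sequences,
    with no dynamic programming involved.
    """
    from itertools import combinations

    def _score(a: str, b: str, matrix: alignment.ScoringMatrix,
               gap_open: int = 11, gap_extend: int = 1) -> int:
        sub = matrix.scores
        ea = alignment.encode(a)
        eb = alignment.encode(b)
        best = 0
        for k in range(1, min(len(a), len(b)) + 1):
            for qi in combinations(range(len(a)), k):
                for sj in combinations(range(len(b)), k):
                    sc = 0
                    for x in range(k):
                        sc += sub[ea[qi[x]], eb[sj[x]]]
                        if x:
                            dq = qi[x] - qi[x - 1] - 1
                            ds = sj[x] - sj[x - 1] - 1
                            if dq:
                                sc -= gap_open + gap_extend * dq
                            if ds:
                                sc -= gap_open + gap_extend * ds
                    if sc > best:
                        best = sc
        return int(best)

    return _score


@pytest.fixture
def rng():
    return np.random.default_rng(0)
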