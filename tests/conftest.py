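import numpy as np
import pytest

from dyndag import (DbnStructure, GroundTruth, TransitionTable,
                    build_score_table, build_transition_table,
                    simulate_cohort, NO_ATTRITION)


def make_truth(n, w_edges=(), b_edges=(), first=None, trans=None, seed=None):
    """Hand-built ground truth; unspecified CPTs are fair coins."""
    W = np.zeros((n, n), dtype=bool)
    B = np.zeros((n, n), dtype=bool)
    for i, j in w_edges:
        W[i, j] = True
    for i, j in b_edges:
        B[i, j] = True
    st = DbnStructure(W, B)
    cpt_first, cpt_trans = [], []
    for j in range(n):
        k1 = len(st.w_parents(j))
        kt = k1 + len(st.b_parents(j))
        f = (first or {}).get(j, np.full(1 << k1, 0.5))
        t = (trans or {}).get(j, np.full(1 << kt, 0.5))
        cpt_first.append(np.asarray(f, dtype=float))
        cpt_trans.append(np.asarray(t, dtype=float))
    return GroundTruth(structure=st, cpt_first=cpt_first, cpt_trans=cpt_trans,
                       seed=seed)


def graded_cpt(kt, lo=0.2, hi=0.8):
    """P(1 | config) rising linearly with the number of active parents."""
    out = []
    for cfg in range(1 << kt):
        bits = [(cfg >> t) & 1 for t in range(kt)]
        out.append(lo + (hi - lo) * (np.mean(bits) if kt else 0.5))
    return np.asarray(out)


@pytest.fixture(scope="session")
def chain3_truth():
    """Three variables, within edge 0->1, strong self-edges everywhere."""
    n = 3
    trans = {}
    st = make_truth(n, w_edges=[(0, 1)], b_edges=[(j, j) for j in range(n)])
    for j in range(n):
        kt = len(st.structure.w_parents(j)) + len(st.structure.b_parents(j))
        trans[j] = graded_cpt(kt)
    return make_truth(n, w_edges=[(0, 1)], b_edges=[(j, j) for j in range(n)],
                      first={1: np.array([0.2, 0.8])}, trans=trans)


@pytest.fixture(scope="session")
def chain3_table(chain3_truth):
    """500 transition rows simulated from the planted chain."""
    panel = simulate_cohort(chain3_truth, n_participants=125, n_waves=5,
                            attrition=NO_ATTRITION, seed=11)
    return build_transition_table(panel)


@pytest.fixture(scope="session")
def chain3_scores(chain3_table):
    return build_score_table(chain3_table, ess=1.0, max_parents=3)


@pytest.fixture(scope="session")
def coin2_table():
    """Two independent coin variables, 30 rows."""
    rng = np.random.default_rng(7)
    return TransitionTable.from_arrays(rng.integers(0, 2, (30, 2)),
                                       rng.integers(0, 2, (30, 2)))
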