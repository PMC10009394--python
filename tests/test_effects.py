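import numpy as np
import pytest

from dyndag import (DagSample, DbnStructure, TransitionTable, all_effects,
                    build_transition_table, do_effect, draw_parameters,
                    effect_distribution, simulate_cohort, NO_ATTRITION)
from dyndag.effects import ParameterDraw

from conftest import make_truth


def brute_force_effect(structure, params, source, target):
    """Independent oracle: sum the full joint of the mutilated 2n-node
    network over all 2^(2n-1) free assignments."""
    n = structure.n
    fams = {}
    for j in range(n):
        fams[j] = ([int(v) for v in structure.w_parents(j)],
                   params.theta_first[j])
        pa2 = [int(v) + n for v in structure.w_parents(j)] \
            + [int(v) for v in structure.b_parents(j)]
        fams[j + n] = (pa2, params.theta_trans[j])
    free = [v for v in range(2 * n) if v != source]
    m = len(free)
    bits = (np.arange(1 << m)[:, None] >> np.arange(m)) & 1
    out = []
    for x in (0, 1):
        col = {v: bits[:, k] for k, v in enumerate(free)}
        col[source] = np.full(1 << m, x)
        joint = np.ones(1 << m)
        for v in free:
            pa, tab = fams[v]
            idx = np.zeros(1 << m, dtype=int)
            for t, p in enumerate(pa):
                idx += col[p] << t
            p1 = tab[idx]
            joint *= np.where(col[v] == 1, p1, 1 - p1)
        out.append(joint[col[target + n] == 1].sum())
    return out[1] - out[0]


def _random_params(structure, rng):
    theta_first, theta_trans = [], []
    for j in range(structure.n):
        k1 = len(structure.w_parents(j))
        kt = k1 + len(structure.b_parents(j))
        theta_first.append(rng.uniform(0.05, 0.95, 1 << k1))
        theta_trans.append(rng.uniform(0.05, 0.95, 1 << kt))
    return ParameterDraw(structure=structure, theta_first=theta_first,
                         theta_trans=theta_trans)


def _random_structure(n, rng, p=0.4):
    order = rng.permutation(n)
    W = np.zeros((n, n), bool)
    for a in range(n):
        for b in range(a + 1, n):
            W[order[a], order[b]] = rng.random() < p
    B = rng.random((n, n)) < p
    return DbnStructure(W, B)


class TestDrawParameters:
    def test_uniform_prior_mean_half(self):
        table = TransitionTable.from_arrays(np.zeros((0, 2), int),
                                            np.zeros((0, 2), int))
        st = DbnStructure.empty(2)
        rng = np.random.default_rng(0)
        draws = [draw_parameters(st, table, ess=2.0, seed=rng).theta_trans[0][0]
                 for _ in range(10_000)]
        assert abs(np.mean(draws) - 0.5) < 0.01

    def test_conjugate_posterior_mean(self):
        # 8 ones, 2 zeros, alpha=0.5 -> mean 8.5/11
        X1 = np.array([[1]] * 8 + [[0]] * 2)
        table = TransitionTable.from_arrays(np.zeros((10, 1), int), X1)
        st = DbnStructure.empty(1)
        rng = np.random.default_rng(1)
        draws = [draw_parameters(st, table, ess=1.0, seed=rng).theta_trans[0][0]
                 for _ in range(10_000)]
        assert abs(np.mean(draws) - 8.5 / 11) < 0.01

    def test_seed_determinism(self, chain3_table, chain3_truth):
        a = draw_parameters(chain3_truth.structure, chain3_table, seed=5)
        b = draw_parameters(chain3_truth.structure, chain3_table, seed=5)
        for x, y in zip(a.theta_trans, b.theta_trans):
            np.testing.assert_array_equal(x, y)


class TestDoEffect:
    def test_lone_edge_contrast(self):
        st = DbnStructure(np.zeros((2, 2), bool),
                          np.array([[False, True], [False, False]]))
        params = ParameterDraw(
            structure=st,
            theta_first=[np.array([0.5]), np.array([0.5])],
            theta_trans=[np.array([0.5]), np.array([0.2, 0.8])])
        assert do_effect(st, params, 0, 1) == pytest.approx(0.6, abs=1e-14)

    def test_nondescendant_effect_is_exactly_zero(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(50):
            st = _random_structure(4, rng, p=0.3)
            params = _random_params(st, rng)
            from dyndag.effects import _slice2_descendants
            desc = _slice2_descendants(st)
            for s in range(4):
                for y in range(4):
                    if not desc[s, y]:
                        assert do_effect(st, params, s, y) == 0.0
                        hits += 1
        assert hits > 0

    def test_confounded_pair_matches_bruteforce(self):
        # Z -> source within slice 1, Z -> target between slices: the
        # back-door path must be left open (Z unclamped)
        W = np.zeros((3, 3), bool)
        W[2, 0] = True  # Z -> source
        B = np.zeros((3, 3), bool)
        B[0, 1] = True  # source_t -> target_{t+1}
        B[2, 1] = True  # Z_t -> target_{t+1}
        st = DbnStructure(W, B)
        rng = np.random.default_rng(3)
        params = _random_params(st, rng)
        got = do_effect(st, params, 0, 1)
        want = brute_force_effect(st, params, 0, 1)
        assert got == pytest.approx(want, abs=1e-12)
        # and differs from the naive conditional contrast in general
        assert abs(got) <= 1.0

    @pytest.mark.parametrize("enum_limit", [20, 0])
    def test_matches_bruteforce_on_random_networks(self, enum_limit):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = int(rng.integers(2, 5))
            st = _random_structure(n, rng)
            params = _random_params(st, rng)
            s, y = int(rng.integers(n)), int(rng.integers(n))
            got = do_effect(st, params, s, y, enum_limit=enum_limit)
            want = brute_force_effect(st, params, s, y)
            assert got == pytest.approx(want, abs=1e-10)

    def test_all_effects_matches_pairwise(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            st = _random_structure(4, rng)
            params = _random_params(st, rng)
            grid = all_effects(st, params)
            for s in range(4):
                for y in range(4):
                    assert grid[s, y] == pytest.approx(
                        do_effect(st, params, s, y), abs=1e-10)

    def test_effects_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            st = _random_structure(5, rng)
            grid = all_effects(st, _random_params(st, rng))
            assert (np.abs(grid) <= 1.0).all()


class TestEffectDistribution:
    def test_degenerate_draws_give_tight_interval(self):
        # one structure repeated, massive counts -> parameter posterior is
        # nearly a point mass, so the interval collapses onto the mean
        truth = make_truth(2, b_edges=[(0, 1)], trans={1: np.array([0.2, 0.8])})
        panel = simulate_cohort(truth, n_participants=20_000, n_waves=2,
                                attrition=NO_ATTRITION, seed=7)
        table = build_transition_table(panel)
        sample = DagSample(structures=[truth.structure] * 100)
        dist = effect_distribution(sample, table, seed=8)
        assert dist.upper[0, 1] - dist.lower[0, 1] < 0.03
        assert dist.mean[0, 1] == pytest.approx(0.6, abs=0.03)
        assert dist.significant[0, 1]
        assert not dist.significant[1, 0]

    def test_mean_within_draw_hull_and_flag_rule(self, chain3_table,
                                                 chain3_scores):
        from dyndag import sample_dags
        sample = sample_dags(chain3_scores, n_samples=200, chain_length=4000,
                             seed=9)
        dist = effect_distribution(sample, chain3_table, seed=10)
        assert (dist.mean >= dist.draws.min(axis=0) - 1e-12).all()
        assert (dist.mean <= dist.draws.max(axis=0) + 1e-12).all()
        np.testing.assert_array_equal(
            dist.significant, (dist.lower > 0) | (dist.upper < 0))
        assert (np.abs(dist.draws) <= 1).all()

    def test_tidy_frame_matches_summaries(self, chain3_table, chain3_scores):
        from dyndag import sample_dags
        sample = sample_dags(chain3_scores, n_samples=50, chain_length=2000,
                             seed=11)
        dist = effect_distribution(sample, chain3_table, seed=12)
        df = dist.to_frame()
        assert len(df) == 9
        row = df[(df.source == "V1") & (df.target == "V2")].iloc[0]
        assert row["mean"] == pytest.approx(dist.mean[0, 1])
        assert row["n_draws"] == 50

    def test_structure_mixture_is_bimodal(self):
        # half the structures carry a mediating within-slice edge at t+1,
        # half do not: the effect draws split into two modes at the exact
        # per-structure effects
        with_med = make_truth(2, w_edges=[(0, 1)], b_edges=[(0, 0)],
                              trans={0: np.array([0.15, 0.85]),
                                     1: np.array([0.2, 0.8])})
        without = make_truth(2, b_edges=[(0, 0)],
                             trans={0: np.array([0.15, 0.85])})
        panel = simulate_cohort(with_med, n_participants=4000, n_waves=2,
                                attrition=NO_ATTRITION, seed=13)
        table = build_transition_table(panel)
        structures = [with_med.structure] * 100 + [without.structure] * 100
        dist = effect_distribution(DagSample(structures=structures), table,
                                   seed=14)
        draws = dist.draws[:, 0, 1]
        mode_a, mode_b = draws[:100].mean(), draws[100:].mean()
        # exact per-structure effects at the posterior-mean parameters
        pa = draw_parameters(with_med.structure, table, seed=15)
        pb = draw_parameters(without.structure, table, seed=16)
        assert mode_a == pytest.approx(do_effect(with_med.structure, pa, 0, 1),
                                       abs=0.05)
        assert mode_b == pytest.approx(do_effect(without.structure, pb, 0, 1),
                                       abs=0.05)
        assert abs(mode_a - mode_b) > 0.2  # two separated modes
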