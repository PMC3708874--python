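"""The six stochastic processes: damage, fusion, fission/exchange,
autophagy, biogenesis, and the windowed rate caps."""

import itertools
from collections import Counter, deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitonet import CellState, exchange_units, replication_rate, validate_params, window_allows
from mitonet.events import autophagy_step, damage_step, fission_step, fusion_step, replicate_step
from mitonet.spatial import ContactGraph


def _state(positions, hu_rows):
    return CellState(np.asarray(positions, float), np.asarray(hu_rows, np.uint8))


# ---------------------------------------------------------------------------
# damage
# ---------------------------------------------------------------------------

class TestDamage:
    def test_zero_rate_is_identity(self, rng):
        state = _state([[5, 5]], [[1] * 10])
        damage_step(state, validate_params().replace(k_damage=0.0), rng)
        assert state.hu.sum() == 10

    def test_mean_health_decays_exponentially(self, rng):
        # damage only: ensemble mean health follows h(0) exp(-k t)
        p = validate_params().replace(k_damage=5e-3)  # faster for a short test
        n, steps = 400, 200
        hu = (rng.random((n, 10)) < 0.5).astype(np.uint8)
        state = _state(rng.uniform(1, 24, size=(n, 2)), hu)
        h0 = state.healths().mean()
        for _ in range(steps):
            damage_step(state, p, rng)
        expected = h0 * np.exp(-p.k_damage * steps)
        se = state.healths().std() / np.sqrt(n)
        assert abs(state.healths().mean() - expected) < 3 * se + 1e-9

    def test_per_mito_mode_damages_one_unit(self, rng):
        p = validate_params().replace(k_damage=1e6, damage_mode="per_mito")
        state = _state([[5, 5]], [[1] * 10])
        damage_step(state, p, rng)
        assert state.hu.sum() == 9  # exactly one unit lost per event


# ---------------------------------------------------------------------------
# exchange at fission
# ---------------------------------------------------------------------------

class TestExchangeUnits:
    @given(
        st.integers(2, 12).flatmap(
            lambda m: st.tuples(
                st.lists(st.booleans(), min_size=m, max_size=m),
                st.lists(st.booleans(), min_size=m, max_size=m),
                st.integers(0, m),
                st.integers(0, 2**31 - 1),
            )
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_conserves_total_healthy_units(self, args):
        a, b, n, seed = args
        a, b = np.array(a, np.uint8), np.array(b, np.uint8)
        a2, b2 = exchange_units(a, b, n, np.random.default_rng(seed))
        assert a2.sum() + b2.sum() == a.sum() + b.sum()
        assert a2.size == b2.size == a.size

    def test_forced_outcome_extreme_parents(self, rng):
        # all-healthy vs all-damaged with n=2 of 10 always yields 0.8 / 0.2
        for _ in range(25):
            a2, b2 = exchange_units(np.ones(10, np.uint8), np.zeros(10, np.uint8), 2, rng)
            assert a2.sum() == 8 and b2.sum() == 2

    def test_overdraw_rejected(self, rng):
        with pytest.raises(ValueError):
            exchange_units(np.ones(10, np.uint8), np.ones(10, np.uint8), 11, rng)

    @staticmethod
    def _enumerate_outcomes(a, b, n):
        """Exhaustive distribution of unordered post-exchange health sums."""
        m = len(a)
        dist = Counter()
        for pa in itertools.combinations(range(m), n):
            for pb in itertools.combinations(range(m), n):
                a2, b2 = a.copy(), b.copy()
                for i, j in zip(pa, pb):
                    a2[i], b2[j] = b2[j], a2[i]
                dist[frozenset(Counter([a2.sum(), b2.sum()]).items())] += 1
        total = sum(dist.values())
        return {k: v / total for k, v in dist.items()}

    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_exchanging_n_equals_exchanging_complement(self, n):
        # brute-force enumeration: swapping n of 6 units matches swapping
        # 6 - n up to relabelling of the two mitochondria
        a = np.array([1, 1, 1, 0, 0, 1], np.uint8)
        b = np.array([0, 1, 0, 0, 1, 0], np.uint8)
        d1 = self._enumerate_outcomes(a, b, n)
        d2 = self._enumerate_outcomes(a, b, 6 - n)
        assert set(d1) == set(d2)
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-12)

    def test_simulated_distribution_matches_enumeration(self, rng):
        # chi-square of simulated outcome frequencies against enumeration
        from scipy.stats import chisquare

        a = np.array([1, 0, 1, 1, 0, 1], np.uint8)
        b = np.array([0, 0, 1, 0, 1, 0], np.uint8)
        expected = self._enumerate_outcomes(a, b, 2)
        draws = Counter()
        n_draws = 4000
        for _ in range(n_draws):
            a2, b2 = exchange_units(a, b, 2, rng)
            draws[frozenset(Counter([a2.sum(), b2.sum()]).items())] += 1
        keys = sorted(expected, key=hash)
        stat, pval = chisquare(
            [draws.get(k, 0) for k in keys], [expected[k] * n_draws for k in keys]
        )
        assert pval > 1e-3


# ---------------------------------------------------------------------------
# fusion / fission
# ---------------------------------------------------------------------------

def _touching_pair(h_a=1.0, h_b=1.0, n_hu=10):
    hu = np.zeros((2, n_hu), np.uint8)
    hu[0, : int(round(h_a * n_hu))] = 1
    hu[1, : int(round(h_b * n_hu))] = 1
    state = _state([[5.0, 5.0], [6.0, 5.0]], hu)
    graph = ContactGraph(np.array([[0, 1]]), np.array([2], np.int8))
    return state, graph


class TestFusion:
    def test_below_threshold_never_fuses(self, rng):
        state, graph = _touching_pair(h_a=0.2)
        p = validate_params().replace(k_fus=1e6)
        for _ in range(50):
            fusion_step(state, graph, p, rng)
        assert not state.bonds

    def test_at_threshold_fuses(self, rng):
        state, graph = _touching_pair(h_a=0.3, h_b=0.3)
        p = validate_params().replace(k_fus=1e6)
        fusion_step(state, graph, p, rng)
        assert state.has_bond(0, 1)

    def test_motility_scaling_of_fusion_probability(self, rng):
        # alpha = 0.5 halves the one-moving fusion probability
        p = validate_params().replace(alpha=0.5, beta=0.25)
        counts = {}
        for cls in (2, 1, 0):
            fused = 0
            trials = 3000
            for k in range(trials):
                state, graph = _touching_pair()
                graph.motility[0] = cls
                fusion_step(state, graph, p, np.random.default_rng(1000 * cls + k))
                fused += bool(state.bonds)
            counts[cls] = fused / trials
        base = -np.expm1(-p.k_fus * p.dt)
        assert counts[2] == pytest.approx(base, rel=0.25)
        assert counts[1] == pytest.approx(0.5 * base, rel=0.25)
        assert counts[0] == pytest.approx(0.25 * base, rel=0.35)


class TestFission:
    def test_zero_rate_keeps_bonds(self, rng):
        state, graph = _touching_pair()
        state.add_bond(0, 1)
        fission_step(state, validate_params().replace(k_fis=0.0), rng)
        assert state.bonds

    def test_conserves_healthy_units_and_unbinds(self, rng):
        p = validate_params().replace(k_fis=1e6, n_exchange=3)
        for seed in range(30):
            local = np.random.default_rng(seed)
            hu = (local.random((2, 10)) < 0.5).astype(np.uint8)
            state = _state([[5.0, 5.0], [6.0, 5.0]], hu)
            state.add_bond(0, 1)
            state.bound[:] = True
            total = state.hu.sum()
            fission_step(state, p, local)
            assert not state.bonds
            assert state.hu.sum() == total
            assert not state.bound.any()  # daughters start unbound

    def test_mean_bond_lifetime_matches_rate(self, rng):
        # a single bond at k_fis = 0.1 lives ~1/k_fis = 10 min
        p = validate_params().replace(k_fis=0.1, n_exchange=0)
        lifetimes = []
        for seed in range(600):
            local = np.random.default_rng(seed)
            state, _ = _touching_pair()
            state.add_bond(0, 1)
            t = 0
            while state.bonds and t < 500:
                fission_step(state, p, local)
                t += 1
            lifetimes.append(t)
        mean = np.mean(lifetimes)
        # discrete-step geometric mean is 1/(1 - exp(-k dt)) = 10.5 steps
        assert mean == pytest.approx(10.5, rel=0.15)


# ---------------------------------------------------------------------------
# autophagy
# ---------------------------------------------------------------------------

class TestAutophagy:
    def test_fused_mitochondria_protected(self, rng):
        state, _ = _touching_pair(h_a=0.0, h_b=0.0)
        state.add_bond(0, 1)
        p = validate_params().replace(k_aut=1e6)
        for _ in range(20):
            autophagy_step(state, p, rng)
        assert state.n == 2

    def test_at_threshold_not_removed(self, rng):
        state, _ = _touching_pair(h_a=0.3, h_b=0.3)
        p = validate_params().replace(k_aut=1e6, h_aut=0.3)
        autophagy_step(state, p, rng)
        assert state.n == 2  # strictly-below rule

    def test_removal_probability_matches_rate(self, rng):
        p = validate_params()
        n = 4000
        state = _state(np.column_stack([np.linspace(1, 999, n), np.full(n, 5.0)]),
                       np.zeros((n, 10), np.uint8))
        autophagy_step(state, p, rng)
        removed = n - state.n
        expect = n * -np.expm1(-p.k_aut * p.dt)
        assert removed == pytest.approx(expect, rel=0.25)

    def test_windowed_cap_limits_removals(self, rng):
        p = validate_params().replace(k_aut=1e6, cap_autophagy=3)
        n = 50
        state = _state(np.column_stack([np.linspace(1, 99, n), np.full(n, 5.0)]),
                       np.zeros((n, 10), np.uint8))
        autophagy_step(state, p, rng)
        assert state.n == n - 3


# ---------------------------------------------------------------------------
# biogenesis
# ---------------------------------------------------------------------------

class TestReplication:
    def test_rate_monotone_and_vanishing(self):
        for form in ("linear", "logistic"):
            p = validate_params().replace(replication_form=form)
            rates = [replication_rate(N, p) for N in range(0, 1000, 5)]
            assert all(a >= b for a, b in zip(rates, rates[1:]))
            assert rates[-1] < 1e-6
            assert replication_rate(0, p) > 0

    def test_logistic_half_rate_at_N0(self):
        p = validate_params().replace(replication_form="logistic")
        assert replication_rate(p.N0, p) == pytest.approx(p.k_rep / 2)

    def test_daughter_copies_progenitor_health(self, rng):
        p = validate_params().replace(k_rep=1e6, N0=1e9, L=25.0)
        hu = np.zeros((1, 10), np.uint8)
        hu[0, :7] = 1
        state = _state([[5.0, 5.0]], hu)
        replicate_step(state, p, rng)
        assert state.n == 2
        assert state.hu[1].sum() == 7
        assert np.sqrt(((state.pos[1] - state.pos[0]) ** 2).sum()) >= 1.0

    def test_zero_cap_blocks_population_growth(self, rng):
        p = validate_params().replace(k_rep=1e6, N0=1e9, cap_replication=0)
        state = _state([[5.0, 5.0]], np.ones((1, 10), np.uint8))
        for _ in range(20):
            replicate_step(state, p, rng)
        assert state.n == 1

    def test_far_above_N0_rarely_replicates(self):
        p = validate_params().replace(replication_form="logistic")
        N = p.N0 + 10 * p.sigma_N
        per_step = -np.expm1(-N * replication_rate(N, p) * p.dt)
        assert per_step < 1e-3


class TestWindowAllows:
    def test_unlimited_always_true(self):
        assert window_allows(deque([1.0, 2.0, 3.0]), None, now=100.0)

    def test_full_window_blocks(self):
        ts = deque([10, 20, 30, 40, 50, 60])
        assert not window_allows(ts, 5, now=100.0)

    def test_old_events_fall_out_of_window(self):
        ts = deque([-300.0, -200.0, 10, 20, 30, 40])
        assert window_allows(ts, 5, now=100.0)
        assert list(ts) == [10, 20, 30, 40]  # pruned in place
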