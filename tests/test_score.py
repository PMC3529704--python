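import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, chi2_contingency

from ccit.core import (
    DelayAnnotatedNetwork,
    GeneTable,
    LaggedArc,
    LaggedParentSet,
    TimeSeriesDataset,
)
from ccit.score import (
    ScoreConfig,
    baseline_scores,
    ccit_local_score,
    ccit_score,
    chi2_critical,
    conditional_mi,
    degrees_of_freedom,
    joint_mi,
    mutual_information,
    order_penalty,
)

CHI_4 = chi2.ppf(0.9, 4)
CHI_12 = chi2.ppf(0.9, 12)
CHI_36 = chi2.ppf(0.9, 36)


def brute_force_mi(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    px = counts.sum(axis=1) / total
    py = counts.sum(axis=0) / total
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            p = counts[i, j] / total
            if p > 0:
                mi += p * math.log(p / (px[i] * py[j]))
    return mi


def brute_force_cmi(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    cmi = 0.0
    for i, j, k in itertools.product(*(range(s) for s in counts.shape)):
        p = counts[i, j, k] / total
        if p <= 0:
            continue
        pz = counts[:, :, k].sum() / total
        pxz = counts[i, :, k].sum() / total
        pyz = counts[:, j, k].sum() / total
        cmi += p * math.log(pz * p / (pxz * pyz))
    return cmi


class TestMutualInformation:
    def test_perfect_dependence_binary(self):
        assert mutual_information([[5, 0], [0, 5]]) == pytest.approx(math.log(2))

    def test_independence(self):
        assert mutual_information([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_matches_brute_force(self):
        tab = [[4, 1], [1, 4]]
        assert mutual_information(tab) == pytest.approx(brute_force_mi(tab), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([[0, 0], [0, 0]])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_tables_match_oracle_and_g_statistic(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
        tab = rng.integers(1, 40, size=shape)
        mi = mutual_information(tab)
        assert mi == pytest.approx(brute_force_mi(tab), abs=1e-10)
        # 2N * MI in nats is exactly the likelihood-ratio G-statistic
        g = chi2_contingency(tab, correction=False, lambda_="log-likelihood")[0]
        assert 2 * tab.sum() * mi == pytest.approx(g, rel=1e-10)


class TestConditionalMI:
    def test_conditional_independence_gives_zero(self):
        # X and Y independent within each Z stratum
        tab = np.empty((2, 2, 2))
        tab[:, :, 0] = np.outer([6, 2], [3, 1])
        tab[:, :, 1] = np.outer([1, 3], [2, 6])
        assert conditional_mi(tab) == pytest.approx(0.0, abs=1e-12)

    def test_constant_conditioner_reduces_to_mi(self):
        xy = np.array([[4.0, 1.0], [2.0, 5.0]])
        tab = np.zeros((2, 2, 2))
        tab[:, :, 0] = xy
        assert conditional_mi(tab) == pytest.approx(mutual_information(xy), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tab = rng.integers(1, 20, size=(2, 2, 2))
        assert conditional_mi(tab) == pytest.approx(brute_force_cmi(tab), abs=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mi_chain_rule_exhaustive_small_tables(self, seed):
        """MI(X, {A, B}) = MI(X, A) + MI(X, B | A) on full 3-way tables."""
        rng = np.random.default_rng(seed)
        tab = rng.integers(1, 15, size=(3, 2, 3)).astype(float)  # (x, a, b)
        mi_joint = mutual_information(tab.reshape(3, 6))
        mi_xa = mutual_information(tab.sum(axis=2))
        # CMI(X, B | A): reorder to (x, b, a)
        cmi_xb_a = conditional_mi(np.transpose(tab, (0, 2, 1)))
        assert mi_joint == pytest.approx(mi_xa + cmi_xb_a, abs=1e-10)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "child,parents,j,expected",
        [
            (3, [3], 1, 4),
            (3, [3, 3], 2, 12),
            (3, [3, 3, 3], 3, 36),
            (2, [2], 1, 1),
            (2, [2, 2], 2, 2),
            (3, [3, 2], 1, 4),
            (3, [3, 2], 2, 6),
        ],
    )
    def test_known_values(self, child, parents, j, expected):
        assert degrees_of_freedom(child, parents, j) == expected

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            degrees_of_freedom(3, [3], 2)


class TestOrderPenalty:
    def test_two_three_level_parents(self):
        assert order_penalty(3, [3, 3], 0.9) == pytest.approx(CHI_4 + CHI_12)

    def test_single_binary_parent(self):
        assert order_penalty(2, [2], 0.77) == pytest.approx(chi2.ppf(0.77, 1))

    def test_descending_order_attains_maximum(self):
        # mixed arities [3, 2]: descending gives dfs (4, 6); ascending (2, 8)
        desc = chi2_critical(0.9, 4) + chi2_critical(0.9, 6)
        asc = chi2_critical(0.9, 2) + chi2_critical(0.9, 8)
        assert order_penalty(3, [2, 3], 0.9) == pytest.approx(desc)
        assert desc >= asc

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(2, 4),
        st.lists(st.integers(2, 4), min_size=1, max_size=5),
        st.floats(min_value=0.5, max_value=0.99),
    )
    def test_maximum_over_all_permutations(self, child, arities, alpha):
        """Brute-force check that descending arity order maximizes the
        penalty over every parent permutation."""

        def penalty_for(perm):
            total = 0.0
            for j in range(1, len(perm) + 1):
                base = (child - 1) * (perm[j - 1] - 1)
                prod = int(np.prod(perm[: j - 1])) if j > 1 else 1
                total += chi2_critical(alpha, base * prod)
            return total

        best = max(penalty_for(p) for p in itertools.permutations(arities))
        assert order_penalty(child, arities, alpha) == pytest.approx(best, abs=1e-9)


def _dataset_for(network, N=40, seed=3, periodic=True):
    rng = np.random.default_rng(seed)
    arities = network.gene_table.arities
    arr = np.vstack([rng.integers(0, r, N) for r in arities])
    return TimeSeriesDataset([arr], network.gene_table, periodic=periodic)


class TestCCITScore:
    def test_empty_parent_set_scores_zero(self, worked_example_network):
        ds = _dataset_for(worked_example_network)
        assert ccit_local_score(ds, 2, LaggedParentSet.empty(2)) == 0.0

    def test_worked_example_per_order_penalty(self, worked_example_network):
        """Gene B (parents A, D instantaneous and C delayed, all 3-level)
        is penalized 2*chi_{a,4} + chi_{a,12} per order of regulation."""
        ds = _dataset_for(worked_example_network)
        bd = ccit_score(worked_example_network, ds, ScoreConfig(alpha=0.9, d_max=1))
        b = bd.per_node[1]
        assert b.penalty == pytest.approx(2 * CHI_4 + CHI_12)
        assert sorted(df for _, df, _ in b.penalty_terms) == [4, 4, 12]

    def test_worked_example_joint_penalty(self, worked_example_network):
        ds = _dataset_for(worked_example_network)
        cfg = ScoreConfig(alpha=0.9, d_max=1, penalty_mode="joint")
        bd = ccit_score(worked_example_network, ds, cfg)
        assert bd.per_node[1].penalty == pytest.approx(CHI_4 + CHI_12 + CHI_36)

    def test_network_total_penalty_structure(self, worked_example_network):
        """The whole network is penalized 3*chi_{a,4} + chi_{a,12}: two
        classes for B plus the single delayed parent of A."""
        ds = _dataset_for(worked_example_network)
        bd = ccit_score(worked_example_network, ds, ScoreConfig(alpha=0.9, d_max=1))
        assert bd.total_penalty == pytest.approx(3 * CHI_4 + CHI_12)

    def test_total_decomposes_into_local_scores(self, worked_example_network):
        ds = _dataset_for(worked_example_network)
        cfg = ScoreConfig(alpha=0.9, d_max=1)
        bd = ccit_score(worked_example_network, ds, cfg)
        recomputed = sum(
            ccit_local_score(ds, child, worked_example_network.parent_set(child), cfg)
            for child in range(4)
        )
        assert bd.total == pytest.approx(recomputed, abs=1e-9)

    def test_empty_network_scores_zero(self, worked_example_network):
        ds = _dataset_for(worked_example_network)
        empty = DelayAnnotatedNetwork(worked_example_network.gene_table, set(), 1)
        assert ccit_score(empty, ds).total == 0.0

    def test_mi_term_uses_effective_samples(self, worked_example_network):
        arr = _dataset_for(worked_example_network).series[0]
        aper = TimeSeriesDataset([arr], worked_example_network.gene_table, periodic=False)
        bd = ccit_score(worked_example_network, aper, ScoreConfig(d_max=1))
        assert bd.per_node[1].effective_n == arr.shape[1] - 1  # delta_B = 1

    def test_score_invariant_to_gene_relabeling(self, worked_example_network):
        ds = _dataset_for(worked_example_network)
        cfg = ScoreConfig(alpha=0.9, d_max=1)
        total = ccit_score(worked_example_network, ds, cfg).total
        perm = [2, 0, 3, 1]  # new position of old gene i
        table = GeneTable.uniform(
            [worked_example_network.gene_table.names[i] for i in np.argsort(perm)], 3
        )
        arcs = {
            LaggedArc(perm[a.regulator], perm[a.target], a.lag)
            for a in worked_example_network.arcs
        }
        perm_net = DelayAnnotatedNetwork(table, arcs, 1)
        perm_arr = np.empty_like(ds.series[0])
        for old, new in enumerate(perm):
            perm_arr[new] = ds.series[0][old]
        perm_ds = TimeSeriesDataset([perm_arr], table, periodic=True)
        assert ccit_score(perm_net, perm_ds, cfg).total == pytest.approx(total, abs=1e-9)


class TestJointMI:
    def test_independent_child_has_tiny_mi(self):
        table = GeneTable.uniform(["X", "P1", "P2"], 2)
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 2, (3, 2000))
        ds = TimeSeriesDataset([arr], table)
        mi, n = joint_mi(ds, 0, LaggedParentSet(0, {0: (1, 2)}))
        assert n == 2000 and mi < 0.01

    def test_xor_child_has_full_bit(self):
        table = GeneTable.uniform(["X", "P1", "P2"], 2)
        rng = np.random.default_rng(0)
        p = rng.integers(0, 2, (2, 500))
        x = p[0] ^ p[1]
        ds = TimeSeriesDataset([np.vstack([x, p])], table)
        mi, _ = joint_mi(ds, 0, LaggedParentSet(0, {0: (1, 2)}))
        # deterministic function of the joint parent state: MI = H(child)
        freq = np.bincount(x, minlength=2) / len(x)
        entropy = -np.sum(freq * np.log(freq))
        assert mi == pytest.approx(entropy, abs=1e-12)
        assert mi == pytest.approx(math.log(2), abs=0.01)

    def test_mixed_lags_conditioned_jointly(self):
        """Joint MI over a mixed-lag parent set equals MI of the child
        against the cross-product configuration, not a per-lag sum."""
        table = GeneTable.uniform(["X", "A", "B"], 2)
        rng = np.random.default_rng(4)
        N = 400
        a = rng.integers(0, 2, N)
        b = rng.integers(0, 2, N)
        x = np.zeros(N, dtype=int)
        x[1:] = a[1:] ^ b[:-1]  # X[t] = A[t] xor B[t-1]: pairwise invisible
        ds = TimeSeriesDataset([np.vstack([x, a, b])], table)
        pset = LaggedParentSet(0, {0: (1,), 1: (2,)})
        mi_joint, _ = joint_mi(ds, 0, pset)
        mi_a, _ = joint_mi(ds, 0, LaggedParentSet(0, {0: (1,)}))
        mi_b, _ = joint_mi(ds, 0, LaggedParentSet(0, {1: (2,)}))
        assert mi_joint > 0.5  # close to ln 2
        assert mi_a + mi_b < 0.05


class TestBaselines:
    def test_theorem_counterexample_vs_naive_combination(
        self, worked_example_network, worked_example_dataset
    ):
        """Scoring the arc types separately and adding them differs from
        the combined score whenever conditioning on the delayed parent
        changes the instantaneous MI."""
        cfg = ScoreConfig(alpha=0.9, d_max=1)
        ccit = ccit_score(worked_example_network, worked_example_dataset, cfg).total
        naive = baseline_scores(worked_example_network, worked_example_dataset, cfg)
        assert abs(ccit - naive["mit01"]) > 1e-6

    def test_identical_without_cross_order_parents(
        self, worked_example_network, worked_example_dataset
    ):
        """Dropping the delayed co-parent of B leaves no child with mixed
        orders, and the combined score collapses onto MIT0 + MIT1."""
        reduced = worked_example_network.copy()
        reduced.remove_arc(2, 1, 1)
        cfg = ScoreConfig(alpha=0.9, d_max=1)
        ccit = ccit_score(reduced, worked_example_dataset, cfg).total
        naive = baseline_scores(reduced, worked_example_dataset, cfg)
        assert ccit == pytest.approx(naive["mit01"], abs=1e-9)

    def test_lag0_only_network(self, worked_example_dataset):
        table = worked_example_dataset.gene_table
        net = DelayAnnotatedNetwork(table, {LaggedArc(0, 1, 0), LaggedArc(3, 1, 0)}, 1)
        bl = baseline_scores(net, worked_example_dataset)
        assert bl["mit1"] == 0.0
        assert bl["mit01"] == pytest.approx(bl["mit0"])

    def test_lagged_only_network(self, worked_example_dataset):
        table = worked_example_dataset.gene_table
        net = DelayAnnotatedNetwork(table, {LaggedArc(2, 1, 1), LaggedArc(3, 0, 1)}, 1)
        bl = baseline_scores(net, worked_example_dataset)
        assert bl["mit0"] == 0.0
        assert bl["mit01"] == pytest.approx(bl["mit1"])


class TestPenaltyModeComparison:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_per_order_never_exceeds_joint_with_multiple_classes(self, seed):
        """Splitting the penalty by regulation order can only reduce it
        when more than one lag class is populated."""
        rng = np.random.default_rng(seed)
        child_arity = int(rng.integers(2, 4))
        n_lags = int(rng.integers(2, 4))
        lags = rng.choice(np.arange(4), size=n_lags, replace=False)
        by_class = {
            int(k): [int(a) for a in rng.integers(2, 4, size=int(rng.integers(1, 3)))]
            for k in lags
        }
        per_order = sum(order_penalty(child_arity, ar, 0.9) for ar in by_class.values())
        all_arities = [a for ar in by_class.values() for a in ar]
        joint = order_penalty(child_arity, all_arities, 0.9)
        assert per_order <= joint + 1e-9


class TestTypeIBehavior:
    def test_single_ci_test_rejects_at_about_one_minus_alpha(self):
        """The embedded test 2N*MI > chi2_{alpha, 1} fires on ~10% of
        independent binary datasets at alpha = 0.9."""
        threshold = chi2_critical(0.9, 1)
        hits = 0
        trials = 400
        for s in range(trials):
            rng = np.random.default_rng(s)
            x = rng.integers(0, 2, 300)
            y = rng.integers(0, 2, 300)
            counts = np.zeros((2, 2))
            np.add.at(counts, (x, y), 1)
            if 2 * 300 * mutual_information(counts) > threshold:
                hits += 1
        assert 0.05 < hits / trials < 0.16
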