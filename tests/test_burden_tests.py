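"""The six-test burden battery and its permutation engine.

Permutation tests are checked against independent exhaustive-enumeration
oracles on tiny instances, and the exact tests against direct enumeration of
the contingency-table support.
"""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from painexome import burden_tests as bt


def carrier_input(n_cases, k_cases, n_ctls, k_ctls, hom_cases=0):
    """Single rare site; k carriers per group (hom_cases of them homozygous)."""
    d = np.zeros((n_cases + n_ctls, 1))
    d[:k_cases, 0] = 1
    d[:hom_cases, 0] = 2
    d[n_cases : n_cases + k_ctls, 0] = 1
    y = np.array([1] * n_cases + [0] * n_ctls)
    alleles = k_cases + hom_cases + k_ctls
    return bt.GeneTestInput(d, y, mafs=np.array([alleles / (2 * (n_cases + n_ctls))]))


def random_input(rng, n=24, J=4, n1=None):
    n1 = n // 2 if n1 is None else n1
    mafs = rng.uniform(0.01, 0.04, J)
    d = rng.binomial(2, mafs * 4, size=(n, J)).astype(float)
    y = np.array([1] * n1 + [0] * (n - n1))
    return bt.GeneTestInput(d, y, mafs=mafs)


class TestCarrierFixedThreshold:
    def test_worked_example_eleven_vs_one_carriers(self):
        """11/102 vs 1/101 carriers -> Fisher two-sided p = 0.0050."""
        inp = carrier_input(102, 11, 101, 1, hom_cases=1)
        res = bt.carrier_fixed_threshold_test(inp)
        assert res.p == pytest.approx(0.005, abs=5e-5)
        assert res.direction == 1

    def test_equal_carrier_rates_give_p_one(self):
        inp = carrier_input(50, 4, 50, 4)
        assert bt.carrier_fixed_threshold_test(inp).p == pytest.approx(1.0)

    def test_no_rare_site_is_missing_result(self):
        d = np.random.default_rng(0).binomial(2, 0.3, (20, 2)).astype(float)
        inp = bt.GeneTestInput(d, np.array([1] * 10 + [0] * 10), mafs=np.array([0.3, 0.2]))
        assert bt.carrier_fixed_threshold_test(inp) is None

    @staticmethod
    def enumerate_fisher(table):
        """Independent oracle: sum hypergeometric pmf over tables with point
        probability <= observed."""
        (a, b), (c, d) = table
        r1, c1, n = a + b, a + c, a + b + c + d
        lo, hi = max(0, c1 - (c + d)), min(r1, c1)
        pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
        return sum(v for v in pmf.values() if v <= pmf[a] * (1 + 1e-9))

    def test_matches_enumeration_for_all_small_margins(self):
        """Every 2x2 with margins <= 12 agrees with support enumeration."""
        checked = 0
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        if max(a + b, c + d, a + c, b + d) > 12:
                            continue
                        table = [[a, b], [c, d]]
                        p_scipy = stats.fisher_exact(table)[1]
                        assert p_scipy == pytest.approx(self.enumerate_fisher(table), rel=1e-8)
                        checked += 1
        assert checked > 500


class TestCcravatPearson:
    def test_hand_evaluated_chi_square(self):
        """Direct sum of (O-E)^2/E on the 11/91 vs 1/100 table."""
        table = np.array([[11, 91], [1, 100]])
        rowsum, colsum, n = table.sum(1), table.sum(0), table.sum()
        expect = np.outer(rowsum, colsum) / n
        chi2_hand = float(((table - expect) ** 2 / expect).sum())
        inp = carrier_input(102, 11, 101, 1, hom_cases=1)
        res = bt.ccravat_pearson_test(inp)
        assert res.statistic == pytest.approx(chi2_hand)
        assert chi2_hand == pytest.approx(8.7527, abs=1e-3)
        assert res.p == pytest.approx(stats.chi2.sf(chi2_hand, 1))

    def test_equal_proportions_statistic_zero(self):
        res = bt.ccravat_pearson_test(carrier_input(50, 4, 50, 4))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_agreement_with_fisher_when_counts_large(self):
        """Within a factor of 2 of Fisher when all expected counts >= 5."""
        rng = np.random.default_rng(8)
        compared = 0
        for _ in range(1000):
            n1, n0 = rng.integers(40, 120, 2)
            k1 = rng.integers(8, n1 // 2)
            k0 = rng.integers(8, n0 // 2)
            table = np.array([[k1, n1 - k1], [k0, n0 - k0]])
            expect = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if expect.min() < 5:
                continue
            p_f = stats.fisher_exact(table)[1]
            chi2 = float(((table - expect) ** 2 / expect).sum())
            p_c = stats.chi2.sf(chi2, 1)
            if p_f > 0.01:  # asymptotic and exact diverge in the deep tail
                assert 0.5 < p_c / p_f < 2.0
                compared += 1
        assert compared > 200


class TestMadsenBrowning:
    def test_control_frequency_pseudocount(self):
        """A site absent from 101 controls gets q_hat = 1/204."""
        d = np.zeros((202, 1))
        d[:3, 0] = 1  # carriers only among cases
        y = np.array([1] * 101 + [0] * 101)
        w = bt.madsen_browning_weights(d, y)
        q = 1 / 204
        assert w[0] == pytest.approx(np.sqrt(101 * q * (1 - q)))

    def test_exhaustive_permutation_matches_oracle(self):
        """n = 7: engine result equals brute-force rank-sum enumeration."""
        rng = np.random.default_rng(42)
        d = rng.binomial(2, 0.2, size=(7, 2)).astype(float)
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        inp = bt.GeneTestInput(d, y, mafs=np.array([0.02, 0.03]))
        res = bt.madsen_browning_test(inp, B=10_000, seed=1)
        w = bt.madsen_browning_weights(inp.dosages, y)
        gamma = inp.imputed() @ (1.0 / w)
        ranks = stats.rankdata(gamma)
        expect = 3 * 8 / 2
        t_obs = abs(ranks[y == 1].sum() - expect)
        t_all = [abs(sum(ranks[list(c)]) - expect) for c in combinations(range(7), 3)]
        p_oracle = np.mean([t >= t_obs - 1e-12 for t in t_all])
        assert res.p == pytest.approx(p_oracle)
        assert res.n_permutations == math.comb(7, 3)

    def test_no_controls_is_an_error(self):
        d = np.ones((4, 1))
        with pytest.raises(ValueError):
            bt.madsen_browning_weights(d, np.array([1, 1, 1, 1]))

    def test_functional_weights_change_the_statistic(self):
        rng = np.random.default_rng(9)
        inp = random_input(rng, n=40, J=5)
        inp.func_weights = np.array([1.0, 0.25, 1.0, 0.5, 0.25])
        r0 = bt.madsen_browning_test(inp, use_functional_weights=False, B=200, seed=0)
        r1 = bt.madsen_browning_test(inp, use_functional_weights=True, B=200, seed=0)
        assert r0.statistic != r1.statistic


class TestASum:
    def test_alpha0_zero_reduces_to_plain_sum(self):
        rng = np.random.default_rng(10)
        inp = random_input(rng, n=30, J=4)
        res = bt.asum_test(inp, alpha0=0.0, B=500, seed=1)
        xc = inp.imputed() - inp.imputed().mean(0)
        s = xc.sum(1)
        ybar = inp.y.mean()
        U = float(s @ (inp.y - ybar))
        V = ybar * (1 - ybar) * float((s**2).sum())
        assert res.statistic == pytest.approx(U * U / V)

    def test_exhaustive_permutation_matches_oracle(self):
        """n = 8 with re-screening inside every label assignment."""
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.25, size=(8, 3)).astype(float)
        y = np.array([1] * 4 + [0] * 4)
        inp = bt.GeneTestInput(d, y, mafs=np.full(3, 0.03))
        res = bt.asum_test(inp, alpha0=0.1, B=10**6, seed=3)
        crit = stats.chi2.isf(0.1, 1)

        def oracle_stat(yv):
            ybar = yv.mean()
            xc = d - d.mean(0)
            Uj = xc.T @ (yv - ybar)
            ssj = (xc**2).sum(0)
            vf = ybar * (1 - ybar)
            t = np.where(ssj > 0, Uj**2 / (vf * ssj), 0)
            sg = np.where((Uj < 0) & (t > crit), -1.0, 1.0)
            num = float(sg @ Uj) ** 2
            den = vf * float(sg @ (xc.T @ xc) @ sg)
            return num / den if den > 0 else 0.0

        t_obs = oracle_stat(y)
        t_all = [
            oracle_stat(np.isin(np.arange(8), c).astype(int))
            for c in combinations(range(8), 4)
        ]
        p_oracle = np.mean([t >= t_obs - 1e-9 for t in t_all])
        assert res.p == pytest.approx(p_oracle)

    def test_adaptive_recoding_beats_plain_sum_with_mixed_effects(self):
        """With half-protective, half-deleterious sites the adaptive test has
        more power than the non-adaptive sum test (its design rationale)."""
        rng = np.random.default_rng(12)
        n, J, B, reps = 120, 8, 300, 120
        wins_adaptive = wins_plain = 0
        for _ in range(reps):
            y = np.array([1] * (n // 2) + [0] * (n // 2))
            beta = np.array([1.5] * (J // 2) + [-1.5] * (J // 2))
            base = rng.uniform(0.02, 0.05, J)
            p_case = base * np.exp(beta * 0.5)
            p_ctl = base * np.exp(-beta * 0.5)
            d = np.vstack(
                [
                    rng.binomial(2, np.clip(p_case, 0, 1), size=(n // 2, J)),
                    rng.binomial(2, np.clip(p_ctl, 0, 1), size=(n // 2, J)),
                ]
            ).astype(float)
            inp = bt.GeneTestInput(d, y, mafs=base)
            p_ad = bt.asum_test(inp, alpha0=0.1, B=B, seed=rng).p
            p_pl = bt.asum_test(inp, alpha0=0.0, B=B, seed=rng).p
            wins_adaptive += p_ad <= 0.05
            wins_plain += p_pl <= 0.05
        assert wins_adaptive > wins_plain

    def test_too_few_per_class_rejected(self):
        d = np.random.default_rng(0).binomial(2, 0.3, (5, 2)).astype(float)
        with pytest.raises(ValueError):
            bt.asum_test(bt.GeneTestInput(d, np.array([1, 0, 0, 0, 0]), mafs=np.array([0.1, 0.1])))


class TestSSU:
    def test_single_site_reduces_to_squared_score(self):
        """On one site the SSU statistic is exactly the squared score."""
        rng = np.random.default_rng(13)
        d = rng.binomial(2, 0.15, size=(30, 1)).astype(float)
        y = np.array([1] * 15 + [0] * 15)
        inp = bt.GeneTestInput(d, y, mafs=np.array([0.1]))
        res = bt.ssu_test(inp, B=500, seed=2)
        xc = d - d.mean(0)
        u = float(xc[:, 0] @ y)
        assert res.statistic == pytest.approx(u * u)

    def test_asymptotic_close_to_permutation(self):
        """Satterthwaite approximation within 20% relative of permutation p
        on moderately sized inputs."""
        rng = np.random.default_rng(14)
        n_checked = 0
        for _ in range(30):
            d = rng.binomial(2, rng.uniform(0.02, 0.3, 10), size=(400, 10)).astype(float)
            y = np.array([1] * 200 + [0] * 200)
            rng.shuffle(y)
            inp = bt.GeneTestInput(d, y, mafs=np.full(10, 0.03))
            p_perm = bt.ssu_test(inp, B=4000, seed=rng).p
            p_asym = bt.ssu_test(inp, method="satterthwaite").p
            if 0.05 < p_perm < 0.95:  # compare away from the floor
                assert abs(p_perm - p_asym) / p_asym < 0.2
                n_checked += 1
        assert n_checked >= 10

    def test_constant_dosage_missing_result(self):
        d = np.zeros((10, 3))
        inp = bt.GeneTestInput(d, np.array([1] * 5 + [0] * 5), mafs=np.zeros(3))
        assert bt.ssu_test(inp) is None


class TestAlleleMatching:
    def test_identical_subjects_have_maximal_similarity(self):
        d = np.array([[0, 1, 2], [0, 1, 2], [2, 0, 0], [1, 1, 0.0]])
        inp = bt.GeneTestInput(d, np.array([1, 0, 1, 0]), mafs=np.full(3, 0.04))
        K = bt.allele_matching_kernel(inp)
        off_diag = K[np.triu_indices(4, 1)]
        assert K[0, 1] == pytest.approx(off_diag.max())

    def test_exhaustive_permutation_matches_oracle(self):
        """n = 6: engine equals brute-force within/between enumeration."""
        rng = np.random.default_rng(15)
        d = rng.binomial(2, 0.3, size=(6, 3)).astype(float)
        y = np.array([1, 1, 1, 0, 0, 0])
        inp = bt.GeneTestInput(d, y, mafs=np.full(3, 0.04))
        res = bt.allele_matching_test(inp, B=10_000, seed=4)
        K = bt.allele_matching_kernel(inp)

        def oracle_stat(yv):
            within, between = [], []
            for i in range(6):
                for k in range(i + 1, 6):
                    (within if yv[i] == yv[k] else between).append(K[i, k])
            return np.mean(within) - np.mean(between)

        t_obs = oracle_stat(y)
        t_all = [
            oracle_stat(np.isin(np.arange(6), c).astype(int))
            for c in combinations(range(6), 3)
        ]
        p_oracle = np.mean([t >= t_obs - 1e-12 for t in t_all])
        assert res.p == pytest.approx(p_oracle)

    def test_small_n_rejected(self):
        d = np.random.default_rng(0).binomial(2, 0.3, (3, 2)).astype(float)
        with pytest.raises(ValueError):
            bt.allele_matching_test(bt.GeneTestInput(d, np.array([1, 0, 1]), mafs=np.array([0.1, 0.1])))


class TestPermutationEngine:
    def test_observed_maximum_gives_floor_p(self):
        y = np.array([1] * 5 + [0] * 15)
        scores = np.arange(20.0)[::-1]  # cases hold the top scores

        def statistic(yv):
            return float(scores @ yv)

        p, used = bt.permutation_pvalue(statistic, y, B=999, seed=0, exhaustive=False)
        assert p == pytest.approx(1 / (999 + 1))
        assert used == 999

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=30)
        y = np.array([1] * 15 + [0] * 15)

        def statistic(yv):
            return float(scores @ yv)

        p1, _ = bt.permutation_pvalue(statistic, y, B=500, seed=11, exhaustive=False)
        p2, _ = bt.permutation_pvalue(statistic, y, B=500, seed=11, exhaustive=False)
        assert p1 == p2

    def test_exhaustive_mode_equals_enumeration(self):
        """B covering all C(6,3) assignments triggers exact enumeration."""
        scores = np.array([3.0, 1.0, 2.0, -1.0, 0.5, -2.0])
        y = np.array([1, 1, 1, 0, 0, 0])

        def statistic(yv):
            return float(scores @ yv)

        p, used = bt.permutation_pvalue(statistic, y, B=10_000)
        t_obs = statistic(y)
        t_all = [sum(scores[list(c)]) for c in combinations(range(6), 3)]
        assert used == math.comb(6, 3)
        assert p == pytest.approx(np.mean([t >= t_obs - 1e-12 for t in t_all]))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n1=st.integers(2, 6),
        n0=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_p_in_valid_range(self, n1, n0, seed):
        """Permutation p always lies in [1/(B+1), 1]."""
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n1 + n0)
        y = np.array([1] * n1 + [0] * n0)
        B = 99
        p, used = bt.permutation_pvalue(lambda yv: float(scores @ yv), y, B=B)
        assert 1 / (B + 1) <= p <= 1 or used != B  # exhaustive mode: p in (0, 1]
        assert 0 < p <= 1


class TestBattery:
    def test_gene_without_rare_sites_is_dropped(self, small_study, cohort1_labels):
        from painexome.variant_qc import build_gene_blocks

        blocks = build_gene_blocks(
            small_study.cohorts[0].to_call_set(), small_study.gene_regions
        )
        gene, block = next(iter(blocks.items()))
        block.sites["maf"] = 0.4  # make every site common -> carrier tests missing
        res = bt.run_battery(blocks, cohort1_labels, bt.BatteryConfig(n_permutations=50, seed=0))
        assert gene in res.dropped
        assert gene not in res.pvalues.index

    def test_single_gene_gives_one_by_six_table(self, small_study, cohort1_labels):
        from painexome.variant_qc import build_gene_blocks

        blocks = build_gene_blocks(
            small_study.cohorts[0].to_call_set(), small_study.gene_regions
        )
        one = {k: v for k, v in list(blocks.items())[:1]}
        res = bt.run_battery(one, cohort1_labels, bt.BatteryConfig(n_permutations=100, seed=0))
        assert res.pvalues.shape == (1, 6)
        assert list(res.pvalues.columns) == list(bt.TEST_NAMES)

    def test_battery_reproducible_for_fixed_seed(self, small_study, cohort1_labels):
        from painexome.variant_qc import build_gene_blocks

        blocks = build_gene_blocks(
            small_study.cohorts[0].to_call_set(), small_study.gene_regions
        )
        few = {k: blocks[k] for k in list(blocks)[:3]}
        cfg = bt.BatteryConfig(n_permutations=200, seed=5)
        r1 = bt.run_battery(few, cohort1_labels, cfg)
        r2 = bt.run_battery(few, cohort1_labels, cfg)
        assert r1.pvalues.equals(r2.pvalues)
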