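"""Rho statistic, Saillard standard error, clock calibration, comparisons."""

import numpy as np
import pytest

import mitophylo as mp
from mitophylo.haplo_tree import CladeNode, HaplogroupTree
from mitophylo.mito_io import parse_variant_label
from mitophylo.rho_dating import (
    AgeEstimate,
    ClockModel,
    PiecewiseCorrection,
    RhoEstimate,
    average_rates,
    compare_ages,
    complete_clock,
    compute_rho,
    compute_sigma,
    rho_to_age,
)
from mitophylo.synthetic_data import simulate_clade


def _star_tree(private_counts):
    """Star clade: one child per tip carrying the given private counts."""
    root = CladeNode("X")
    for i, k in enumerate(private_counts):
        child = CladeNode(parent=root)
        child.edge_variants = [
            parse_variant_label(f"A{100 * (i + 1) + j}G") for j in range(k)
        ]
        child.samples = [f"t{i}"]
        root.children.append(child)
    return HaplogroupTree(root)


def _nested_tree():
    """Shared edge (1 event, 2 tips); private 0 and 2 below it."""
    root = CladeNode("X")
    shared = CladeNode(parent=root)
    shared.edge_variants = [parse_variant_label("A100G")]
    a = CladeNode(parent=shared)
    a.samples = ["t1"]
    b = CladeNode(parent=shared)
    b.edge_variants = [parse_variant_label("A200G"), parse_variant_label("A300G")]
    b.samples = ["t2"]
    shared.children = [a, b]
    root.children = [shared]
    return HaplogroupTree(root)


class TestRho:
    def test_star_mean(self):
        est = compute_rho(_star_tree([1, 2, 3]))
        assert est.rho == pytest.approx(2.0)
        assert est.n == 3

    def test_single_tip(self):
        est = compute_rho(_star_tree([5]))
        assert est.rho == pytest.approx(5.0)

    def test_nested_path_enumeration(self):
        # explicit paths: t1 -> 1 event, t2 -> 3 events; rho = 2
        est = compute_rho(_nested_tree())
        assert est.rho == pytest.approx(2.0)

    def test_empty_clade_rejected(self):
        with pytest.raises(ValueError):
            compute_rho(HaplogroupTree(CladeNode("X")))

    def test_synonymous_filter_monotone(self, ref, rng):
        sim = simulate_clade(12, 15000, 2e-6, ref, model="kingman", seed=11)
        tree = mp.build_mp_tree(sim.profiles, name_clades=False)
        r_all = compute_rho(tree).rho
        r_syn = compute_rho(tree, mutation_filter="synonymous", ref=ref).rho
        assert 0 <= r_syn <= r_all


class TestSigma:
    def test_star_formula_and_monte_carlo(self, rng):
        """sigma = sqrt(sum m_e n_e^2)/n; for private counts (1,2,3) this
        is sqrt(6)/3, matching Poisson resampling of the edge counts."""
        tree = _star_tree([1, 2, 3])
        sigma = compute_sigma(tree)
        assert sigma == pytest.approx(np.sqrt(6) / 3, abs=1e-12)
        reps = rng.poisson([1, 2, 3], size=(100_000, 3)).mean(axis=1)
        assert sigma == pytest.approx(reps.std(ddof=1), abs=5e-3)

    def test_zero_mutations_zero_sigma(self):
        assert compute_sigma(_star_tree([0, 0, 0])) == 0.0

    def test_shared_edge_matches_monte_carlo(self, rng):
        """4 events on one edge over 4 tips: rho resamples as a single
        Poisson(4) count, so SD(rho) = 2."""
        root = CladeNode("X")
        shared = CladeNode(parent=root)
        shared.edge_variants = [parse_variant_label(f"A{100 + i}G") for i in range(4)]
        for i in range(4):
            tip = CladeNode(parent=shared)
            tip.samples = [f"t{i}"]
            shared.children.append(tip)
        root.children = [shared]
        sigma = compute_sigma(HaplogroupTree(root))
        draws = rng.poisson(4, size=100_000).astype(float)
        assert sigma == pytest.approx(draws.std(ddof=1), rel=0.02)
        assert sigma == pytest.approx(2.0, abs=1e-12)


class TestClock:
    def test_rate_averaging(self):
        assert average_rates(1.665e-8, 1.708e-8) == pytest.approx(1.6865e-8, rel=1e-12)
        assert average_rates(3e-8, 3e-8) == 3e-8
        assert 1.665e-8 <= average_rates(1.665e-8, 1.708e-8) <= 1.708e-8
        with pytest.raises(ValueError):
            average_rates(-1e-8, 1e-8)

    def test_rho_to_age_arithmetic(self):
        clock = complete_clock()
        est = RhoEstimate("X", 1.0, 0.0, 10)
        age = rho_to_age(est, clock)
        assert age.years == pytest.approx(1.0 / (1.6865e-8 * 16569), rel=1e-9)
        assert age.years == pytest.approx(3578.6, abs=0.5)

    def test_zero_rho_zero_age(self):
        age = rho_to_age(RhoEstimate("X", 0.0, 0.5, 4), complete_clock())
        assert age.years == 0.0
        assert age.ci_low == 0.0

    def test_incompatible_filter_clock_pairing(self):
        syn_clock = ClockModel("synonymous", 1e-8, 10000)
        with pytest.raises(ValueError):
            rho_to_age(RhoEstimate("X", 1.0, 0.1, 5, "all"), syn_clock)
        with pytest.raises(ValueError):
            rho_to_age(
                RhoEstimate("X", 1.0, 0.1, 5, "synonymous"), complete_clock()
            )

    def test_monotone_correction_preserves_order(self):
        def corr(t):
            return t + 0.5 * t**2 / 10000

        c1 = ClockModel("custom", 1e-8, 16569, corr)
        a1 = rho_to_age(RhoEstimate("A", 2.0, 0.3, 5), c1)
        a2 = rho_to_age(RhoEstimate("B", 3.0, 0.3, 5), c1)
        assert a1.years < a2.years
        assert a1.ci_low <= a1.years <= a1.ci_high

    def test_piecewise_correction_table(self, tmp_path):
        path = tmp_path / "corr.tsv"
        path.write_text("0\t0\n10000\t12000\n20000\t30000\n")
        corr = PiecewiseCorrection.from_tsv(path)
        assert corr(0) == 0
        assert corr(5000) == pytest.approx(6000)
        assert corr(15000) == pytest.approx(21000)
        assert corr(25000) == pytest.approx(39000)  # linear extrapolation
        bad = tmp_path / "bad.tsv"
        bad.write_text("0\t0\n10000\t9000\n5000\t10000\n")
        with pytest.raises(ValueError):
            PiecewiseCorrection.from_tsv(bad)


class TestCompare:
    def _age(self, years, sigma_years):
        return AgeEstimate("X", years, years - 1, years + 1, "complete", sigma_years, 10)

    def test_equal_ages_p_one(self):
        z, p = compare_ages(self._age(10000, 500), self._age(10000, 500))
        assert z == 0
        assert p == pytest.approx(1.0)

    def test_quantile_196(self):
        sa, sb = 300.0, 400.0
        joint = np.hypot(sa, sb)
        z, p = compare_ages(self._age(10000 + 1.96 * joint, sa), self._age(10000, sb))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_ages(self._age(10000, 0.0), self._age(9000, 0.0))

    def test_distinct_clade_ages_detected(self, big_ref):
        """18 ky vs 10 ky star clades (n = 30) separate at small p in the
        clear majority of replicates."""
        clock = complete_clock()
        hits = 0
        for i in range(25):
            sa = simulate_clade(30, 18000, clock.mu, big_ref, seed=9000 + 2 * i)
            sb = simulate_clade(30, 10000, clock.mu, big_ref, seed=9001 + 2 * i)
            ta = rho_to_age(compute_rho(mp.build_mp_tree(sa.profiles, name_clades=False)), clock)
            tb = rho_to_age(compute_rho(mp.build_mp_tree(sb.profiles, name_clades=False)), clock)
            _, p = compare_ages(ta, tb)
            hits += p < 0.01
        assert hits >= 23


class TestCalibration:
    def test_unbiased_and_covered(self, big_ref):
        """Scaled-down calibration check: mean rho-based age of simulated
        star clades is within 3 Monte-Carlo SEs of the true age and the
        95% interval covers it in >= 85% of 60 clades."""
        clock = complete_clock()
        T = 18600.0
        ages, cover = [], 0
        for i in range(60):
            sim = simulate_clade(30, T, clock.mu, big_ref, seed=3000 + i)
            tree = mp.build_mp_tree(sim.profiles, name_clades=False)
            age = rho_to_age(compute_rho(tree), clock)
            ages.append(age.years)
            cover += age.ci_low <= T <= age.ci_high
        ages = np.asarray(ages)
        se = ages.std(ddof=1) / np.sqrt(len(ages))
        assert abs(ages.mean() - T) <= 3 * se
        assert cover / len(ages) >= 0.85

    def test_sigma_matches_resampling_variance(self, big_ref, rng):
        """Saillard sigma^2 vs empirical variance of rho under Poisson
        resampling of the edge counts, within 5% at 1e5 reps."""
        sim = simulate_clade(25, 15000, complete_clock().mu, big_ref, seed=77)
        tree = mp.build_mp_tree(sim.profiles, name_clades=False)
        est = compute_rho(tree)
        terms = [
            (len(n.edge_variants), n.tip_count())
            for n in tree.root.walk()
            if n is not tree.root and n.edge_variants
        ]
        m = np.array([t[0] for t in terms], dtype=float)
        ne = np.array([t[1] for t in terms], dtype=float)
        draws = rng.poisson(m, size=(100_000, len(m)))
        rho_reps = draws @ ne / est.n
        assert est.sigma**2 == pytest.approx(rho_reps.var(ddof=1), rel=0.05)
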