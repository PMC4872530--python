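"""Tip-dated clock: rho statistic, JC likelihoods, MCMC, HPD intervals."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from mitopaleo.clock import (
    ClockMCMCConfig,
    ClockPrior,
    TipDatedSequence,
    effective_sample_size,
    hpd_interval,
    mcmc_tmrca,
    pruning_loglik,
    rho_tmrca,
    simulate_clade,
    star_loglik,
)
from mitopaleo.reference import encode, load_reference


def _brute_force_hpd(samples, mass):
    """Exhaustive search over all contiguous sample windows."""
    x = np.sort(samples)
    n = len(x)
    m = int(np.ceil(mass * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if width < best[0]:
            best = (width, (x[i], x[i + m - 1]))
    return best[1]


def _jc_matrix(branch):
    """JC transition matrix via matrix exponential (independent of the
    closed form used by the implementation)."""
    q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(q, -1.0)
    return expm(q * branch)


class TestHPD:
    def test_matches_exhaustive_window_search(self):
        rng = np.random.default_rng(2)
        samples = rng.gamma(3.0, 2.0, size=100)
        assert hpd_interval(samples, 0.95) == _brute_force_hpd(samples, 0.95)
        assert hpd_interval(samples, 0.5) == _brute_force_hpd(samples, 0.5)

    def test_uniform_width(self):
        rng = np.random.default_rng(3)
        low, high = hpd_interval(rng.uniform(0, 1, 50_000), 0.95)
        assert high - low == pytest.approx(0.95, abs=0.01)

    def test_point_mass_zero_width(self):
        low, high = hpd_interval(np.full(100, 3.7), 0.95)
        assert low == high == 3.7

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), 1.5)


class TestRho:
    def test_identical_tips_age_zero(self, reference):
        tips = [TipDatedSequence(f"t{i}", reference, 0.0) for i in range(4)]
        est = rho_tmrca(tips, reference)
        assert est.point == 0.0

    def test_one_substitution_hand_arithmetic(self, reference):
        """Mean 1 substitution at mu=2.06e-8 over 16,569 sites ~ 2.93 ky."""
        mu = 2.06e-8
        seq = "C" + reference[1:] if reference[0] != "C" else "G" + reference[1:]
        tips = [
            TipDatedSequence("a", seq, 0.0),
            TipDatedSequence("b", seq, 0.0),
        ]
        est = rho_tmrca(tips, reference, mu)
        assert est.point == pytest.approx(1 / (16569 * mu), rel=1e-9)
        assert est.point == pytest.approx(2930, abs=1.0)

    def test_recovers_simulated_truth_within_2se(self, reference):
        prior = ClockPrior()
        tips = simulate_clade(
            50_000, [0.0] * 19 + [35_000.0], prior.rate_mean, reference, seed=301
        )
        est = rho_tmrca(tips, reference, prior.rate_mean)
        assert abs(est.point - 50_000) < 2 * est.se


class TestSimulateClade:
    def test_tip_at_clade_age_is_root(self, reference):
        tips = simulate_clade(35_000, [35_000.0], 2.06e-8, reference, seed=5)
        assert tips[0].sequence == reference

    def test_expected_substitution_count(self, reference):
        mu, t = 2.06e-8, 50_000.0
        root = encode(reference)
        counts = []
        for rep in range(200):
            tips = simulate_clade(t, [0.0], mu, reference, seed=400 + rep)
            counts.append(int((encode(tips[0].sequence) != root).sum()))
        lam = mu * 16569 * t
        # repeated hits make observed differences <= events; allow that margin
        sd = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * sd + 0.02 * lam

    def test_seeded_determinism(self, reference):
        a = simulate_clade(50_000, [0.0, 1000.0], 2.06e-8, reference, seed=9)
        b = simulate_clade(50_000, [0.0, 1000.0], 2.06e-8, reference, seed=9)
        assert [t.sequence for t in a] == [t.sequence for t in b]

    def test_tip_older_than_clade_rejected(self, reference):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_clade(30_000, [35_000.0], 2.06e-8, reference, seed=1)


class TestLikelihoods:
    def test_star_loglik_matches_expm_enumeration(self):
        """4 tips, 10 sites: direct sum over root states with expm matrices."""
        rng = np.random.default_rng(12)
        tips = rng.integers(0, 4, size=(10, 4)).astype(np.uint8)
        branches = np.array([0.01, 0.05, 0.002, 0.08])
        mats = [_jc_matrix(b) for b in branches]
        expected = 0.0
        for site in tips:
            site_like = 0.0
            for root in range(4):
                p = 0.25
                for tip_idx, base in enumerate(site):
                    p *= mats[tip_idx][root, base]
                site_like += p
            expected += np.log(site_like)
        patterns, counts = np.unique(tips, axis=0, return_counts=True)
        got = star_loglik(patterns, counts, branches)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_pruning_matches_internal_state_enumeration(self):
        """Balanced 4-taxon tree: brute-force sum over all internal states."""
        newick = "((A:0.02,B:0.05):0.03,(C:0.01,D:0.04):0.06);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        rng = np.random.default_rng(21)
        seqs = {
            lab: "".join("ACGT"[i] for i in rng.integers(0, 4, size=10))
            for lab in "ABCD"
        }
        got = pruning_loglik(tree, seqs)

        m = {lab: _jc_matrix(b) for lab, b in zip("ABCD", [0.02, 0.05, 0.01, 0.04])}
        m_u, m_v = _jc_matrix(0.03), _jc_matrix(0.06)
        expected = 0.0
        for site in range(10):
            obs = {lab: "ACGT".index(seqs[lab][site]) for lab in "ABCD"}
            site_like = 0.0
            for root in range(4):
                for u in range(4):
                    for v in range(4):
                        site_like += (
                            0.25
                            * m_u[root, u]
                            * m_v[root, v]
                            * m["A"][u, obs["A"]]
                            * m["B"][u, obs["B"]]
                            * m["C"][v, obs["C"]]
                            * m["D"][v, obs["D"]]
                        )
            expected += np.log(site_like)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_missing_data_marginalised(self):
        patterns = np.array([[0, 4]], dtype=np.uint8)  # second tip is N
        counts = np.array([1])
        got = star_loglik(patterns, counts, np.array([0.01, 0.05]))
        only = star_loglik(
            np.array([[0]], dtype=np.uint8), np.array([1]), np.array([0.01])
        )
        assert got == pytest.approx(only, rel=1e-12)


class TestMCMC:
    def test_prior_recovery_without_likelihood(self, reference):
        """Likelihood off: the sampler reproduces its priors."""
        prior = ClockPrior()
        tips = [TipDatedSequence("a", reference, 0.0)]
        est = mcmc_tmrca(
            tips,
            prior,
            ClockMCMCConfig(n_iter=20_000, burn_in=2000, seed=17),
            use_likelihood=False,
        )
        rates = est.trace[:, 1]
        assert np.mean(rates) == pytest.approx(prior.rate_mean, rel=0.05)
        ages = est.trace[:, 0]
        assert np.mean(ages) == pytest.approx(100_000, rel=0.15)

    def test_posterior_brackets_simulated_truth(self, reference):
        prior = ClockPrior()
        tips = simulate_clade(
            50_000, [0.0] * 19 + [35_000.0], prior.rate_mean, reference, seed=501
        )
        est = mcmc_tmrca(tips, prior, ClockMCMCConfig(seed=502))
        assert est.hpd_low <= 50_000 <= est.hpd_high
        assert est.hpd_low <= est.point <= est.hpd_high

    def test_rate_scaling_halves_age(self, reference):
        """Doubling the rate prior roughly halves the inferred age."""
        base = ClockPrior()
        tips = simulate_clade(
            60_000, [0.0] * 10, base.rate_mean, reference, seed=601
        )
        slow = mcmc_tmrca(tips, base, ClockMCMCConfig(seed=602))
        fast = mcmc_tmrca(
            tips,
            ClockPrior(2 * base.rate_mean, 2 * base.rate_sd),
            ClockMCMCConfig(seed=602),
        )
        assert slow.point / fast.point == pytest.approx(2.0, rel=0.2)

    def test_star_newick_matches_builtin_star(self, reference):
        """A multifurcating Newick topology is the star model: same data,
        same estimate up to Monte-Carlo error."""
        prior = ClockPrior()
        tips = simulate_clade(
            50_000, [0.0, 0.0, 0.0, 35_000.0], prior.rate_mean, reference,
            seed=701, labels=["a", "b", "c", "d"],
        )
        topo = dendropy.Tree.get(data="(a:1,b:1,c:1,d:1);", schema="newick")
        star = mcmc_tmrca(tips, prior, ClockMCMCConfig(seed=702))
        via_tree = mcmc_tmrca(tips, prior, ClockMCMCConfig(seed=702), topology=topo)
        mc_err = 2 * np.sqrt(
            star.trace[:, 0].std() ** 2 / star.ess
            + via_tree.trace[:, 0].std() ** 2 / via_tree.ess
        )
        assert abs(star.point - via_tree.point) < max(mc_err, 2000.0)

    def test_nested_topology_recovers_matching_simulation(self, reference):
        """Data generated on a two-level chronogram (root 60 ky, internal
        splits at 30 ky) is recovered by MCMC on that fixed topology."""
        prior = ClockPrior()
        mu = prior.rate_mean
        internal1 = simulate_clade(30_000, [0.0], mu, reference, seed=711)[0].sequence
        internal2 = simulate_clade(30_000, [0.0], mu, reference, seed=712)[0].sequence
        seqs = {
            "a": simulate_clade(30_000, [0.0], mu, internal1, seed=713)[0].sequence,
            "b": simulate_clade(30_000, [0.0], mu, internal1, seed=714)[0].sequence,
            "c": simulate_clade(30_000, [0.0], mu, internal2, seed=715)[0].sequence,
            "d": simulate_clade(30_000, [0.0], mu, internal2, seed=716)[0].sequence,
        }
        tips = [TipDatedSequence(k, v, 0.0) for k, v in seqs.items()]
        topo = dendropy.Tree.get(
            data="((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);", schema="newick"
        )
        est = mcmc_tmrca(tips, prior, ClockMCMCConfig(seed=717), topology=topo)
        assert est.hpd_low <= 60_000 <= est.hpd_high

    def test_topology_leaf_without_sequence_rejected(self, reference):
        tips = [TipDatedSequence("a", reference, 0.0)]
        topo = dendropy.Tree.get(data="(a:1,zz:1);", schema="newick")
        with pytest.raises(ValueError, match="no sequence"):
            mcmc_tmrca(tips, ClockPrior(), ClockMCMCConfig(n_iter=10), topology=topo)

    def test_root_age_bound_must_exceed_tips(self, reference):
        tips = [TipDatedSequence("a", reference, 300_000.0)]
        with pytest.raises(ValueError, match="root_age_max"):
            mcmc_tmrca(tips, ClockPrior(), ClockMCMCConfig())


def test_median_relative_bias_across_age_grid(reference):
    """Point estimates stay within 10% median relative bias for clade ages
    spanning 20-80 ky.

    At 20 ky each lineage carries only ~7 expected substitutions, so single
    replicates scatter by ~12%; 15 replicates bring the median's
    Monte-Carlo error safely below the 10% bound being tested."""
    prior = ClockPrior()
    for truth in (20_000.0, 80_000.0):
        errors = []
        for rep in range(15):
            tips = simulate_clade(
                truth, [0.0] * 10, prior.rate_mean, reference, seed=800 + rep
            )
            est = mcmc_tmrca(tips, prior, ClockMCMCConfig(seed=900 + rep))
            errors.append((est.point - truth) / truth)
        assert abs(np.median(errors)) <= 0.10, f"truth {truth}: {errors}"


def test_effective_sample_size_iid_near_n():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(4000)
    ess = effective_sample_size(x)
    assert ess > 2000


def test_effective_sample_size_autocorrelated_far_below_n():
    rng = np.random.default_rng(9)
    steps = rng.standard_normal(4000)
    walk = np.cumsum(steps)
    assert effective_sample_size(walk) < 400
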