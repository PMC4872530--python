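"""Private-site statistic and mixture-likelihood contamination estimation."""

import math
import random

import numpy as np
import pytest

from mitopaleo.consensus import build_pileup, call_consensus
from mitopaleo.contamination import (
    MixtureMCMCConfig,
    PrivateSite,
    PrivateSiteSet,
    ReferencePanel,
    count_conflicting,
    find_private_sites,
    mixture_estimate,
    mixture_grid_ml,
    mixture_loglik,
    private_site_estimate,
)
from mitopaleo.reference import MT_LENGTH
from mitopaleo.simulate import SimConfig, SimulatedRead, simulate_reads


def _panel_with_freq(consensus_base: str, other: str, count: int, total: int, pos: int):
    """Panel of ``total`` genomes, ``count`` carrying ``consensus_base`` at pos."""
    base_seq = ["A"] * MT_LENGTH
    seqs = []
    for i in range(total):
        seq = base_seq.copy()
        seq[pos - 1] = consensus_base if i < count else other
        seqs.append("".join(seq))
    return ReferencePanel.from_sequences(seqs)


class TestPrivateSites:
    def test_allele_below_threshold_included(self):
        panel = _panel_with_freq("G", "C", 3, 100, pos=500)
        consensus = "A" * 499 + "G" + "A" * (MT_LENGTH - 500)
        sites = find_private_sites(consensus, panel, 0.05)
        assert sites.positions == [500]
        assert sites.sites[0].panel_frequency == pytest.approx(0.03)

    def test_exactly_5pct_excluded(self):
        """The frequency threshold is strict: 5% is not 'below 5%'."""
        panel = _panel_with_freq("G", "C", 5, 100, pos=500)
        consensus = "A" * 499 + "G" + "A" * (MT_LENGTH - 500)
        assert find_private_sites(consensus, panel, 0.05).positions == []

    def test_sample_has_two_nearly_private_sites(
        self, pm1, worldwide_panel
    ):
        """The packaged panel leaves exactly two rare alleles in the sample."""
        sites = find_private_sites(pm1.sequence, worldwide_panel, 0.05)
        assert len(sites) == 2
        assert sites.positions == [1438, 10517]

    def test_consensus_n_sites_ignored(self, worldwide_panel, pm1):
        seq = "N" * 100 + pm1.sequence[100:]
        sites = find_private_sites(seq, worldwide_panel, 0.05)
        assert sites.positions == [1438, 10517]


class TestConflictCounting:
    def _site(self):
        return PrivateSiteSet(
            sites=[PrivateSite(position=1438, allele="G", panel_frequency=0.01)],
            freq_threshold=0.05,
        )

    def test_all_matching_reads(self):
        reads = [
            SimulatedRead(start=1437, length=1, strand="+", bases="G")
            for _ in range(10)
        ]
        assert count_conflicting(reads, self._site()) == (0, 10)

    def test_one_in_77_conflicts(self):
        """The headline fixture: 77 covering reads, one conflicting base."""
        reads = [
            SimulatedRead(start=1437, length=1, strand="+", bases="G")
            for _ in range(76)
        ] + [SimulatedRead(start=1437, length=1, strand="+", bases="T")]
        assert count_conflicting(reads, self._site()) == (1, 77)

    def test_non_covering_reads_ignored(self):
        reads = [
            SimulatedRead(start=0, length=10, strand="+", bases="G" * 10),
            SimulatedRead(start=1430, length=10, strand="+", bases="G" * 10),
        ]
        assert count_conflicting(reads, self._site()) == (0, 1)

    def test_read_n_bases_excluded(self):
        reads = [SimulatedRead(start=1437, length=1, strand="+", bases="N")]
        assert count_conflicting(reads, self._site()) == (0, 0)

    def test_conflict_rate_tracks_contamination(self, pm1, contaminant, worldwide_panel):
        """At c=0.2 the conflicting fraction sits near 0.2 (binomial noise)."""
        reads = simulate_reads(
            pm1,
            SimConfig(
                target_mean_depth=33,
                contamination_fraction=0.2,
                contaminant=contaminant,
                seed=41,
            ),
        )
        sites = find_private_sites(pm1.sequence, worldwide_panel, 0.05)
        k, n = count_conflicting(reads, sites)
        sd = math.sqrt(0.2 * 0.8 / n)
        assert abs(k / n - 0.2) < 3 * sd


class TestPrivateSiteEstimate:
    def test_reproduces_headline_statistic(self):
        """1 conflicting of 77 -> 1.3% with a truncated-Wald 0-3.8% CI."""
        est = private_site_estimate(1, 77)
        assert round(est.c_hat * 100, 1) == 1.3
        assert round(est.ci_low * 100, 1) == 0.0
        assert round(est.ci_high * 100, 1) == 3.8

    def test_zero_conflicts(self):
        est = private_site_estimate(0, 100)
        assert est.c_hat == 0.0
        assert est.ci_low == 0.0

    def test_wald_matches_textbook_formula(self):
        """Independent re-derivation: p +/- z * sqrt(p(1-p)/n)."""
        from scipy.stats import norm

        est = private_site_estimate(10, 100, method="wald")
        p = 10 / 100
        z = norm.ppf(0.975)
        half = z * math.sqrt(p * (1 - p) / 100)
        assert est.ci_low == pytest.approx(p - half, abs=1e-12)
        assert est.ci_high == pytest.approx(p + half, abs=1e-12)

    def test_wilson_and_exact_available(self):
        wilson = private_site_estimate(1, 77, method="wilson")
        exact = private_site_estimate(1, 77, method="exact")
        # Wilson and Clopper-Pearson lower bounds are strictly positive here
        assert wilson.ci_low > 0.0
        assert exact.ci_low > 0.0
        assert wilson.ci_high != exact.ci_high

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="n_total"):
            private_site_estimate(0, 0)


class TestMixtureLikelihood:
    def _toy(self):
        consensus = "A" * MT_LENGTH
        g1 = "C" + "A" * (MT_LENGTH - 1)  # differs from consensus at pos 1
        g2 = "A" * MT_LENGTH
        panel = ReferencePanel.from_sequences([g1, g2])
        reads = [
            SimulatedRead(start=0, length=4, strand="+", bases="AAAA"),
            SimulatedRead(start=0, length=4, strand="+", bases="CAAA"),
            SimulatedRead(start=100, length=4, strand="+", bases="AAAA"),
        ]
        return reads, consensus, panel

    def test_hand_computed_toy_value(self):
        """Two-genome panel, three reads: direct arithmetic reproduction."""
        reads, consensus, panel = self._toy()
        c, eps = 0.3, 0.01
        m, x = 1 - eps, eps / 3

        def p(matches, mismatches):
            return m**matches * x**mismatches

        expected = (
            math.log((1 - c) * p(4, 0) + (c / 2) * (p(3, 1) + p(4, 0)))
            + math.log((1 - c) * p(3, 1) + (c / 2) * (p(4, 0) + p(3, 1)))
            + math.log((1 - c) * p(4, 0) + (c / 2) * (p(4, 0) + p(4, 0)))
        )
        got = mixture_loglik(reads, consensus, panel, c=c, eps=eps, trim=0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_c_zero_reduces_to_consensus_likelihood(self):
        reads, consensus, panel = self._toy()
        eps = 0.01
        got = mixture_loglik(reads, consensus, panel, c=0.0, eps=eps, trim=0)
        expected = (
            4 * math.log(1 - eps)
            + 3 * math.log(1 - eps)
            + math.log(eps / 3)
            + 4 * math.log(1 - eps)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_loglik_decreasing_in_c_for_endogenous_read(self):
        """A read matching the consensus and conflicting with every panel
        genome makes the likelihood monotone decreasing in c."""
        consensus = "A" * MT_LENGTH
        panel = ReferencePanel.from_sequences(["C" * MT_LENGTH, "G" * MT_LENGTH])
        reads = [SimulatedRead(start=0, length=4, strand="+", bases="AAAA")]
        grid = np.linspace(0.0, 1.0, 101)[:-1]
        values = [
            mixture_loglik(reads, consensus, panel, c=float(c), eps=0.01, trim=0)
            for c in grid
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_order_invariance(self, pm1, contaminant, mixture_panel):
        reads = simulate_reads(
            pm1,
            SimConfig(
                target_mean_depth=4,
                contamination_fraction=0.2,
                contaminant=contaminant,
                seed=53,
            ),
        )
        shuffled = reads.copy()
        random.Random(0).shuffle(shuffled)
        ll_a = mixture_loglik(reads, pm1.sequence, mixture_panel, 0.1, 0.01)
        ll_b = mixture_loglik(shuffled, pm1.sequence, mixture_panel, 0.1, 0.01)
        assert ll_a == ll_b

    def test_empty_panel_rejected(self, pm1, clean_reads):
        panel = ReferencePanel(
            n_genomes=2, frequencies=np.zeros((MT_LENGTH, 4)), sequences=None
        )
        with pytest.raises(ValueError, match="sequences"):
            mixture_loglik(clean_reads, pm1.sequence, panel, 0.1, 0.01)


class TestMixtureEstimate:
    def test_uncontaminated_posterior_near_zero(self, pm1, mixture_panel):
        reads = simulate_reads(
            pm1, SimConfig(target_mean_depth=2000 * 60 / MT_LENGTH, seed=61)
        )
        cons = call_consensus(build_pileup(reads))
        est = mixture_estimate(reads, cons, mixture_panel, MixtureMCMCConfig(seed=62))
        assert est.c_hat < 0.05
        assert est.ci_low == 0.0

    def test_grid_ml_agrees_with_posterior_mode(self, pm1, contaminant, mixture_panel):
        reads = simulate_reads(
            pm1,
            SimConfig(
                target_mean_depth=2000 * 60 / MT_LENGTH,
                contamination_fraction=0.2,
                contaminant=contaminant,
                seed=77,
            ),
        )
        cons = call_consensus(build_pileup(reads))
        est = mixture_estimate(reads, cons, mixture_panel, MixtureMCMCConfig(seed=78))
        c_ml, _ = mixture_grid_ml(reads, cons, mixture_panel, trim=15)
        # under the uniform prior the posterior mode is the MLE; the chain's
        # highest-posterior visited point estimates it
        assert abs(est.map_c - c_ml) <= 0.01

    def test_estimate_recovers_truth(self, pm1, contaminant, mixture_panel):
        reads = simulate_reads(
            pm1,
            SimConfig(
                target_mean_depth=2000 * 60 / MT_LENGTH,
                contamination_fraction=0.2,
                contaminant=contaminant,
                seed=81,
            ),
        )
        cons = call_consensus(build_pileup(reads))
        est = mixture_estimate(reads, cons, mixture_panel, MixtureMCMCConfig(seed=82))
        assert est.ci_low <= 0.2 <= est.ci_high
        assert est.converged
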