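# mitopaleo

Analysis toolkit for ancient human mitochondrial genomes, built around the
computational workflow used to authenticate and interpret a deeply sequenced
Paleolithic mitogenome: simulation of damaged ancient reads, consensus
calling, deamination-based authentication, contamination estimation by two
independent methods, diagnostic-site haplogroup classification, and
tip-dated molecular-clock TMRCA estimation.

It is aimed at researchers and students in ancient DNA and mitochondrial
phylogeography who want a small, fully testable implementation of this
pipeline whose every stage can be validated against simulation truth.

## What it computes

**Consensus and authentication.** Aligned reads over the 16,569-bp circular
mitochondrial reference frame are piled up per site; the consensus is the
plurality base subject to depth and support thresholds. Post-mortem
deamination leaves C→T misincorporations at read 5′ ends (G→A at 3′) whose
rate decays geometrically with distance from the fragment end,
*δ(i) = δ₀·λⁱ*; the package measures this profile against the sample's own
consensus, fits (δ₀, λ), and renders an ancient-consistent verdict.

**Contamination, two ways.** (1) At *nearly private sites* — positions where
the consensus allele has frequency < 5% in a worldwide panel of *n* = 311
mitogenomes — essentially every contaminant molecule carries the common
allele, so the fraction of reads conflicting with the consensus estimates
the contamination fraction *c* directly, with a truncated-Wald binomial CI
(Wilson/exact available). (2) A read-level Bayesian mixture model: each read
derives from the consensus with probability 1−*c* or from one of *K* panel
mitogenomes with probability *c*/*K*, with i.i.d. per-base error ε;

&nbsp;&nbsp;&nbsp;&nbsp;L = ∏ᵣ [(1−c)·P(r | cons, ε) + (c/K)·Σₖ P(r | panelₖ, ε)],
&nbsp;&nbsp;&nbsp;&nbsp;P(r | s, ε) = (1−ε)^matches · (ε/3)^mismatches,

sampled by Metropolis-Hastings under uniform priors, reporting the
posterior mean and 95% HPD interval.

**Haplogroup and archaic screening.** Substitutions against the reference
(labels like `T10517A`) are matched to a PhyloTree-style diagnostic-site
table covering the lineage path N → R → U → U6 and its derived branches
(U6a'b'd, defined by 16219; U6c, defined by eleven sites; U5 as the sister
clade). A haplotype carrying a clade's diagnostics but none of its derived
branches' is *basal* (e.g. `U6*`). The variant list is also screened
against 63 archaic-diagnostic positions (sites at which archaic mitogenomes
are fixed for an allele absent in moderns) and against the panel for
private mutations.

**Tip-dated TMRCA.** For aligned mitogenomes with known ages (years BP),
the clade age is estimated by the rho statistic (mean substitution count
to a root haplotype, scaled by *L·μ*) and by MCMC over root age and clock
rate on a star topology with a Jukes-Cantor pruning likelihood and a
truncated-normal rate prior (default mean 2.06×10⁻⁸, SD 1.94×10⁻⁹
substitutions/site/year), reporting the posterior median and 95% HPD.

The packaged reference sequence is a *synthetic* stand-in on the true rCRS
coordinate frame (see `mitopaleo/reference.py`); all analyses are
parameterised by the reference, so a real sequence can be substituted
directly.

## Worked example

```bash
mitopaleo simulate --depth 33 --seed 1 --out reads.sam
mitopaleo consensus reads.sam --out-fasta cons.fasta
mitopaleo damage reads.sam cons.fasta
mitopaleo haplotype cons.fasta
```

The simulator draws ~9,100 reads (mean fragment 60 bp) from the packaged
15-substitution basal-U6 haplotype with 30% terminal deamination. The
commands above print:

```
wrote 9113 reads to reads.sam
mean coverage 33.18x; 0 uncalled sites
ancient-consistent: terminal C->T 0.296, G->A 0.321 (threshold 0.05); monotone decline: yes; fitted delta0=0.215 lambda=0.656
{
  "n_variants": 15,
  "variants": ["G73A", "G263A", "G750A", "A1438G", "T3348C", "G8701A",
               "A9540G", "A10398G", "T10517A", "G11467A", "A12308G",
               "T12372C", "T12705C", "T16172C", "G16223A"],
  "haplogroup": "U6*",
  "basal": true,
  "archaic_matches": 0,
  "archaic_sites_screened": 63,
  "private_mutations": ["T10517A"]
}
```

That is: the consensus recovers all 15 substitutions of the source
haplotype; the damage profile is ancient-consistent with ~30% terminal
C→T; the haplotype carries the two U6-defining mutations (3348, 16172) but
no derived-branch diagnostics, so it is called basal `U6*`; none of the 63
archaic-diagnostic alleles appear; and `T10517A` is absent from the
311-genome panel, i.e. private. Running the private-site contamination
statistic on 1 conflicting read among 77 covering two nearly-private sites
gives 1.3% (95% CI 0–3.8%).

The full pipeline (`mitopaleo run`) writes a deterministic JSON report with
every threshold and seed used.

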