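# Methods

This note documents the models, parameter defaults, and design choices
behind each stage, and what the simulation-based tests do and do not
establish.

## Reference frame and packaged fixtures

All coordinates are 1-based positions on the 16,569-bp circular human
mitochondrial reference frame (0-based internally). The packaged reference
*sequence* is synthetic: a fixed-seed pseudo-random sequence with
human-mtDNA-like base composition (A 30.9%, C 31.3%, G 13.1%, T 24.7%),
checksum-verified at load. Position 10517 is pinned to T so the packaged
private-mutation fixture carries its canonical label `T10517A`. Because
every analysis takes the reference as input, substituting a real reference
sequence changes no code. Consequences of the synthetic stand-in: variant
*labels* and diagnostic-site alleles are internally consistent but not
literally those of the real mitochondrial phylogeny; positions, counts,
tree topology of the clade definitions, and all statistical behaviour are
unaffected.

The sample haplotype fixture carries 15 substitutions. Three are
well-established public knowledge for a basal-U6 Paleolithic mitogenome
(the U6-defining transitions at 3348 and 16172, and the private mutation
T10517A); the other twelve are placeholders marked `source=inferred` in
the data file, chosen so the haplotype carries the full diagnostic path
N → R → U → U6 plus four non-diagnostic changes. Diagnostic alleles
without a conventionally fixed base default to the transition of the
reference base.

The 63 archaic-diagnostic positions are not hard-coded: they are derived
at runtime by `derive_diagnostic_sites` from ten synthetic archaic
genomes (fixed transversions at 63 positions disjoint from all other
fixtures) against a reference-only modern panel — the same operation a
user would run on real archaic mitogenomes.

## Read simulation

Reads are drawn uniformly from the circular genome; fragment lengths are
truncated-normal (mean 60 bp, SD 15, minimum 20 — typical for ancient
mtDNA); read count is `round(depth·L/mean_length)` so realized depth
matches the target in expectation. Defaults describe a deeply sequenced
Paleolithic sample from a non-UDG double-stranded library: 33× depth, 30%
terminal C→T deamination (δ₀ = 0.30) decaying geometrically with λ = 0.60
per position, sequencing error 0.002/base, contamination 0. Damage is
applied in molecule orientation (for minus-strand reads the stored
reference-orientation bases are reverse-complemented first), then
sequencing error. Contaminant reads (probability *c* per read, independent
Bernoulli) are undamaged by default — a modern contaminant — toggleable.
A single seed drives one `numpy` generator consumed sequentially, so
identical configurations are byte-identical.

Not emulated: indels, quality-score variation, reference bias from
mapping, library duplicates, UDG chemistry. Tests passing on these
simulations therefore validate the estimators under their stated models,
not robustness to alignment artefacts.

## Consensus

Plurality call with `min_depth=3` and `min_support=0.6` (no published
thresholds exist for this kind of pipeline step; these are conservative
commonplace values). Ties break toward the reference allele, then
alphabetically — reference bias made explicit and testable rather than
left to hash order. Sites failing thresholds are N and excluded from
variant lists (reported separately). An optional damage-aware mode was
considered and rejected: at 33× with δ₀ ≤ 0.3 the plurality call is
already correct at every site in practice (verified empirically), so the
extra mode would be untestable dead weight here.

## Damage authentication

Mismatch rates are computed against the sample consensus, not the
reference, so true variants are not counted as damage. Default window
P = 15 terminal positions; verdict threshold `min_terminal_rate = 0.05`
(inclusive), plus monotone decline within 3-SD binomial noise. The decay
fit is weighted least squares of log-rate on position. Known limitation:
with a sequencing-error floor (ε/3 per specific substitution) the distal
positions flatten the fitted line, biasing δ₀ downward and λ upward (at
defaults: fitted ≈ 0.20/0.67 for truth 0.30/0.60). The fit is exact on
noiseless geometric input; for accurate magnitudes on error-bearing data,
fit a shorter window or subtract the background first. The authentication
verdict depends only on the terminal rates and monotonicity and is
unaffected.

## Contamination

**Private-site statistic.** Sites where the consensus allele has panel
frequency strictly below 5% (the threshold is exclusive by definition of
"below"). The count is of read-site incidences; a read spanning both
private sites contributes two observations (toggleable to per-read
counting — the convention is ambiguous in the field and documented here).
The default interval is the Wald normal approximation truncated to [0, 1];
this (and not Wilson or Clopper-Pearson) reproduces the canonical
1 / 77 → 1.3% (0–3.8%) worked example, and both alternatives are exposed.

**Mixture model.** Per-read two-component mixture with uniform weights
over the K panel genomes and a free error rate ε shared by all
components. Damage-affected terminal positions are excluded from the
likelihood; the exclusion window (15) matches the damage-profile window,
beyond which residual deamination at default parameters is ≈ 3×10⁻⁴ per
read end and indistinguishable from sequencing error. Priors:
c ~ U(0, 1), ε ~ U(10⁻⁵, 0.1). Sampling is component-wise Metropolis with
reflecting Gaussian proposals; step sizes adapt toward ~44% acceptance
during burn-in only, so retained samples target the exact posterior.
Default 5,000 iterations, 1,500 burn-in (ESS typically several hundred;
ESS < 100 sets a non-convergence flag). The likelihood is evaluated on
sufficient statistics: per-read (compared, mismatch) count differences
between each panel genome and the consensus, with uninformative reads
dropped analytically and identical rows aggregated.

**HPD at the boundary.** c is bounded below by 0, and a sample-window HPD
can exclude an arbitrarily thin sliver above a boundary the continuous
high-density region genuinely reaches. The reported interval is therefore
extended to 0 whenever the empirical posterior density at 0 is at least
half the density at the HPD cutoff (estimated on a window of 1/20 the
interval width). For interior posteriors the rule never fires; for
boundary-concentrated posteriors it restores the intended interpretation.

**What the calibration shows.** With the contaminant present in an
8-genome panel, ~30 discriminating sites, and 2,000 reads, the 95%
credible interval covers the truth in ≥ 90% of seeded replicates at
c ∈ {0, 0.05, 0.2}, and the chain's MAP agrees with an independent grid
maximum-likelihood search within 0.01. With only two private sites at
33×, the private-site statistic rests on ~66 read-site observations and
carries binomial noise of a few percent — the two estimators' intervals
overlap on shared data, but occasional tail draws are expected and the
tests allow them at the nominal rate.

## Haplogroup classification

The clade table is an editable TSV (name, parent, position, ref, alt).
Classification returns the deepest clade whose *own* diagnostic set is
fully carried; missing diagnostics on ancestral clades are reported but
not fatal (back-mutations occur in real data). Equal-depth full matches
on sibling branches are flagged ambiguous with the better path-score
(then lexicographic) reported. The basal flag is set when the called
clade has defined children and none is fully matched; it renders as a
`*` suffix (`U6*`). Private mutations are variants whose alternate allele
has panel frequency exactly 0; sites with no panel data are excluded
(privacy cannot be asserted).

## Tip-dated clock

Units are enforced: ages in years BP, rates in substitutions/site/year.

The rho estimator dates the root as the mean over tips of
`age_i + d_i/(L_i·μ)` with `d_i` the substitution count to the root
haplotype over the L_i comparable sites; its SE follows from Poisson
counts on a star genealogy.

The Bayesian estimator fixes the topology — the package does not infer
trees. The default is a star tree (a reasonable stand-in for a rapid
radiation, validated here by simulation); alternatively a user-supplied
Newick fixes the tree shape, with internal-node ages scaling
proportionally with the root age (relative depths taken from the input
branch lengths) and tip ages held fixed. Root age and rate are sampled by
component-wise Metropolis with the same burn-in-only adaptation. Root-age prior: uniform on (oldest tip age,
200 ky); rate prior: normal truncated at 0, default mean 2.06×10⁻⁸ and
SD 1.94×10⁻⁹ — the rate is treated as a whole-molecule per-year rate.
Likelihood: Jukes-Cantor via Felsenstein pruning on site patterns
(pattern compression makes one evaluation O(patterns·tips·4); a general
fixed-topology pruning routine is provided and verified against explicit
enumeration on 4-taxon toys). HKY is a deliberate non-feature: with
mitogenome-scale data and the shallow timescales here, JC vs HKY moves
the age estimate far less than the rate prior does.

Calibration: across seeded star simulations (truth 50 ky, 20 tips
including one at 35 ky), the 95% HPD covers the truth in ≥ 90% of
replicates and the rho and posterior-median estimates agree within two
combined standard errors. The published-scale worked example in the
acceptance script (truth 50 ky) yields a point estimate near 50 ky with
an HPD of roughly ±8–10 ky — the same order as published intervals for
mitochondrial clade ages of this depth, as expected since the rate prior
dominates the uncertainty.

HPD intervals everywhere are the shortest contiguous interval containing
95% of posterior samples; the effective sample size uses Geyer's initial
positive sequence estimator.

## Numerical conventions

- Consensus tie-breaks: reference allele, then A > C > G > T.
- Binomial intervals truncated to [0, 1]; `n_total = 0` is an error, not
  a silent zero.
- Degenerate damage profiles: all-zero rates fit δ₀ = 0 with λ undefined
  (NaN); a single usable position yields no decay estimate.
- Pattern products are computed in linear space (safe for ≤ ~100 tips in
  float64); likelihood mixes use log-sum-exp.
- All MCMC output is seeded and byte-reproducible; every report records
  the seeds and thresholds used.

## Problem sizes used in tests

Unit tests run at 4–60× simulated depth on the full 16,569-bp molecule;
calibration studies use 50 seeded replicates per condition (2,000 reads
for the mixture estimator; 20 tips for the clock), sizes at which the
intervals under test are a few percent (contamination) or a few thousand
years (TMRCA) wide — informative about calibration while keeping the
whole suite in the minutes range on one CPU.
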