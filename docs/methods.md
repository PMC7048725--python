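# Methods

This note documents the statistical models implemented in `strassign`, the
choices made where conventions differ between the field's standard
programs, and what the synthetic-data generator does and does not emulate.

## Data model

Markers are codominant, diploid length polymorphisms (microsatellites).
Allele labels are arbitrary non-negative integers, typically fragment
sizes; no binning or size calling is performed — that is upstream
laboratory work. Missingness is per locus, never per single allele: a
half-called locus is demoted to missing, because a lone allele call cannot
distinguish a homozygote from a dropout-affected heterozygote. Every
individual must be typed at one locus or more.

Two GRDB hygiene screens are provided, both reporting pairs rather than
deleting anything (exclusion is an explicit, auditable step):

* **duplicates** — identical unordered allele pairs at every mutually
  typed locus, with a configurable minimum number of shared loci
  (default: the full locus list, i.e. complete-profile identity; the
  tolerance for missing loci is a user decision);
* **first-order relatives** — pairs sharing at least one allele at every
  mutually typed locus, the necessary condition for parent–offspring
  pairs. Unrelated pairs can satisfy it by chance; with 10 reasonably
  diverse loci the false-positive rate is small (the test suite checks the
  empirical rate against the exact product of per-locus sharing
  probabilities).

## Diversity statistics

Per population and locus: number of alleles Na; effective alleles
Ne = 1/Σp²; observed heterozygosity Ho (fraction of typed individuals with
two distinct alleles); expected heterozygosity He = 1 − Σp²; unbiased
expected heterozygosity uHe = 2N/(2N−1)·He with N the typed individuals.
Population summaries are means and SDs across loci, ignoring loci with no
data in that population.

**Allelic richness** is rarefied to a standard sample of n individuals
(2n gene copies): AR = Σ_i [1 − C(2N−N_i, 2n)/C(2N, 2n)], each term the
probability that allele i (with N_i copies among the 2N sampled genes)
appears in a random draw of 2n genes. The default n per locus is the
minimum across populations of individuals typed there, the convention of
rarefaction-based software, so every population supports the draw.

**FIS** defaults to (uHe − Ho)/uHe per locus, averaging over polymorphic
loci; the uncorrected alternative (He − Ho)/He is available because the
major packages disagree on the denominator and published tables rarely
state which was used. Neither variant is asserted against any published
value.

**Hardy–Weinberg exact test.** The null distribution is Levene's
conditional distribution of genotype arrays given the observed allele
counts; the p-value is the total probability of arrays no more probable
than the observed one. The implementation enumerates the full array space
when a cheap bound on its size is below a cap (50 000 by default) and
otherwise estimates p by Monte Carlo: each iteration randomly re-pairs the
2N gene copies into N genotypes, which is an exact draw from the Levene
distribution, so no Markov-chain burn-in or mixing argument is needed; the
binomial standard error is reported. p-values are reported raw;
multiple-testing adjustment is left to the caller.

## Assignment

The Rannala–Mountain criterion scores a query genotype against each
candidate unit using the Dirichlet posterior-predictive genotype
probability with uniform prior mass 1/K per allele (formulas in the
README). Two conventions matter:

* **K per locus** counts distinct alleles over the reference *and* query
  data jointly. A query allele never seen in the reference still receives
  prior mass; excluding it would zero the likelihood everywhere and make
  the score undefined.
* **The threshold is strict** (best score > 70 %, not ≥): scores exactly
  at the threshold are unassigned.

Likelihoods are accumulated in log space and scores normalized after
subtracting the maximum, so underflow cannot occur. Missing query loci are
skipped.

**Leave-one-out validation** removes the focal individual's two gene
copies per locus from its own unit's counts (full exclusion, not
down-weighting) and re-scores it against all units. Reported are the
percentage of individuals whose best unit is their true unit and the
*quality index* — the mean score (%) awarded to the true unit, which
penalizes confident misassignment more than the hit rate does. Individuals
in singleton units are skipped with a note.

**Exclusion p-values** simulate genotypes from a unit's
posterior-predictive distribution (sequential Pólya draws, exactly the
compound-Dirichlet distribution the likelihood integrates over) and report
(1 + #{simulated ≤ observed})/(n_sim + 1) on the log-likelihood scale —
never exactly zero. Alleles unseen in the unit are handled as
exchangeable prior-mass categories. A unit is "excluded" at p < 0.05.

## Admixture clustering

The sampler is the standard admixture model for unlinked codominant loci:
cluster label Z per gene copy, allele frequencies P per cluster and locus,
admixture vector Q per individual, symmetric Dirichlet(α) prior on Q with
α learned by a Metropolis random walk on log α (uniform prior on (0.001,
10)). Two frequency priors are available:

* **independent** — flat Dirichlet(1) per cluster and locus;
* **correlated (default)** — an F-model: P_kl ~ Dirichlet(p_anc,l ·
  (1−F_k)/F_k) with one drift parameter F_k per cluster, updated by
  Metropolis on log F. The ancestral frequencies p_anc are fixed at the
  pooled empirical frequencies rather than sampled — a documented
  simplification; bit-compatibility with the original admixture software
  is not claimed. F is initialized at 0.3: a small initial F makes the
  prior concentration (1−F)/F overwhelm the data likelihood before
  clusters separate, trapping the chain near the symmetric mode.

* **LOCPRIOR-lite** — optionally, the prior mean of Q_i mixes a symmetric
  component with the sampling location's current mean membership with
  weight r (default 0.7), a simplified form of location-informed priors
  for data sets where structure is weak.

The per-run model evidence is estimated as mean(lnL) − var(lnL)/2 over
post-burn-in samples of the complete-data likelihood — the harmonic-style
estimator conventional in this literature, used only to compare K values,
not as an absolute evidence. At K = 1 it agrees with the exact
Dirichlet-multinomial evidence (tested). **ΔK** is the absolute second
difference of mean lnP across K divided by the between-run SD at K;
endpoints of the K range get no ΔK, and a zero SD is reported as infinite.
Replicate runs at one K are aligned by column permutation maximizing the
Q dot-product similarity to the first run (exhaustive over permutations
for K ≤ 6, greedy beyond), the strategy of CLUMPP's greedy mode.

Chain-length guidance: the lnP estimator needs enough post-burn-in samples
for its variance term to stabilize; the package's own analyses use 800
sweeps after a burn-in of 250 with thinning 5 on databases of ~60
individuals, and the test suite verifies that doubling the chain moves
posterior-mean Q by less than the Monte Carlo error. Production analyses
on real data should use order-of-magnitude longer chains (the scale is
configuration, not code).

## Synthetic data

The generator draws ancestral frequencies per locus from a flat Dirichlet,
cluster frequencies from Dirichlet(p_anc·(1−F_c)/F_c), locality
frequencies from Dirichlet(p_cluster·(1−F_l)/F_l), and genotypes in
Hardy–Weinberg proportions within localities. This hierarchical
Dirichlet drift model matches the correlated-frequencies assumption of
the clustering model and gives closed-form calibration targets: the
drift parameter approximates the corresponding FST level (checked against
a Weir–Cockerham estimate within ±0.02). Defaults are study-shaped: 3
clusters holding (2, 4, 9) localities, 12 individuals per locality (180
total), 10 loci, 8 alleles per locus, F_c = 0.15, F_l = 0.03.

What it does **not** emulate: mutation dynamics (no stepwise-mutation
process), migration or admixed individuals, null alleles, stutter, or
linkage — so passing tests demonstrate correctness of the statistical
machinery under the model's own assumptions, not robustness to every
artifact of real microsatellite data. Real-data deviations (relatives in
the sample, departures from HW, uneven sampling) will generally lower
assignment accuracy relative to the synthetic figures.

**Dropout/consensus model.** Each allele of a true genotype drops
independently with probability d per amplification; a heterozygote with
one dropped allele is observed as a homozygote (false homozygote with
probability 2d(1−d)/(1−d²) given a non-missing call). The protocol
amplifies heterozygous calls twice and apparent homozygotes four times and
confirms an allele only when seen in two or more amplifications; one
confirmed allele after the full homozygote schedule is called homozygous,
zero or three-plus confirmed alleles are flagged unresolved, and one
confirmed allele on a short schedule requests more replicates (topped up
to the homozygote schedule, with a bounded number of extra rounds, before
the locus is declared missing). The suite verifies the protocol's
false-homozygote rate is below the single-amplification rate across
dropout rates in (0, 0.5).

## Pipeline and reproducibility

All stochastic components take explicit seeds; per-run seeds for Evanno
replicates derive deterministically from the base seed. The pipeline
writes only CSV/JSON (plots are optional extras) and a manifest with the
configuration and its hash; identical configuration and seeds give
byte-identical CSVs (tested). Stage failures abort with the stage name;
partial outputs are retained.

## Known limitations

* The F-model fixes ancestral frequencies at pooled empirical values and
  shares no hierarchical prior across F_k; with very few populations the
  drift estimates are crude.
* The evidence estimator is biased for short chains; ΔK comparisons
  should use equal chain lengths across K (the pipeline does).
* Exclusion p-values condition on the reference counts and ignore
  sampling error in the reference itself, as is conventional.
* The HWE enumeration cap is heuristic; extremely allele-rich loci fall
  back to Monte Carlo even when enumeration might be feasible.
* Locality-level assignment accuracy on weakly differentiated localities
  is intrinsically low; the package reports it honestly rather than
  smoothing over it.
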