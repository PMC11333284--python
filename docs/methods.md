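# Methods

This note documents the statistical models, numerical choices and design
decisions behind `rareburden`, in the spirit of the model documentation of
packages like statsmodels or msprime.  It states no empirical results; every
number the package claims is computed by the test suite or by
`scripts/acceptance.py`.

## Cohort database and rarity filtering

The cohort store holds participants (pedigree links, affection, disease-class
labels, HPO terms, ICD10 codes, solved status), transcripts (single-exon
spans with strand), and rare variants with sparse genotype dosages.  Inputs
are standard files: a multi-sample VCF, a six-column PED, a phenotype TSV and
a transcript TSV.  Multi-allelic VCF records are decomposed into one variant
per alternate allele with shared-suffix/prefix trimming; full left-alignment
against a reference genome is not attempted because the pipeline's inputs do
not include a FASTA (for the short single-exon transcripts targeted here,
trimming is sufficient and tested).  Only PASS records overlapping a listed
transcript are stored.  Missing genotypes are retained as missing: burden
computations treat them as zero copies, while inheritance classification
treats them as unknown.

**pMAF.**  The probabilistic minor allele frequency of a variant observed
`ac` times among `an` called alleles is the upper 99% quantile of the flat
prior Beta(ac+1, an−ac+1) posterior on its population frequency, maximized
over all supplied allele-count sources (the quantile level is configurable).
The database assigns each stored variant's pMAF from external reference
counts carried in the VCF INFO fields `EXTAC`/`EXTAN` (gnomAD-style) when
present, falling back to the internal cohort counts otherwise.  This matters:
in a case-enriched cohort a fully penetrant recurrent pathogenic variant can
be carried by dozens of cases, so an internal-frequency filter would discard
exactly the variants the analysis exists to find, whereas population
reference panels keep them rare.  The rarity thresholds are 0.01% for the
dominant model and 0.1% for the recessive model.

**Case/control construction.**  One case is selected per family containing at
least one member of the target disease class (lexicographically smallest
such member — a deterministic stand-in for earliest enrollment).  Controls
are one member from each remaining family (preferring genotyped, then
phenotype-annotated members, then the smallest identifier).  Relatedness is
inferred from family identifiers only; kinship estimation is out of scope.
By construction the case and control sets are disjoint and mutually
unrelated.

## Gene-level Bayesian association

Three models are compared per gene with prior probabilities 0.99 / 0.005 /
0.005 (no association / dominant / recessive), so the overall prior
probability of association is 0.01.

Let y be the case indicator over the n selected unrelated participants and G
the n×J dosage matrix over the mode's qualifying variants.  The generative
model is:

- z_j ~ Bernoulli(ω) i.i.d., ω ~ Beta(2, 8) — latent pathogenicity of
  variant j;
- carrier indicator x_i = 1 iff participant i holds ≥1 pathogenic allele
  (dominant) or ≥2 pathogenic alleles, summed over pathogenic variants
  (recessive, which thereby covers homozygotes and compound heterozygotes
  without phasing);
- y_i | x_i ~ Bernoulli(τ if x_i else τ₀), τ₀ ~ Beta(1, 99), τ ~ Beta(3, 1).

τ₀, τ and ω integrate analytically given z, leaving

log P(y | z) = log B(a₀+s₀, b₀+n₀−s₀) − log B(a₀, b₀)
             + log B(a₁+s₁, b₁+n₁−s₁) − log B(a₁, b₁)

with (n₁, s₁) the carrier count and the cases among carriers, and
log P(z | k pathogenic) = log B(a_ω+k, b_ω+J−k) − log B(a_ω, b_ω).  The
hyperparameter defaults encode: a ~1% baseline case probability, high but
uncertain penetrance, and an expectation that a minority (~20%) of qualifying
variants are pathogenic.  All are configurable.

**Exact sum.**  For J ≤ 12 (4,096 configurations) the sum over z is exact.
Configurations are visited in Gray-code order so each step toggles one
variant; per-participant pathogenic-allele counts are updated sparsely over
that variant's carriers, and the (n₁, s₁) → log-likelihood map is memoized.
Variant-level posteriors P(z_j = 1 | y) come from the same enumeration.

**Collapsed Gibbs above the exact limit.**  z is sampled by systematic-scan
Gibbs with τ₀, τ, ω collapsed.  The marginal likelihood uses a power
posterior ladder π_t(z) ∝ P(z) P(y|z)^t with 11 temperatures t_l =
(l/10)^5, traversed from prior to posterior within each of 4 chains (5,000
sweeps per rung, first 1,000 discarded).  The estimator is stepping-stone:
samples at rung l estimate Z(t_{l+1})/Z(t_l) = E_{t_l}[exp((t_{l+1}−t_l)
log P(y|z))], and the log ratios telescope to the log marginal likelihood
(Z(0) = 1 because the pathogenicity prior is normalized).  Stepping-stone was
chosen over trapezoidal thermodynamic integration because the latter showed a
systematic quadrature bias on this ladder that exceeded the Monte Carlo error
across chains, while stepping-stone's only error is Monte Carlo.  Chain-level
estimates provide a standard error; PPP estimates come from the t = 1 rung.
All mixture computations are in log space with log-sum-exp.

**Outputs.**  Posterior model probabilities (normalized in log space), PPA =
posterior(dominant) + posterior(recessive), the log Bayes factor of the
prior-weighted association mixture against the null, and per-variant PPP
averaged over the two modes weighted by their posterior share of the
association mass (variants absent from a mode contribute zero there).  A gene
with no qualifying variants yields identical marginals under all three
models, hence PPA exactly equal to the 0.01 prior.

## Ontology, similarity and homogeneity

Only `is_a` edges of the OBO file are honored; obsolete terms are dropped;
the graph must be acyclic with a single root.  Annotation sets are closed
under ancestry before any frequency computation, which makes term frequency
monotone nonincreasing from ancestor to descendant and Resnik similarity well
behaved.  Information content is the natural logarithm: IC(t) = −ln f(t),
with f computed over a caller-chosen reference cohort (default: all
HPO-annotated participants).  Terms absent from every closed set carry an
infinite-IC sentinel and are excluded from common-ancestor maxima rather than
allowed to produce infinite similarities.

Resnik similarity is the maximum IC over common ancestors; set similarity is
the symmetric best-match average; the homogeneity of k participants is the
mean over all k-choose-2 pairwise similarities.  The Monte Carlo homogeneity
test draws random subsets of k *participants* (whole annotation profiles, not
terms) without replacement from a reference population and reports the
proportion of draws with homogeneity ≥ observed.  The estimator is the plain
proportion r/n (which can be zero); an (r+1)/(n+1) correction is available
but off by default.  The default draw count is 100,000; the generator is
always explicitly seeded and the seed is recorded in the result.  Groups
containing an empty annotation set are rejected rather than silently scored.
A floating-point tolerance of 1e−12 is applied to the ≥ comparison so that
exact ties (e.g. a population of identical profiles) count as exceedances.

## Transcript mapping, inheritance and regions

Genomic coordinates map to 1-based cDNA coordinates strand-awarely (on the
minus strand n = end − pos + 1 with reverse-complemented alleles).  HGVS
`n.` names are rendered for substitutions, insertions, deletions and delins;
when the transcript sequence is available, indels are normalized to their
3'-most transcript position by right-rolling through repeat context
(duplication notation is not used — recurrent insertions are reported as
`ins`).  Without a sequence, coordinates are rendered unshifted.

Trio classification: a carried allele is de novo iff both parents are
genotyped homozygous reference; inherited maternal/paternal iff the
corresponding parent carries it; unknown iff a parental genotype is missing.
A parent listed in the mosaic-override table converts a de novo call to
`mosaic_parent` while retaining the de novo origin flag (such parents are
hom-ref by genotype and detected only by read inspection, which is out of
scope).  In the degenerate case where both parents carry the allele the call
is `inherited_maternal` by a fixed alphabetical convention; for the allele
frequencies this pipeline filters to, the case does not arise.

The per-base table counts, for each cDNA base, carriers of rare alleles whose
footprint covers the base, stratified into affected-de-novo (including
mosaic-parent), affected-inherited, affected-unknown and unaffected, plus the
number of distinct alternate alleles.  Footprint conventions: insertions
count at their left flanking base; deletions count at every deleted base
(the alternative start-only convention for multi-base deletions is a
documented choice, not derivable from first principles).  Region highlighting
is seed-and-extend: from each seed base (which must have zero unaffected
carriers) extend over consecutive bases with zero unaffected carriers — bases
with no carriers at all extend too — stopping at transcript ends or before
any unaffected carrier, then merge overlaps.  Outputs are sorted disjoint
closed intervals.

## Depletion, enrichment, prevalence

The solved-case depletion test is one-sided binomial: with X ~ Binomial(n,
baseline solve rate) counting solved cases, P = P(X ≤ observed solved).  The
"fewer-or-equal solved" direction is fixed by the use case (a group explained
by a new etiology should contain fewer solved cases than chance).

Term enrichment uses Fisher's two-sided exact test (the sum of all
fixed-margin tables whose point probability does not exceed the observed
table's — conventions for two-sided Fisher differ, so this one is pinned and
oracle-tested against exhaustive enumeration).  Only terms carried by at
least five cases are tested, reduced to the nonredundant set at each
frequency level: within a case-count level, a term that is a strict ancestor
of another term at the same count is implied by closure and dropped.
Multiplicity is handled by Bonferroni multiplication capped at one, exactly;
adjusted P < 0.05 is significant.  The recommended background is the
phenotype-coded unrelated participants excluding the case group; the
denominator of prevalence percentages is a caller parameter because "N coded
cases" may or may not include the case group itself in published usage.

Prevalence ranking merges diagnostic solved counts with per-gene override
counts (for genes whose case count is defined by a variant region rather than
diagnostic classifications), filters by a minimum count, ranks by count with
a gene-name tie-break and renders percentages to two decimals.

The summary term graph contains terms present in at least half the cases or
significantly enriched, reduced per frequency level, together with the
ancestors needed to connect them: the ancestor closure is taken, edges are
transitively reduced, and non-selected pass-through ancestors with a single
child are contracted (the root is kept).  Exports are DOT and GraphML.

## Synthetic cohorts

The generator emulates a trio-based national sequencing programme with a
dominant de novo hotspot in a 141-base single-exon minus-strand gene
(`RNUT1`), alongside neutral background genes:

- case probands carry a hotspot de novo variant with probability
  `de_novo_rate` (default 0.05); 70% of carriers get the recurrent single-base
  insertion after cDNA base 64, the rest random hotspot substitutions;
  parents are homozygous reference, masked missing with probability 0.1 per
  parent, and optionally one parent is flagged mosaic in a sidecar table;
- carriers are affected with probability `penetrance` (default 0.9);
  non-carrier probands are affected by ascertainment;
- affected probands join the `ID` disease class and receive the umbrella
  neurodevelopmental term plus the class term (omitted 10% of the time to
  exercise imputation); causal carriers add a shared six-term profile
  (analogues of intellectual disability, microcephaly, hypotonia, seizures,
  proportionate short stature, motor delay; each with probability 0.85) plus
  Poisson noise terms, inducing the homogeneity signal; everyone draws
  background terms from a weighted pool over a ~50-term toy ontology;
- a small fraction of affected probands are coded only with ICD10 F-codes,
  exercising the code-based affection definition;
- non-carrier cases are "solved" with probability 0.201 (the baseline
  diagnostic solve rate); carrier cases never are;
- every gene receives neutral rare substitutions at `background_rare_rate`
  per participant (default 0.001) at equal rates in cases and controls, with
  gnomAD-style external counts in `EXTAC`/`EXTAN` (60% absent, 20% singleton
  scale passing the dominant filter, 20% too common for the dominant but not
  the recessive filter);
- the unrelated control pool is `n_control_families` singletons.

The causal-gene sequence is adjusted so the recurrent insertion cannot be
3'-shifted, keeping its rendering and footprint at the configured flank.  All
output files are emitted in sorted order, making bundles byte-identical for a
given config; `truth.json` records the config, gene sequences, carriers and
assignments for testing.

What the generator does **not** emulate: linkage disequilibrium, population
structure, sequencing error, genotype-quality variation, realistic
genome-scale variant density, and related individuals beyond trios.  Passing
calibration and recovery tests on these cohorts therefore demonstrates
correctness of the statistical machinery under the stated generative
assumptions, not robustness to artifacts of real sequencing data.

## Study conditions used in calibration and acceptance runs

- Null panels: 20 replicates of 50 genes, 100 case trios + 800 unrelated
  controls (≈1:8 case:control, the ratio regime of large national cohorts),
  background rare-variant rate 0.005 per gene per participant.
- Label permutation: 200 uniform permutations on the most variant-rich gene
  of a null panel.
- Homogeneity uniformity: 500 random groups of k = 6 from ≈150 affected
  profiles, 400 Monte Carlo draws each.
- Recovery: 500 case trios + 5,000 controls, de novo carrier rate 0.05,
  penetrance 0.9, a 10-gene panel; the Gibbs-vs-exact oracle uses a J = 8,
  n = 200 fixture at the default sampler settings.

These sizes are the package's chosen experiment scales; all are parameters of
the corresponding `rareburden.calibration` functions.

The calibration and recovery experiments run their gene tests with the exact
enumeration cutoff raised to 20 variants (`ModelPriors(exact_limit=20)`):
at these cohort sizes enumeration is fast and deterministic even for a gene
that happens to draw many qualifying variants, whereas the default cutoff of
12 would occasionally divert a single variant-rich null gene onto the far
slower stochastic Gibbs path.  The package default stays at 12; the
Gibbs-vs-exact oracle comparison exercises the Gibbs path explicitly (with
8 chains, so the chain-to-chain standard error used as the comparison
yardstick has adequate degrees of freedom).

## Known limitations

- Unrelatedness is family-ID based; cryptic relatedness is invisible.
- The association model ignores covariates, X-linked inheritance and phasing;
  the recessive carrier rule counts unphased pathogenic alleles.
- pMAF assumes external reference counts are from comparable populations.
- The OBO parser honors `is_a` only; cross-ontology mappings and versioning
  are out of scope.
- Exact association inference is exponential in the number of qualifying
  variants; the Gibbs path is stochastic and reports chain-level standard
  errors rather than deterministic values.
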