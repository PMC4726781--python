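# Methods

This note documents the models, rules and numerical choices behind
`pgxconcord`, and what its synthetic-study tests do and do not demonstrate
about real data.

## Sites, genotypes and matching

A variant site is a normalized biallelic (contig, 1-based position, ref,
alt) tuple, optionally annotated with rsID, gene and star-allele tags.
Normalization is purely local: the shared allele suffix is trimmed first,
then the shared prefix (advancing the position), always keeping both
alleles non-empty so indels retain one anchor base. Indel left-alignment
against a reference genome is deliberately **not** performed — the tool
requires no FASTA — so two inputs that place the same indel at different
anchor points will not match. All supported comparisons declare identical
coordinates, which is why local trimming suffices; this is a documented
limitation for arbitrary callsets.

Genotypes are unordered, unphased diploid pairs over {ref, alt, other,
missing}; phase in inputs is discarded (no stage uses it) and non-diploid
records are rejected. Multiallelic records are split into one biallelic
site per alternate allele; in each biallelic view, an allele that is
neither that site's ref nor alt is carried as *other* rather than folded
into the reference class, so cross-allele disagreements surface as
mixed-discordant instead of vanishing.

Cross-platform site matching keys on (contig, position, ref, alt); when
one side carries only an rsID (panel exports often do), rsID matching is
the logged fallback, and one rsID mapping to conflicting coordinates is an
error rather than a silent choice.

## Evaluability rules

All threshold comparisons follow the literal inequality directions of the
validation protocol, with boundary semantics unit-tested explicitly:

| rule | predicate | default |
|---|---|---|
| test evaluable | DP ≥ 4 **and** GQ ≥ 10 | exclusion is strict `<` |
| truth confident | amplicon depth ≥ 10 | inclusive |
| panel confident | call rate > 85% | strictly exclusive |
| tranche cut | FILTER ∈ {pass} or {pass, 99–99.9%} | strict |

Absent evidence always fails a predicate (no default-to-zero). A call
failing both the tranche cut and DP/GQ is counted once, in the
tranche-exclusion bucket: stratification precedes evaluability, which
keeps the two strata's bookkeeping identities exact. Missing DP is
reconstructed as the sum of per-allele read counts when AD is present.

VQSR tranche labels are consumed, never computed. The FILTER dialect maps
`PASS`/`.` to the pass stratum and any string matching
`VQSRTranche*99.00to99.90` to the 99–99.9% tranche; any other non-empty
FILTER maps to the beyond-99.9% stratum with a warning, because an
unrecognized filter must never silently enter the pass stratum. Variant
callers differ in the exact strings they emit, so the dialect is an
ordered, user-extensible regex table.

## Classification and summaries

The decision cascade (tranche → evaluability → no-call → missing truth →
genotype comparison) is total over the matched universe; a test-platform
slot with no record at all is treated as a no-call. Truth no-calls and
truth-confidence failures are pooled into the missing-truth class, with
the sub-reason retained in the per-call report.

Genotype comparison counts alternate-allele copies as multisets. Extra
test copies with none missed are false positives; missed truth copies with
none introduced are false negatives — in particular het-vs-hom-alt is a
false negative (an alt copy went undetected), which is what makes the
operator exactly FP↔FN symmetric under platform swap. Partially missing
genotypes (half-calls) and any *other*-allele involvement are
mixed-discordant: they are neither clean introductions nor clean misses.

Concordance is computed over all evaluated calls (denominator = "total
calls evaluated"). An alternative alt-carrying-only denominator is easy to
derive from the per-call report but is not the default, since the
headline rates are defined over evaluated calls. Reported rates are
rounded half-up to two decimals (`Decimal` arithmetic, not binary-float
rounding). The count identities — total = low-quality + no-calls +
missing-truth + evaluated; evaluated = concordant + FP + FN + mixed — are
asserted after every summary construction.

Adjudication never overwrites a classification: for each Sanger-resolved
discordant pair it records which platform's genotype matches the Sanger
alleles (test correct / truth correct / both wrong), and warns about and
ignores records for non-discordant pairs.

## Off-target distance

Distance to the capture design is measured from the variant's normalized
leftmost position only (one number per site; indel end positions are
ignored). Intervals are stored 1-based closed after BED conversion, merged
and sorted; for position *p* left of [s, e] the gap is s − p, to the right
p − e, and a contig with no targets yields an infinite distance flagged
uncapturable. The default padding radius for invoking an off-target site
is 100 bases, with coverage-by-distance bins flagged when their maximum
aggregate (summed-over-samples) depth falls below 150-fold — the empirical
regime in which coverage beyond the padding is consistently poor. Both
values are configurable, and the tool is capture-kit-agnostic: any BED
defines the design.

## Synthetic studies

The generator emulates the statistical structure the comparison assumes,
not sequencing reads. Per stage (each with an independent child generator
derived from the global seed in a frozen order — sites, true genotypes,
truth observation, test observation, panel observation, targets):

* **Truth genotypes** are drawn per site under Hardy–Weinberg equilibrium
  from a per-site alt frequency (default Uniform(0.05, 0.5), typical of
  common pharmacogene polymorphisms).
* **Truth observation** uses Poisson depths around 250× (amplicon-like);
  a `missing_truth_rate` fraction (default 4%) of calls is absent or
  under-depth, half/half.
* **Test observation** draws depth from a negative binomial
  (mean 50, dispersion 5 — overdispersed capture coverage that naturally
  pushes a few calls under the DP floor), alternate reads from a binomial
  with per-read alt probabilities {ε, ½, 1 − ε} (ε = 0.01), and calls the
  genotype by flat-prior maximum likelihood. GQ is the Phred-scaled
  posterior error of the call, capped at 99, with likelihood ties broken
  toward the lower-dosage class; zero reads give a no-call. Any monotone
  evidence-consistent GQ model would serve; this one is standard and
  checkable against direct enumeration.
* **Tranche-dependent corruption**: each site draws one tranche
  (defaults 27:16:0 across pass / 99–99.9% / beyond); each emitted
  genotype is replaced, with per-tranche probability, by a uniformly
  chosen different genotype class, exercising both FP and FN branches.
  Defaults are 0.004 for pass-filter calls and 0.26 in the tranche —
  the discordance levels of the two strata in the validating experiment
  (3/741 and 133/508). Every corruption is logged in a ledger, making
  error-rate recovery a testable property.
* **Panel observation** copies the true genotypes, corrupts at 1.1%, and
  draws call rates from Beta(38, 2) × 100 (mean ≈ 95%, a small tail below
  the 85% floor). Site subsets can be dropped from the panel or added as
  panel-only to exercise matching in both directions.
* **Targets** place ~80% of sites inside an interval and the rest at
  gaps from 5 to 1000 bases, spanning the padding boundary.

What passing these tests shows: the pipeline's arithmetic, filtering,
stratification and recovery behavior are correct under known error
structure. What they do not show: robustness to alignment artifacts,
pseudogene (e.g. *CYP2D7*) homology contamination, allele-specific capture
bias, structural variation, or tranche labels that correlate with
genotype context — none of which the generator models.

## Numerical and design choices

* Positions are 1-based in memory (VCF convention); BED is converted on
  read, preserving interval lengths.
* Genotype-likelihood arithmetic runs in log space
  (`scipy.stats.binom.logpmf` + log-sum-exp); the posterior error uses
  `expm1` for stability when the call is near-certain.
* Problem sizes in the test suite (up to 50 samples × 120 sites for
  recovery checks, ~10 kb contigs for the per-base distance oracle) are
  chosen so the whole suite exercises every stage in well under a minute
  per module while keeping binomial standard errors small enough for
  3-standard-deviation bounds to be meaningful.
* Stochastic tests fix their seeds; determinism is also asserted directly
  (identical seed + config ⇒ byte-identical emitted files).
* Exit codes: 0 success, 2 data validation, 64 usage. Logs go to stderr;
  output files carry no timestamps (the manifest holds run metadata).

## Known limitations

* No reference-genome-aware indel left-alignment (see above).
* Site-level metrics (sensitivity/precision curves, Ti/Tv) are out of
  scope; the unit of analysis is the per-sample genotype call.
* Star-allele tags are annotations only — no diplotype translation, CNV
  or hybrid-allele resolution.
* The shipped pharmacogene catalog records site identities and tranche
  assignments (rsIDs, regions, star alleles), not coordinates; it
  documents the validated site panel rather than serving as a calling
  target list.
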