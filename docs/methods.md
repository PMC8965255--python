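# Methods

`isoqtl` implements a systems-genetics pipeline for recombinant inbred (RI)
panels: it takes a merged multi-source transcript annotation, per-library
transcript quantification, strain genotypes, and a strain-level phenotype,
and produces coexpression modules and individual transcript isoforms that
satisfy three candidacy criteria linking expression to the trait.  This note
describes the models and procedures, the parameters that matter, and the
choices made where the design was open.

## The genetic setting

An RI panel is a set of inbred strains derived from two progenitors by
repeated sib-mating.  Every strain is homozygous at every locus, so a marker
is a 0/1 vector over strains — its strain distribution pattern (SDP).
Markers with identical SDPs (or identical after swapping allele labels;
single-marker regression is invariant to relabeling) are statistically
indistinguishable and are collapsed to their left-most representative before
scanning (`genotypes.collapse_to_sdp`).  Because each strain is a fixed
genome, the same genotypes can be paired with expression measured in some
animals and a behavioral phenotype measured in others; all association runs
at the strain level.

## Annotation model

Transcripts carry a source label with three levels: `ensembl` (reference
annotation), `stringtie` (splice-graph reconstruction; novel exon chains),
and `aptardi` (3'-terminus extension; alternative polyadenylation isoforms
that share a parent's junctions but end elsewhere).  Coordinates are kept
1-based inclusive (native GTF) everywhere; only BED export converts to
0-based half-open.  The strand-aware 3' terminus is the last exon's end on
`+` and the first exon's start on `-`.  Two termini match when they are
within ±100 bases (inclusive), on the same chromosome and strand.  Junction
identity is exact — single-base shifts are treated as distinct junctions,
because real splice variation can differ by one base and fuzzing would erase
it.  A novel transcript is associated with a reference gene when it shares
at least one exact junction; single-exon transcripts are unassociated by
default, with an opt-in exonic-overlap fallback.

## Quantification: equivalence-class EM

Ambiguous alignments are summarized as equivalence classes: the set of
transcripts a read is compatible with, plus a count.  Abundances are
estimated with a lightweight EM.  The generative model: a read picks
transcript *t* with prior probability `alpha_t / sum(alpha)` and a position
uniformly along its length `l_t`, so the posterior weight of member *t* for
a class-*c* read is `(alpha_t/l_t) / sum_{t' in c}(alpha_t'/l_t')`.  The EM
update assigns each class's count by these weights and is exactly the EM for
the class-count log likelihood

    LL(alpha) = sum_c n_c log( sum_{t in c} (alpha_t / sum(alpha)) / l_t ),

which the test suite verifies is non-decreasing per iteration and reaches
the grid-search optimum on two-transcript instances.  Convergence: maximum
absolute change in expected counts < 1e-8, or 1,000 iterations.  Effective
length is the spliced transcript length; no fragment-length correction is
applied (the statistic surface downstream — ranks, ANOVA R², regression
LOD — is insensitive to a smooth length correction, and the choice is
isolated behind the length accessor).

## Detected-above-background cascade

Ordered steps: (1) drop libraries with fewer than 10 million raw read pairs;
(2) drop transcripts on unplaced contigs (only configured chromosomes
remain); (3) quantify; (4) simultaneously drop transcripts with zero
estimated counts in at least ⌈N/3⌉ of the N designated quantitation
libraries (the RI-panel libraries, not loading controls) and transcripts of
200 nt or shorter; (5) re-quantify every retained library against the
survivors, so reads that supported a removed isoform flow to retained ones;
(6) re-apply the zero-count rule.  The fractional threshold uses a ceiling
with a ≥ comparison, so at N=90 the boundary is exactly 30 libraries, and
the length boundary keeps 201 nt while removing 200 nt.  A ledger records
genes, transcripts, and per-source counts at every step and asserts the
totals never increase.  The cascade is idempotent on its own output.

## Normalization

1. **Upper-quartile**: each library is scaled so its 75th percentile of
   counts (over transcripts expressed in at least one library) equals the
   across-library mean of those percentiles.  Using the mean as the
   reference (rather than a fixed library) makes scale factors change
   smoothly when libraries are added.
2. **Moderated log**: `log2(count + 1)` followed by shrinkage of each
   library value toward the transcript mean with weight `lam/(lam + n)`
   (`lam = 1`).  This is a deliberate, documented stand-in for a shrunken
   GLM-based regularized log: every downstream statistic used here (rank
   correlation, ANOVA R², regression LOD) depends only on a monotone
   variance-stabilized scale, and the transform is strictly monotone in the
   count.  The transform chain is recorded in the matrix provenance tag.
3. **Batch adjustment**: parametric empirical-Bayes location/scale
   correction.  Per transcript, values are standardized; per batch,
   location (gamma) and scale (delta²) estimates are shrunk toward
   batch-level priors — Normal for gamma, inverse-gamma for delta², with
   moment-matched hyperparameters.  The gamma prior variance is debiased by
   the expected estimation noise (`tau² = max(var(gamma_hat) −
   mean(delta²)/n_b, 0)`), so with randomly permuted batch labels the
   adjustment vanishes as the number of transcripts grows.  After
   adjustment each transcript's grand mean is restored exactly (the
   location adjustment is mean-zero by construction, verified to 1e-8).
4. **Strain means**: arithmetic mean over each strain's libraries;
   loading-control technical replicates are excluded from panel statistics.

## Heritability and the prefilter

Panel-sense heritability of a transcript is R² = SS_between/SS_total from
the one-way ANOVA of individual library values with strain as the factor.
It is invariant to affine transforms of expression.  Note the estimator's
null expectation at k strains of n replicates is (k−1)/(N−1) — about 0.33
at 30×3 — so estimated values never concentrate near zero.

The prefilter runs three ordered steps with a ledger: keep each gene's top
3 isoforms by mean TPM over the retained panel libraries (ties at the
boundary keep the lexicographically smaller id, making the result input-
order independent); drop transcripts at or below the median R² of the
post-top-3 set (boundary inclusive — equality is dropped; median of an even
count is the mean of the central order statistics); drop transcripts with
no reference-gene junction association.

## Coexpression network

Unsigned weighted network on strain-mean expression: adjacency
`|cor|^beta` with soft threshold beta = 7 (a diagnostic `scale_free_fit`
reports the R² of the log-log degree regression), topological overlap
similarity, and average-linkage clustering of `1 − TOM`.  Modules come from
a recursive branch cut: a branch below the height cutoff (0.98) containing
at least `min_module_size` (5) leaves becomes a module, and is split
further only when both children are large enough and the merge height
exceeds the taller child's merge by more than a cohesion gap.  The gap
threshold maps monotonically from the split sensitivity (0–4; 4, the
default, is the most aggressive split at 0.05).  This is a simplified,
documented alternative to the reference dynamic hybrid tree cut, whose
internals are unspecified; planted-partition recovery and null behavior —
not module identity against the reference implementation — are the tested
contract.  Transcripts in no accepted branch form the unassigned pool, and
labels are size-ranked (`M1` largest).

Each module is summarized by its eigengene: the first principal component
of the per-transcript standardized strains × members matrix, signed so the
mean correlation with members is positive, with variance explained = first
eigenvalue / trace (verified against a full spectral decomposition).
Intra-modular connectivity is the sum of a member's adjacency to other
members; its argmax (ties to the smallest id) is the hub.

## QTL mapping

Single-marker regression LOD: `(n/2) log10(RSS0/RSS1)`, capped at 50 for
perfect fits; the scan evaluates all polymorphic SDP representatives, and
the implementation's least-squares route is cross-checked against the
closed form `−(n/2) log10(1 − r²)` to 1e-10.  Genome-wide significance is
empirical: trait strain labels are permuted jointly across markers
(preserving linkage), the genome-wide max LOD is recorded per permutation
(1,000 by default), thresholds are upper quantiles, and
`p = (1 + #{maxima ≥ observed})/(n_perm + 1)`.  Phenotype QTL are tiered:
significant at genome-wide p < 0.05, suggestive at p < 0.63; expression and
eigengene QTL use a stricter p < 0.01 and keep only the global maximum per
trait (ties to the first chromosome/position).

The 95% Bayesian credible interval treats `10^LOD`, normalized within the
peak's chromosome, as a posterior over marker positions: markers are
accumulated in decreasing-LOD order until the mass reaches the coverage,
and the interval spans the accumulated markers expanded to their flanking
markers (verified against exhaustive enumeration).

Conditioned scans add a covariate marker's allele to both the null and the
alternative model; markers collinear with the covariate (including itself)
get LOD 0.  An eQTL is called local when its peak is on the transcript's
chromosome within 10 Mb (inclusive) of the transcript midpoint — an
explicit, configurable convention.

## Candidate selection

A feature (transcript strain-mean profile or module eigengene) is a
candidate when (1) its Spearman correlation with the trait has p < 0.01
(two-sided t-approximation on n−2 df — approximate but adequate at panel
sizes of 21–30), (2) its best QTL reaches empirical genome-wide p < 0.01,
and (3) that QTL's peak marker lies inside the 95% credible interval of any
phenotype QTL of at least suggestive tier, same chromosome, inclusive
endpoints.  Candidates are sorted by correlation p.  No multiple-testing
correction is applied — the criteria act jointly as the error control — but
a Benjamini–Hochberg column is emitted for transparency.  Candidacy is
monotone in the thresholds.

## Synthetic study generator

The generator emulates the study design the analysis assumes; its defaults
are the study conditions, not tuning dials.

* **Genotypes**: 30 strains, homozygous; each chromosome is a two-state
  Markov chain with switch probability R = 4r/(1+6r) (sib-mating RI map
  expansion; r = 0.5 is a fixed point, and the expansion can be switched
  off for unit tests).  Default map: 20 chromosomes × 25 evenly spaced
  markers.
* **Annotation**: ~1,080 genes giving ~2,000 transcripts; every gene has a
  reference transcript, about half gain an exon-skipping reconstruction
  isoform, and about half gain a 3'-extension isoform sharing all junctions.
  Two percent of genes sit on an unplaced contig and two percent of
  reference transcripts fall below the length filter, so the cascade always
  has work to do.
* **Expression**: negative binomial with log mean = baseline + strain
  effect + planted eQTL effect + batch effect + log depth offset.
  Baselines are log-normal (median 150 counts); within-strain biological
  log-SD 0.3; eight batches with per-transcript location effects of SD 0.2;
  depths log-normal around 71 M read pairs (SD 0.45 on the log scale, so
  shallow libraries below the 10 M floor are rare but possible); dispersion
  0.05 (dispersion → 0 recovers Poisson, used in tests).  Three replicate
  libraries per strain plus loading-control technical replicates of a
  separate control strain.
* **Heritability targets**: each transcript draws a target R² uniformly
  from (0.33, 0.67) — median near 0.5, matching the panel-scale behavior
  the analysis expects.  Because the ANOVA R² at 30×3 has null expectation
  ≈ 0.326, the strain-effect variance is solved from the expected
  sums-of-squares identity `sigma_b² = sigma_w² (h(N−1) − (k−1)) /
  (n(k−1)(1−h))`, with the within-group variance including an analytic
  log-scale counting-noise term (1/mu + dispersion).  Targets below the
  null expectation floor at zero strain variance.  Realized mean estimates
  track targets within well under 0.05; the full Kolmogorov distance to the
  uniform target is dominated by the estimator's own sampling noise
  (SD ≈ 0.065 at this design), so distributional coverage is asserted
  through interior deciles.
* **Phenotype**: strain mean = planted marker effects + strain noise scaled
  so each planted marker explains its configured variance fraction in
  expectation; 6 animals per strain add within-strain noise (SD 1.0 — a
  free parameter; only strain means feed mapping); measured in the first 21
  strains, so scans always exercise the strain-intersection path.
* **Equivalence classes**: reads pick a (transcript, exon) cell with
  probability proportional to molar abundance × exon length; the class is
  the set of transcripts carrying that exact exon.  Identical twins share
  all reads; transcripts with unique 3' exons get unique classes.

What the generator does **not** emulate: read sequences and alignment
error, fragment-length effects, GC/length bias, correlated gene programs
beyond planted modules, dominance or epistasis, population structure
beyond the two-progenitor mosaic.  Passing tests therefore demonstrate the
statistical machinery on data with the assumed structure, not robustness to
real-data artifacts upstream of the count matrix.

## Scaled experiment designs

Two experiment designs are deliberately compact:

* **Recovery experiments** (planted 50%-variance phenotype QTL at 21
  strains) run on a sparse framework map — 5 chromosomes × 4 markers with
  r = 0.4, i.e. ~20 nearly independent SDPs.  Exact-marker recovery is an
  order-statistics contest between the planted marker's sample r² and the
  null maximum: at 200 independent SDPs the win rate is capped near 80%
  regardless of implementation, and densely linked neighbors add coin-flip
  losses.  The sparse map isolates what the experiment is meant to
  measure — that the scan finds the right locus and the credible interval
  covers it — from map-resolution noise.
* **End-to-end candidate recovery** plants a six-transcript module sharing
  an eQTL (log effect 2.0) at the phenotype marker (variance fraction 0.8)
  among ~200 null transcripts.  The plant is strong on purpose: Spearman
  p < 0.01 at 21 strains requires |rho| > 0.55, so a weak plant would
  measure sampling noise rather than the selection machinery.  Null runs of
  the same design yield zero candidates essentially always.

Problem sizes in the acceptance script (500 calibration traits × 1,000
permutations, 200 recovery replicates, 100 planted and 50 null pipeline
runs, ~2,000-transcript studies) are the package's standard experiment
sizes and complete in about a minute on one CPU.

## Numerical conventions

Ties in top-k TPM ranking, hub selection, and peak finding break
deterministically (lexicographic id or first map position).  Constant
traits give LOD 0; monomorphic markers are skipped and logged; perfect fits
are capped.  Zero-variance transcripts are flagged undefined for
heritability and rejected by name in the network.  All randomness descends
from a single study seed through fixed-key `SeedSequence` spawning, and
every pipeline output is byte-identical across reruns of the same
configuration.

## Known limitations

The EM ignores within-transcript position classes (a read's class depends
only on which transcripts share its exon), which understates ambiguity for
partially overlapping exons.  The moderated log is not the reference
regularized log; values are not comparable across packages, only within a
run.  The branch cut is not the reference dynamic tree cut; module counts
will differ.  Local/distal classification depends on an arbitrary 10 Mb
window.  The Spearman p-value is a t-approximation, slightly liberal below
n ≈ 10.  No kinship/mixed-model correction is applied, matching the
marker-regression design; panels with strong relatedness structure would
need one.
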