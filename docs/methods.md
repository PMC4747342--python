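# Methods

## Coordinate and annotation model

All coordinates are 0-based, half-open. BED input is native; the
refFlat-like gene table is read 0-based by default with a `one_based` flag,
and GTF (1-based closed) is converted on read. Overlap means ≥ 1 shared
base; no overlap-fraction threshold is applied, since the analyses operate
on narrow (±150 bp) mode-centered peaks.

A peak is annotated to exactly one category by priority:
`TSS_1KB > UP_1_5KB > UP_5_10KB > EXON > UTR > INTRON > INTERGENIC`.
Windows around the TSS are defined in transcription-direction offsets
(negative = upstream), so upstream windows sit 5′ of the TSS on the coding
strand of each gene; this makes annotation invariant under mirroring the
genome (a property the test suite checks). `EXON` means CDS-overlapping
exon segments; exon segments outside the CDS are `UTR`; a gene without an
annotated CDS contributes whole exons as `EXON`. Intron indices count in
transcription direction, and when several transcripts' introns overlap a
peak the transcript with the TSS nearest the peak mode reports the index.
`INTERGENIC` is the fallthrough: a peak overlapping none of the six region
types, which coincides with lying outside every gene territory (10 kb
upstream of the TSS to the transcript 3′ end) except that category regions
take precedence where a TSS window pokes past the 3′ end of a sub-kilobase
gene. The peak's representative position for distance computations is the
mode, matching the ±150 bp boundary convention.

Random backgrounds for fold-enrichment are size- and width-matched: each
observed peak contributes one random interval of its own width per
replicate, with chromosomes weighted by their number of valid start
positions. Ten replicates and the mean random count are the defaults. Peaks
are width-matched individually rather than drawn at a fixed width; a fixed
width can be obtained by passing uniform-width peaks.

## Motif model

A PWM is a width × 4 column-stochastic matrix with an explicit background.
Windows score as Σ log₂(p(base)/bg(base)); windows containing non-ACGT
characters never match. Scanning uses the strand-symmetrized
mononucleotide composition of the scanned FASTA as background (uniform
fallback), scans both strands (the reverse strand via the flipped integer
score matrix, so both strands share one null table), reports every window
with null exceedance probability below the threshold (default 10⁻⁴, the
conventional scanning default), and collapses hit multiplicity only when a
peak-level presence call is needed.

The null distribution is exact: column log-odds are rounded to 1/1000-bit
bins and the distribution of the integer sum under the background is built
by dynamic programming; the discretization error is orders of magnitude
below the threshold granularity, and the test suite checks the DP against
full enumeration for widths up to 8. `pwm_from_counts` applies a
background-weighted pseudocount (default 0.1 per column) so log-odds stay
finite.

The shipped PAX8- and PPARG-like matrices are synthetic stand-ins (sharp
columns, dominant probability 0.98, widths 12 and 13) built from
plausible consensus sequences — a paired-domain-like site and a DR1
nuclear-receptor repeat. Real matrices can be supplied in MEME minimal
format and flow through the identical code path.

## Contingency tests

2×2 tables report the sample odds ratio ad/bc (flagged undefined when
bc = 0) and the two-sided Fisher exact p (sum of probabilities of tables no
more probable than the observed one). Direction-concordance analysis
cross-tabulates one run's DE genes by a second run's UP/DOWN/NC calls; the
headline p-value is the exact conditional test on the full 2×3 table,
computed by enumerating all tables with the observed margins (the 2-row
generalization of Fisher's test). The 2×2 restricted to doubly-changed
genes is returned alongside with its own odds ratio and p. The
homolog-overlap comparison of two reference cistromes is tested by Fisher
exact on set-exclusive homologs so the table's cells stay disjoint; the
choice of Fisher's test for this comparison is an assumption of this
package.

## Enrichment engines

**Directional expression enrichment.** For each gene set, membership (0/1)
is regressed logistically on x = sign(log2FC)·(−ln p) over the whole tested
universe. The slope's two-sided Wald p gives significance; its sign gives
the direction (induced/repressed). The signed statistic is the standard
directional construction; it makes the engine exactly antisymmetric under
sign-flips of the fold changes (tested). Sets are filtered to 5–500 members
after intersection with the universe; q-values are Benjamini–Hochberg
across tested sets; FDR ≤ 0.05 is the reporting convention.

**Peak-presence enrichment with locus-length adjustment.** Long gene loci
collect peaks by chance, so a naive membership × has-peak test is badly
anticonservative for any set of long genes. The engine fits
`has_peak ~ membership + cr(log10 locus_length, df = 10)` where `cr` is a
natural cubic spline with knots at quantiles. Locus length spans 10 kb
upstream of the TSS to the transcript 3′ end. The spline basis spans the
constant and therefore doubles as the model intercept; when all locus
lengths are equal the basis is empty, a plain intercept is used, and the
model reduces exactly to the unadjusted membership logit (tested to 1e-6
on the coefficient). Mappability is not modeled; locus length is the only
adjustment.

When the maximum-likelihood fit separates (e.g. every peak-bearing gene in
the set) or fails to converge, the engine refits with Firth's penalized
likelihood (Jeffreys prior, damped Newton iterations) and flags the result.
Wald tests are used throughout.

**Stratified enrichment.** Peaks are assigned to the nearest-TSS gene with
a signed transcription-direction distance; strata are
(motif) × (near: |distance| ≤ 10 kb; far: distance < −10 kb, i.e. more than
10 kb upstream). The asymmetric far definition follows the source
convention; both windows are configurable. Each stratum gets its own
locus-length-adjusted run, and a joint report marks sets both peak-enriched
and significant in a supplied expression-enrichment run, with the
expression direction.

## Synthetic data generator

The generator emulates the structure of a dual-motif fusion-factor study
and is the basis of all end-to-end tests. Defaults (the study conditions):

- **Genome**: 4 chromosomes totaling 6 Mb, i.i.d. bases at (0.29, 0.21,
  0.21, 0.29). The genome is sized so that gene territories (gene span plus
  10 kb upstream) leave intergenic space as the majority bp share, matching
  the intergenic-dominant structure of mammalian cistromes; a smaller
  genome at the same gene count would have essentially no intergenic bp.
- **Genes**: 300 non-overlapping models, 1 + Poisson(3) exons of 80–400 bp,
  introns 500–3000 bp, CDS insets 80–250 bp defining UTRs, random strands.
- **Peaks**: 2,000 non-overlapping 300 bp peaks (mode at center), placed by
  annotation-category weights (default 25% TSS ±1 kb, 19% intron, 40%
  intergenic, remainder upstream/exon/UTR). Placement uses per-position
  priority masks, so a peak's realized annotation always equals the
  intended category; the masks also yield the exact category distribution
  of a uniform random interval, which is the closed-form denominator for
  fold-enrichment checks.
- **Motifs**: per peak, class (both / PAX8-only / PPARG-only / neither) at
  rates (0.20, 0.20, 0.25, 0.35), chosen so 65% of peaks carry a motif and
  half the PAX8-motif peaks also carry a PPARG motif. Sites are sampled
  from the PWM (consensus optional), written into the genome on a random
  strand at a Gaussian offset (σ = 20 bp) from the peak center, or
  uniformly; co-planted sites never overlap.
- **Expression**: four pairwise comparisons. Null genes carry z ~ N(0,1);
  members of a planted set get z shifted by ±3.5; p is the two-sided normal
  tail, log2FC = z/2, FDR is BH per table. The vehicle-control comparison
  carries no effects (pure null). The default effect layout plants two
  induced and one repressed set for the fusion-vs-control comparisons and
  reverses one of the induced sets under ligand, emulating a
  ligand-reversed (oxidative-stress-like) program.
- **Homologs**: two species-B gene sets of 1,500 mapped to species-A genes
  (10% unmapped), with A-side binding planted at 34% versus 25%.

Everything derives from one seeded integer-state generator
(`numpy.random.default_rng`), so outputs are byte-identical per seed.

What the generator does **not** emulate: read-level noise, peak-width and
peak-height variation, correlated gene expression, GC or mappability
structure, overlapping transcripts and alternative isoforms, and real motif
degeneracy beyond the sharp stand-in matrices. Passing tests therefore
demonstrate correctness of the computations and calibration of the tests
under idealized inputs, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

- Score discretization 1/1000 bit; p-value lookups are exact on the
  discretized lattice and monotone by construction.
- Nearest-TSS ties break to the lexicographically smallest gene id;
  equidistant-intron ties take the smallest index.
- Fold ratios with a zero random denominator are NaN, never infinity.
- Odds ratios with bc = 0 are flagged undefined (inf/nan by numerator).
- The 2×c exact test uses a relative tolerance of 1e-7 when comparing table
  probabilities, the same convention as common implementations.
- Degenerate enrichment fits (sets covering none or all of the universe, a
  constant evidence statistic, all-or-none outcomes) are skipped or
  reported as null results with an explanatory note rather than fitted.
- BH q-values come from the standard step-up procedure; inputs outside
  (0, 1] are rejected.

## Test problem sizes

Calibration suites use 500-replicate nulls on 300-gene universes;
oracle-equivalence suites use 200–500 peaks and small-width PWMs where the
null is enumerable; the end-to-end study uses the default generator sizes.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted tolerances while keeping the whole suite fast.

## Known limitations

- The locus-length engine adjusts length only; mappability and other
  covariates are out of scope.
- No GO DAG structure: gene sets are flat; ancestry relations between
  terms are not modeled.
- No q-value per motif hit (peak-level presence is what downstream
  analyses consume).
- The exact 2×c test enumerates; it is intended for the 2×3 tables of this
  workflow and small margins, not for large r×c problems.
- Homolog maps are inputs; no ortholog inference is performed, and
  many-to-many maps use any-homolog semantics (a strict 1:1 subset is
  available).
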