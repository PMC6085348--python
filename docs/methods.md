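# Methods

This note documents the models behind `stormtrace`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical choices a user adjusting the package should know about.

## Study system and synthetic generator

Stormwater is modelled as a two-component mixture: a human-gut microbial
community with total weight *f* (the contamination fraction, 0 ≤ f ≤ 1)
and an environmental freshwater background with weight 1 − f. The
generator builds a reference of *organisms*, each contributing

* a 16S-like **marker** (default 400 bp), the unit of the amplicon table;
* a longer **catalog gene** (default 500–2,000 bp), the shotgun mapping
  target.

Environment markers are substitution-mutated copies of gut markers at an
exact divergence fraction (default 0.10, i.e. ~90% cross-pool identity):
they belong to the same gene family but sit safely below the 99%
faecal-indicator threshold, so indicator assignment on clean sequences is
unambiguous (asserted by brute-force all-pairs alignment). Environment
catalog genes are independent random sequences, far below the 90%/200 bp
shotgun thresholds. Divergences under ~0.015 would break the separation
guarantee and are rejected.

Per sample:

* Within-pool relative abundances are Dirichlet with configurable
  concentration (default 1.0: strongly variable communities; analyses that
  presuppose a shared catchment community, e.g. clustering or source
  attribution demonstrations, use a higher concentration such as 20 so
  samples differ by contamination rather than by unrelated composition).
* **Amplicon counts** are multinomial at fixed depth over marker weights,
  emulating an already-denoised, already-classified sequence-type table;
  denoising, chimera formation, PCR/primer bias are deliberately out of
  scope.
* **Shotgun reads** are uniform windows of catalog genes (length
  Normal(600, 60), truncated to the gene) with i.i.d. per-base errors at a
  configurable rate, split 60/20/20 substitution/insertion/deletion — a
  long-read-like profile. The default 5% corresponds to a mean Q-score of
  ~13, and per-base FASTQ qualities are written accordingly. True origins
  are retained for oracle tests.
* **Wells**: each well of volume *v* ml is positive with probability
  1 − exp(−c·v/d) at concentration *c* per ml and dilution *d*. The
  default layout is a two-volume tray of 49 × 1.86 ml + 48 × 0.186 ml
  (Quanti-Tray/2000-like; the assayed volumes are configuration, not a
  constant of the method). At a 1:100 dilution this tray's reporting
  limits land at <100 and ≥242,000 per 100 ml, the values the pipeline
  uses by default.
* **DNA yield** is LogUniform(0.16, 3.73) ng/ml — the observed range for
  uncontaminated stormwater — plus 20·f ng/ml, so yield carries signal
  about contamination as it does in real samples. The true *E. coli*
  concentration is 2×10⁶·f per 100 ml with lognormal noise (σ = 0.3 on the
  log scale), tying culture counts and sequence indices together by
  construction.

Every generator is a pure function of (config, seed). What passing tests
on this system show is that the *procedures* behave as claimed (recovery,
ordering, censoring, FDR control); they cannot show robustness to real
nuisances the generator omits: chimeras, primer bias, basecalling
artefacts, taxonomic misclassification, or community structure beyond a
Dirichlet.

## MPN estimation

The log-likelihood of concentration *c* (cells/ml, pre-dilution) is
Σ p·log(1 − e^(−cv/d)) + (n − p)·(−cv/d) over well classes. It is
maximised by bounded Brent search on log₁₀c over [10⁻⁶, 10⁶] per ml
(relative tolerance 10⁻⁸); the likelihood is concave in *c* for mixed
outcomes, so a single bounded search suffices (cross-checked against a
10,000-point grid in the tests). All-negative trays report `below_lod`,
all-positive `above_uod`; a point estimate falling outside the configured
reporting limits is likewise flagged censored, with the raw MLE still
returned. No confidence intervals are produced. The proprietary tray
lookup tables are not reproduced — the ML estimate is the method.

## Sequence matching

One alignment contract serves both matching decisions: semi-global
alignment (query end-to-end, free end gaps on the reference) with match
+1, mismatch −1, gap open −2, gap extend −1, computed by Biopython's
`PairwiseAligner`. Percent identity is matches / aligned columns, where
columns include internal gaps and any query overhang but not the
reference's free flanks; `N` occupies a column and never matches, and
queries with more than 10% `N` are rejected. The original protocols used
external aligner binaries; fixing an explicit scoring contract instead
makes results reproducible without version-pinned executables — the
thresholds (99% for indicator sets; 90%/200 bp for shotgun mapping), not
the engine, carry the method. Scores are compared exactly against an
independent dynamic-programming oracle in the tests; co-optimal alignments
can differ in gap placement, so identities of gapped optima may differ in
the last decimal between engines.

A k-mer prefilter (k = 11, ≥2 shared k-mers) screens candidates before
alignment. At the shipped thresholds it is empirically lossless to <0.5%
on simulated 5%-error reads; exhaustive-alignment equivalence of the full
best-hit path is asserted in the acceptance tests. Ties on score break by
higher identity, then lexicographic target id.

An E-value ceiling appears in the match policy for interface completeness
but is off by default: a proper E-value needs a database-size model, and
the identity/length thresholds carry the decision. The significance
direction intended is "E ≤ 10⁻⁶".

## Amplicon indicator index

Three indicator definitions of increasing breadth: one genus
(*Escherichia/Shigella*), a 20-genus list (shipped as an editable
plain-text config of commonly used sewage-indicator genera — a documented
placeholder, not a reproduction of any specific published panel), and all
sequence types with ≥99% best-hit identity to gut markers over ≥90% of the
marker length. The per-sample index is raw FIO fraction × DNA yield
(units "FIO-ng/ml"). Pearson correlation against MPN is computed on log₁₀
scales by default (both modes exposed); censored MPNs are substituted by
their reporting limit (they are plotted at the limits, and dropping them
discards exactly the most informative extremes — both policies exposed);
zero indices are dropped under the log transform (or floored to half the
smallest positive index). Sensitivity arithmetic: one genome of
*G* bp weighs G·649/N_A grams (~3.23 fg at 3 Mbp), so a DNA yield maps to
genome equivalents per ml and the expected reads-per-FIO-read is the
total/FIO concentration ratio.

## Shotgun protocol and saturation

Reads are truncated to 400 bp; shorter reads are **discarded** (the trim
exists to homogenise read length, which padding or keeping short reads
would defeat; the discard count is logged). 10,000 survivors are
subsampled uniformly without replacement under the protocol seed (with
replacement would be defensible too; without replacement matches how a
fixed read file is consumed). The saturation curve uses one seeded shuffle
and nested prefixes — mirroring accumulation during a real-time run rather
than independent re-subsampling — and reports the smallest depth within 1
percentage point (the tolerance is expressed in percentage points) of the
full-depth ratio. The 90% identity cutoff derives from ~94% intraspecies
identity × (1 − 5% error), rounded to the nearest ten.

## Community statistics

Bray–Curtis on counts (or relative abundances); Spearman-based
dissimilarity mapped to [0, 1] as (1 − ρ)/2 with mid-ranked ties (the
choice of transform for ordination input is configuration; (1 − ρ)/2 was
chosen to bound the matrix like Bray–Curtis). Non-metric MDS minimises
Kruskal stress-1 with monotone regression (SMACOF via scikit-learn,
isotonic/pool-adjacent-violators inside), best of 8 seeded restarts,
centred coordinates. Hierarchical clustering is average-linkage
(ultrametric inputs are reproduced exactly; merge heights are
non-decreasing). Rarefaction is a multivariate hypergeometric draw per
sample; samples below depth are dropped with a warning. Differential
abundance aggregates sequence types to a rank, tests relative abundances
with the Wilcoxon rank-sum (exact null for combined n ≤ 20, normal
approximation with continuity correction otherwise), restricts testing to
taxa above a mean-abundance floor in at least one group (10⁻³ at
phylum/class, 10⁻² at genus), and adjusts with Benjamini–Hochberg.
FDR control of the whole procedure is verified by a 500-replicate null
simulation.

## Source attribution

A collapsed Gibbs sampler over per-read source assignments. For known
source *v* with rarefied counts *m*, P(x|v) = (m_{x,v} + α)/(m_v + αT)
with T taxa and α = 0.001; the "Unknown" source starts from α on every
taxon and learns its distribution from currently assigned reads — the key
design choice, since without it any sink read absent from all sources
would be forced onto the nearest source. The assignment prior is
(n_v^{-i} + β)/(n − 1 + β(V+1)) with β = 1. Sink and sources are rarefied
to a common depth (default 9,648). Defaults: 100 burn-in sweeps, 100 kept
draws thinned ×10, 10 restarts (4 in the pipeline for speed); proportions
are the mean over kept draws and restarts, with their standard deviation
as a spread estimate (not a calibrated credible interval). Sources are
processed in sorted-id order so column order cannot affect results. The
inner chain is numba-compiled; a run at depth 5,000 with two sources takes
seconds.

## Pipeline defaults and problem sizes

The pipeline's defaults are the protocol constants named above (99 / 90 /
200 bp / 400 bp trim / 10,000 subsample / α 0.05 / floors 10⁻³ and 10⁻² /
depth 9,648 / α 0.001), a 40-sample design (10 clean + 30 on a geometric
f-gradient from 0.01 to 0.5), amplicon depth 10,000, and 600 shotgun reads
for 10 samples. The test suite and the acceptance script run the same
machinery at sizes chosen to keep a full run in minutes on one core
(e.g. 10+10 reference organisms, 10,000-read saturation runs, 500-read
oracle-equivalence batches); all sizes are configuration, and scaling them
up changes runtime, not logic.

## Known limitations

* The generator's communities are Dirichlet-multinomial; real stormwater
  has spatial/temporal autocorrelation, lineage-level microdiversity and
  compositional effects it does not imitate.
* MPN assumes perfect mixing and per-cell independence; clumped cells
  bias it low.
* The E-value filter is a stub by design; use identity/length thresholds.
* Attribution spread estimates are across-draw standard deviations, not
  posterior credible intervals with guaranteed coverage.
* No α-diversity beyond what a count table trivially yields, no plotting:
  outputs are TSV/JSON/Newick meant for downstream tools.
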