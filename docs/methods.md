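# Methods

This note documents the models, conventions and design choices behind
`ampliem`, in the spirit of a statistical-software methods appendix.  It
states nothing the tests or `scripts/acceptance.py` do not themselves
compute.

## Genetic distance

Pairwise distances come from a semi-global affine-gap dynamic programme
(match +1, mismatch −1, gap open 2, gap extend 1 by default).  Leading
and trailing gap runs in either sequence are free, so reads with unequal
trimming are not penalised.  The homopolymer discount is defined
operationally: a gap column whose inserted/deleted base equals the base
immediately adjacent to the gap position in the *other* sequence (on
either side) is charged `h × cost`, `h = 0.5` by default.  This local
definition is order-independent and is implemented identically in the
DP and in the exhaustive enumeration oracle the tests compare against
(all alignments of sequence pairs up to length 8).

Distance is `(mismatches + internal gap columns) / (matches +
mismatches + internal gap columns)`; end-gap columns are excluded from
both sides, a length-k internal gap contributes k columns, and a pair
whose optimal alignment has no aligned core is assigned distance 1.
The scoring parameters and `h` are exposed in `AlignmentParams` because
no canonical values exist for this distance; the defaults are
conventional DNA scoring.  Ties in the DP are broken deterministically
(substitution over gap, then gap in the first sequence), and operands
are oriented canonically before alignment so that the reported counts —
not just the optimal score — are exactly symmetric.  The distance is a
dissimilarity, not a metric: the triangle inequality is not guaranteed
and is deliberately not asserted.

Degenerate inputs fail loudly: empty sequences and non-ACGT symbols
raise (naming the offending position).  The DP kernel is JIT-compiled
(numba) and costs ~3 ms for a 430-bp pair on one core, which sets the
problem sizes used in the tests (all-vs-all matrices of up to a few
hundred unique sequences).

## Preprocessing

The chain is merge → quality filter → dereplicate → abundance filter.
Merging scans every ungapped overlap ≥ `min_overlap`, keeps the one
with most matches (ties → longer), resolves disagreements by the higher
Phred base, and returns a reject *value* (not an exception) when the
best overlap is too short or too mismatched.  The quality filter slides
a 50-base window in steps of one base and requires every window mean to
reach Phred 32; reads shorter than the window are judged on their whole
mean — the strictest reading of a "moving window" and a conservative
short-read fallback.  Whether such a filter runs before or after
merging is a free choice; it runs after merging here (merged bases
carry the max/winning quality).  Dereplication is strict string
equality after upper-casing and U→T; the abundance filter keeps
sequences seen at least twice.  Read counts are conserved exactly
through dereplication, which is property-tested.

## OTU clustering

Initialisation: (i) for each dereplicated sequence, sum the abundances
of every *other* sequence within 3% distance (inclusive, "within");
(ii) sort by that sum, descending (ties: higher own abundance, then
id); (iii) walk the sorted list, each ungrouped sequence seeding a
group that captures all ungrouped sequences at distance strictly below
3%; (iv) re-assign every non-seed to its nearest seed (ties → earlier
seed).  Both radii are configurable.

EM refinement treats the seeds as centres of a K-component mixture with
kernel `f(j|k) ∝ exp(−σ d(j, centre_k))`, σ = 250.  At σ = 250 and
d = 0.03 the kernel is exp(−7.5) ≈ 5.5×10⁻⁴ of its value at d = 0, so
the 3% radius acts as a soft boundary.  The E-step computes
responsibilities; the M-step updates abundance-weighted mixing
proportions and moves each centre to the medoid minimising the
responsibility- and abundance-weighted distance sum.  Medoid (rather
than consensus) updates keep every centre an observed sequence, so the
representative always has computable taxonomy.  K is fixed by the
initialisation; components may only be pruned (weight < 1e-12), never
split.  The weighted log-likelihood is asserted non-decreasing at every
iteration (the medoid step is a generalized M-step, so this holds
exactly); convergence is an absolute log-likelihood change below 1e-6,
with a flagged best-effort return at 100 iterations.  Given the
initialisation the algorithm is deterministic — no seed is involved.
Final hard assignment is argmax responsibility (ties → larger mixing
weight, then earlier component).

## Taxonomy

Exhaustive best hit against the reference set under the alignment
distance; similarity ≡ 1 − distance, floor 0.90 inclusive, applied
globally rather than per rank.  Ties go to the lexicographically
smallest reference id.  References with truncated lineages yield
assignments at the deepest available rank, and rank collapsing keeps
such OTUs under a labelled aggregate (e.g. `"Lachnospiraceae
(family)"`) rather than discarding them.

## Tables and normalization

Lineage filters remove organelle lineages (mitochondria/chloroplast
terms at any rank), domains other than Bacteria, the phylum
Cyanobacteria (chloroplast 16S interference), and an explicit
id-exclusion list.  The exclusion list is the generic mechanism for
removals that are judgment calls (e.g. suspiciously long tree branches
suggesting chimeras); no automatic removal is performed.  All filters
are idempotent.

Replicate selection reduces the "replicates always cluster together"
requirement to mutual nearest neighbourhood in the Bray–Curtis matrix
of relative profiles — equivalent under average linkage, and checkable
pair by pair.  Consistent subjects keep the deeper replicate;
inconsistent ones are flagged and kept-or-dropped per configuration.

TMM follows the trimmed-mean-of-M-values recipe: reference = sample
whose upper quartile of nonzero relative counts is closest to the mean
upper quartile; M/A values over taxa nonzero in both sample and
reference; 30%/5% two-sided rank trimming on M/A; factor =
2^(precision-weighted mean of retained M), with delta-method weights.
Two factor conventions are reported: `composition_factor` (geometric
mean 1, the edgeR sense, equal to 1 when one library is an exact
multiple of another) and `scaling_factor` (library size ×
composition factor, rescaled to geometric mean 1), which is the
depth-inclusive factor used when the question is "how much should this
library be scaled" — a planted 2-fold depth difference appears as a
log2 scaling-factor ratio of 1.  The implementation is cross-checked
against an edgeR run frozen into the test suite.

Core/Venn analysis defines detection as count ≥ 1 and group core as
presence in more than 90% of the group's samples; singletons are
retained throughout (diversity analyses deliberately keep taxa seen in
a single sample; a config flag can drop them).

## Diversity

Shannon entropy is computed in nats and evenness divides by ln(S_obs),
its maximum; Chao1 defaults to the bias-corrected form
`S + F1(F1−1)/(2(F2+1))` so doubleton-free samples stay finite (the
classic form is available by flag); Simpson is published as both the
complement 1 − Σp² and the inverse 1/Σp².  Canberra is averaged over
the taxa with a nonzero pair sum so it lies in [0, 1].  UniFrac is a
postorder branch walk on a supplied rooted newick tree (tree inference
is out of scope): unweighted = unique branch length over branch length
spanned by either community; weighted = Σ l·|p − q| normalized by
Σ l·(p + q) (the raw variant is a flag; normalized is the default so
values are comparable across pairs).  On a star tree with unit branches
the normalized weighted form reduces to ½ Σ|pᵢ − qᵢ|, which is used as
a closed-form check, and the implementation is cross-validated against
scikit-bio on integer counts.  PCoA Gower-centres −½D², reports
negative eigenvalues but excludes them from the proportion-explained
denominator and emits no axes for them.

## Statistics

*Chi-square / Cramér's V*: Pearson chi-square without continuity
correction; V = sqrt(χ²/(n·(min(r,c)−1))).

*ANOVA/Tukey*: the group test is the sequential F with the covariate
(library size) entering first — "adjusted for depth" is interpreted as
sequential ANCOVA, with an optional group × covariate interaction term
after the group term.  The design is built explicitly (intercept →
covariate → group dummies → interaction) because formula interfaces
reorder categorical terms.  Pairwise comparisons use Tukey–Kramer for
unequal n: q = |mean difference| / sqrt(MSE/2·(1/nᵢ+1/nⱼ)), adjusted p
from the studentized-range distribution with the model's residual df;
estimates are raw mean differences.  Adjusted p-values are verified to
1e-6 against a direct double-quadrature of the studentized-range
distribution.

*Kruskal–Wallis* (tie-corrected, χ² approximation) with
*Benjamini–Hochberg* step-up FDR applied within one analysis family at
a time (e.g. all taxa of one screen), never across families.

*Mantel*: Pearson correlation of upper-triangle entries (Spearman by
flag), one-sided permutation p with the add-one rule and an explicit
seed.

*PERMANOVA*: G = −½ J D² J; ordered terms contribute sequential
(Type-I) sums of squares through orthonormal increments of their
centred design columns (categoricals as centred dummies, interactions
as products of centred columns; rank-deficient additions contribute 0
df with a warning).  Pseudo-F = (SS/df)/(SS_res/df_res); p-values
permute rows/columns of D jointly, add-one rule, seeded.  On univariate
Euclidean input the pseudo-F equals the classical one-way ANOVA F to
machine precision (asserted at 1e-10), and the multi-term decomposition
matches a vegan `adonis2(by="terms")` run frozen into the tests to
nine decimals.  Model selection proceeds exactly in three stages:
univariate (and pairwise-interaction) screen at p < 0.2, a complex
model of all survivors, and a reduced model of the terms significant at
0.05 in the complex model, with main effects retained whenever a
retained interaction contains them.  Term order within a model is the
caller's, and is recorded in the output.

*Enterotyping*: family-level profiles, zeros replaced by 1e-6 and
renormalised, root Jensen–Shannon divergence, PAM (BUILD + SWAP,
hand-implemented since no installed package provides k-medoids; the
seed only breaks exact cost ties).  Each cluster is labelled by the
marker family (Bacteroidaceae, Prevotellaceae, Ruminococcaceae) with
the highest mean abundance; a tie raises and demands manual labels.
The per-sample `dominant_family` argmax is available as the fallback
labelling for contingency-table summaries.

## Synthetic-data generator

The generator's defaults are the study conditions: groups O/V/VG of
43/32/26 subjects, two technical replicates, log-normal library sizes
with mean ~11,000 clipped to [1,500, 30,000], 0.5% substitutions, 1%
homopolymer-run ±1 indels, and per-base Phred scores around 38 with a
linear decay of 6 toward the 3' end (so the Q32/50 filter has
non-trivial pass/fail behaviour).  Reads are emitted pre-merged;
paired-end insert-size realism, chimeras beyond a two-parent option,
and primer bias are out of scope.

References are independent random V3–V4-length sequences (400–470 bp),
which are pairwise ~60% distant, far above the 0.06 separation floor
(a request above 0.3 fails explicitly); an optional fraction of
references is derived by mutating 3.5–5.5% of an earlier reference's
positions to stress the clustering radius; an exact seeded fraction of
lineages is truncated at family level.  Lineages draw from nine gut
families across five phyla, with several genera per family so
genus-level collapsing is non-trivial.

Community composition per subject: richness is drawn per diet group
(normal, means 147/183/175 for O/V/VG, SD 25 — offsets of the size the
cohort statistics must recover, against within-group noise small
enough that the *depth-adjusted* test is well powered); OTU inclusion
follows a power-law prevalence so early references form a shared core
(which is what makes the >90%-prevalence core shared between groups);
included OTUs get log-normal abundances (σ = 1.2) scaled by a planted
Bacteroidetes fold-change (1.6 in V/VG) and by a ×3 boost of the
subject's latent enterotype family (drawn per group from the observed
enterotype frequencies).  Nutrient tables contain 76 columns (named
macros plus generic nutrients); planted group multipliers make animal
protein, cholesterol, EPA and DHA omnivore markers and fiber a
plant-diet marker; macro means put every group above the 30% fat
guideline and at/below the 15% protein guideline.  All planted effects
can be switched off for null simulations.

One global seed fans out to per-stage child seeds via
`SeedSequence.spawn` in a fixed order (references, cohort,
compositions, reads, counts), so identical configs give byte-identical
outputs and stages are independently reproducible.

What the generator does *not* emulate: chimeric amplicons, primer/PCR
bias, overdispersed (non-multinomial) technical replicates, phylogenetic
signal in sequence similarity (taxonomically related references are not
more similar than unrelated ones), and correlated nutrient–microbiota
structure beyond the shared diet-group labels.  Passing tests therefore
demonstrate algorithmic correctness and parameter recovery under the
declared error model, not performance on real sequencing data.

## Problem sizes in the tests and acceptance script

Simulation-heavy checks run at reduced scale, chosen as the smallest
sizes at which the measured property is stable: planted-OTU recovery
uses 20 references × 2 samples at ~4,000 reads each over 20 seeds;
PERMANOVA type-I error uses 21 samples × 99 permutations × 1,000
replicates; the richness-power surface uses the full 101-subject cohort
at table level over 200 seeds (read-level simulation is unnecessary for
a table-level statistic).  `scripts/acceptance.py` reports the same
quantities with the replicate counts listed in its JSON output.
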