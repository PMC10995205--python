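# Methods

`magniche` implements the downstream, genome-centric half of a coral
holobiont metagenomics study: it starts from tables a binning/annotation
workflow produces (MAG quality and features, per-sample mean coverages,
annotation counts, a pairwise ANI matrix) and ends with habitat-specificity
calls, comparative statistics, pathway completeness, and constrained
community ordination. This note records the models, the defaults and why,
and the choices made where the design was genuinely open.

## MAG quality and dereplication

A bin's quality score is `completeness − 3 × contamination`; bins are
retained when the score is ≥ 50 **and** completeness is ≥ 75 %, both
inclusive — the conventional medium-quality-plus cutoff. Strain-level
redundancy is collapsed at ANI ≥ 99 % with a greedy centroid rule: bins are
visited in order of decreasing quality (ties broken lexicographically by
id), each unvisited bin becomes a representative and absorbs all remaining
bins at or above the threshold. This gives two provable guarantees that
single-linkage clustering lacks — representatives are pairwise below the
threshold, and every absorbed bin is within threshold of its representative
— at the cost of not reproducing the exact cluster memberships of
score-weighted tools such as dRep on real data. Directional ANI estimates
are symmetrized by taking the maximum of the two directions (conservative:
merges more readily). Per-site mode runs the same rule independently within
each sampling site; overall mode ignores sites and is applied before
biogeography analyses to remove strains recovered independently at
different sites.

## Abundance

Coverage entries with covered fraction below 10 % (inclusive threshold at
exactly 0.10) are treated as undetected and zeroed — covered fraction is a
far better detection criterion than mean coverage for low-abundance
genomes. Mean coverages are then multiplied by `min_library / library(s)`
(scaling to the smallest library in Gbp) and closed to percentages within
each sample over the MAG set under analysis. Because the library scaling is
uniform within a sample it cancels in the within-sample proportions; both
layers (normalized coverage and relative abundance) are therefore retained
and written, and relative abundance is the default input to every
downstream stage. A sample in which nothing is detected is flagged and
carries missing values rather than a silently all-zero column.

## Habitat specificity

A MAG is host (coral) specific when all three criteria hold
simultaneously: (1) mean relative abundance across coral samples strictly
exceeds the mean across seawater samples (coral:seawater ratio > 1; a MAG
absent from seawater with any coral signal has ratio +∞ and passes); (2)
detected in strictly fewer than 50 % of seawater samples; (3) strictly
below 0.1 % relative abundance in every seawater sample. Means include
zeros for samples where the MAG is undetected, which keeps criteria 1 and 3
on the same closed scale. All three inequalities are strict, following the
printed thresholds. A MAG detected nowhere is labelled `undetected` and
excluded from enrichment. The conjunction deliberately tolerates
horizontally acquired symbionts: a genuine symbiont may occur in seawater,
but only rarely and at trace abundance.

## Comparative statistics

* Genomic features (genome size, GC, gene count, coding density) are
  compared between habitat groups with tie-corrected Kruskal–Wallis tests
  (chi-square reference, k − 1 df), BH-adjusted across the four features.
* Functional enrichment binarizes annotation counts at ≥ 1 copy and applies
  the two-sided Fisher exact test per feature (p = sum of hypergeometric
  point probabilities no larger than the observed table's), BH-adjusted
  *within* each namespace (KO, Pfam, CAZy are separate testing families,
  matching how such catalogs are reported). Significance is read at
  adjusted p ≤ 0.05, inclusive.
* Orthologous-cluster enrichment across water-quality categories weights
  each cluster's frequency by the relative abundance of the organisms
  encoding it — `W(c, s) = Σ_m count(c, m) × abundance(m, s)` — and
  compares weights between every unordered category pair with a two-sided
  Mann–Whitney U test. Raw p (< 0.05) is the primary readout, matching the
  original unadjusted convention; BH-adjusted values are also emitted. The
  U test is exact by enumeration of group assignments (valid under ties)
  whenever `n1·n2 ≤ 400` **and** `C(n1+n2, n1) ≤ 2·10⁵` — the second guard
  exists because the binomial coefficient, not the product, governs
  enumeration cost — and otherwise uses the tie-corrected normal
  approximation.
* Benjamini–Hochberg adjustment is the step-up tail minimum, returned in
  input order and capped at 1 (delegated to statsmodels; verified against
  the literal definition in tests).

## Pathway completeness

KEGG-style module definitions are parsed with a recursive-descent grammar:
space-separated serial steps (AND, counted at the top level only), commas
for alternatives (OR, binds tighter than space), plus for complex subunits
(AND within a step, binds tightest), minus for non-essential components
(neither required nor counted), parentheses for grouping; a parenthesised
sub-sequence counts as a single step. Standalone `--` gap tokens are
ignored with a warning. Completeness is `100 × satisfied steps / total
steps`; the reporting flag is strictly above 75 %. Counting steps at the
top level mirrors the dominant convention of annotation tools; nothing
prevents scoring nested sequences differently, but the choice must be fixed
for completeness to be well defined.

## Community ecology

Relative abundances are Hellinger transformed (square root of within-sample
proportions) before Bray–Curtis, making the distances invariant to
per-sample rescaling and tempering double-zero inflation; binary
Bray–Curtis (= Sørensen) serves the functional presence/absence analyses.
PCoA eigendecomposes the Gower-centered matrix; negative-eigenvalue axes
are dropped (magnitudes logged, no Lingoes/Cailliez correction, matching
the uncorrected default of the reference ordination routine) and axis signs
are fixed deterministically. Distance-based RDA regresses the PCoA
coordinates on the centered constraint design (indicator matrix for a
factor, the variables themselves for a numeric constraint); eigen-analysis
of the fitted component yields the constrained axes and, by orthogonality,
constrained + unconstrained inertia equals total positive inertia exactly.

PERMANOVA is single-factor, using the distance partition `SS_total =
Σd²/n` and within-group sums; p-values come from free permutation of the
labels with the +1 convention `p = (1 + #{F_perm ≥ F_obs}) / (1 +
n_perm)`, so 999 permutations floor at 0.001. (For balanced two-group
designs the mirrored labelling reproduces the observed statistic, so the
attainable p there is 2/(n_perm + 1).) An exhaustive-enumeration variant
exists for small fixtures. Environmental fitting regresses each variable
(pairwise-complete, centered) on the first two ordination axes; r² is the
regression coefficient of determination, the arrow is the unit-normalized
coefficient vector, and permutation p shuffles the variable. Pairwise
post-hoc tests use the between-centroid r² on the pair's ordination scores
with label permutation — the referenced R routine's internal statistic is
undocumented, so this transparent equivalent is used and exact agreement
with it on real data is not claimed. Environmental preprocessing Z-scores
each variable (sd with n − 1) and prunes collinearity in input-column
order, removing any column whose Pearson |r| strictly exceeds 0.7 against
an already-retained column (the removal and its partner are logged);
variables with envfit R² > 0.65 and adjusted p ≤ 0.05 feed the final
constrained ordination.

## Synthetic studies

The generator emulates the study design rather than its sequence data: 22
coral + 6 seawater samples over 6 sites in 5 water-quality categories, 40
host-specific + 30 seawater-specific MAGs by default. Completeness and
contamination are truncated normals on [75, 100] and [0, 25/3] whose
location parameters are solved numerically so the *truncated* means equal
91.2 % and 2.03 % (plain clipping would bias them); the contamination cap
guarantees every generated bin passes the quality score. Host bins draw
larger genomes and lower GC than seawater bins. ANI is background-uniform
(76–94 %) with planted cross-bin strain pairs at 99.2–99.9 %.

Coverage is log-normal with MAG- and sample-level effects — the paper
gives no dispersion model, so the log-normal is a modeling choice matching
the heavy-tailed abundance range such studies report (four orders of
magnitude). Raw coverage scales with library size (libraries log-uniform on
2–100 Gbp for coral, 2–30 for seawater), and covered fraction follows the
saturating map `1 − exp(−coverage/κ)` with κ = 1, which gives a closed
form for planting sub-threshold occurrences. Host bins receive trace
"spill" coverage in at most two seawater samples at a level far below the
0.1 % criterion, so noise-free recovery is exact by construction and
label flips under the default noise (σ = 0.5 on log coverage) are rare.
Coral community composition loads on a planted site-level nutrient
gradient: the log-coverage effect is `1.5 × strength × β_m × g_s` with
per-MAG loadings β ~ N(0, 1); `strength` is a dimensionless gain, not an
exact correlation target — the mapping from gain to the realized
correlation with a Bray–Curtis PCoA axis has no closed form, so tests
assert alignment and monotonicity in the gain rather than a point value.
Environmental variables are site-level means plus within-site noise, with
two deliberately collinear pairs (PP ≈ POC, DIP ≈ Si, r > 0.9) to exercise
the pruning and one variable with no site structure at all to serve as a
permutation-null control. Annotations plant a designed number of features
per namespace whose presence log-odds differ between habitat groups by 2.5
(alternating direction); all other features are exchangeable.

What the generator does **not** emulate: real taxonomic covariance
structure, compositional correlations between MAGs beyond the single
gradient, sequencing or binning artifacts, chimeric bins, or annotation
error. Passing tests therefore demonstrate the correctness and calibration
of the statistical machinery under the stated design, not performance on
real sequencing data.

## Numerical choices and problem sizes

Detection, quality, completeness and ANI thresholds are inclusive (≥);
the three specificity criteria and the collinearity/envfit/module-report
thresholds are strict, as printed. Permutation defaults are 999 (the
one-command demo lowers this to 199); all permutation procedures are
bit-reproducible under a fixed seed via `numpy.random.default_rng`. Test
and acceptance simulations run at the study's own scale (70 MAGs, 28
samples) with 20–50 replicate seeds for calibration checks and 500 null
replicates at n = 20 with 199 permutations for the PERMANOVA type-I-error
check; these sizes give Monte-Carlo intervals comfortably inside the
asserted bounds. Degenerate inputs (empty catalogs, all-zero samples,
constant variables, single-member groups) are either handled with flagged,
empty-but-valid outputs or rejected with named errors, never silently
coerced.
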