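# Methods

## Data model

A map experiment is declared by an `ExperimentDesign`: an ordered fraction
scheme (default the six pellets 1K, 3K, 6K, 12K, 24K, 80K), condition
labels, a replicate count, and an explicit column→(condition, replicate,
fraction) mapping. Column mappings are never inferred from names — naming
schemes are site-specific — but a `pattern` shortcut generates systematic
names. Quantities recorded as 0 are stored as missing throughout: in
label-free MS output a zero means "not quantified", and the
consecutive-fraction filter below depends on presence/absence.

## Filtering and normalization

Label-free profiles are retained when intensities are present in at least
`min_consecutive_fractions` (default 4) consecutive fractions of the
ordered scheme, and (when MS/MS metadata exist) when the mean MS/MS count
per fraction is at least `min_mean_msms` (default 2). The MS/MS filter is
skipped when the metadata column is absent — generic tables lack it, and
DIA MS/MS counts are not comparable to DDA counts. Retained profiles are
0-1 normalized over their non-missing values; fractions that were missing
but passed the consecutive rule are then set to 0, so every retained row is
a complete numeric vector (downstream distances require one).

SILAC ratios are kept with more than `silac_min_count` (default 2)
quantification events, or exactly that many with ratio variability below
`silac_max_variability_percent` (default 30). Per-fraction median
normalization is computed **after** this filter, on the retained ratios
only, so rejected low-quality ratios cannot distort the medians (the
processing order is otherwise ambiguous). Ratios are inverted (the
reference channel is heavy), only complete profiles survive, and 0-1
normalization follows.

Artifact filtering (reverse, contaminant, only-by-site) and the per-profile
filters are row-local, so their order does not affect the result; this is
asserted by a test.

## Protein-group alignment

Groups are aligned across experiments in three phases: (1) single-locus
groups are reduced to the canonical accession when the group contains it,
else to the first listed isoform, and reduced ids present in every
experiment match as `primary id`; (2) remaining multi-gene groups are
matched greedily from the largest down, each with its largest remaining
subset in every other experiment, flagged `multiple genes` or `gene level
conflict` depending on locus agreement; (3) leftover single-locus groups
reduce as in phase 1. Subset relations in phase 2 are evaluated at the
**locus** level, because isoform accessions covering the same loci differ
between search-engine runs; accession-level subsets would miss exactly the
matches the conflict flags describe. Ties break deterministically: largest
accession count, then lexicographic sorted locus list; candidate subsets by
locus count, shared accessions, lexicographic order.

## Quality metrics

*Joint PCA.* Profiles of all compared maps are concatenated, each fraction
centered and scaled to unit variance **on the concatenated matrix** (one
shared space), then decomposed. Scores are returned per map; an optional
variance-scaled view multiplies each component by its explained-variance
share, which is the correct scaling when distances in the plot are read as
displacement (translocations).

*Intra-complex scatter* (precision): per map, the L1 distance of each
subunit profile to the element-wise median profile of its complex (the
median profile, not a medoid). Per protein, distances are divided by that
protein's median distance across all compared experiments (or a chosen
reference experiment), then aggregated per (complex, map) by median over
subunits. Complexes need at least 5 subunits covered in every compared map.
A protein with distance 0 everywhere normalizes to 1 (0/0 := 1) and is
flagged rather than propagating NaN.

*Inter-map scatter* (reproducibility): per protein, the mean L1 distance of
its replicate profiles to their mean profile; summarized at a configurable
quantile (default 0.70).

## Localization SVM

Features are the concatenated replicate profiles of one condition (3 × 6 =
18 dimensions by default); replicates as extra dimensions retain replicate
information that averaging would discard. Markers are split 70/30 per
compartment (stratified, seeded); classes with one profiled marker go
entirely to training with a warning. The C/gamma grid is log₂-spaced,
C ∈ 2⁻²…2¹⁰, gamma ∈ 2⁻⁹…2³, with one refinement pass at half-step spacing
around the optimum; when several experiments are loaded, one shared
(C, gamma) maximizes the **summed** fivefold CV accuracy, keeping
performance comparable across experiments. Probabilities come from
fivefold cross-validated Platt scaling
(`CalibratedClassifierCV(SVC, cv=5, ensemble=False)`); the predicted
compartment is the argmax of the calibrated probabilities, so the reported
probability always belongs to the predicted class. Confidence classes bin
the winning probability with strict inequalities: > 0.95 very high, > 0.8
high, > 0.65 medium, > 0.4 low, otherwise best guess (0.95 exactly is
"high"). Evaluation reports the misclassification matrix on the full
hold-out set, per-class recall/precision/F1, the overall F1 (micro-averaged
— in full-coverage multiclass prediction this equals the proportion of
correctly predicted markers; a macro average is also reported), and mean ±
SD over 20 class-stratified 75% subsamples of the test set.

## MR translocation analysis

Proteins must be complete in all six maps; profiles whose smallest pairwise
replicate cosine similarity within either condition is below 0.9 are
removed (strictly below — a minimum of exactly 0.9 survives). Delta
profiles are computed within cognate replicate pairs (default pairing by
replicate index, overridable) as treated − control.

Deltas are differences of compositions and therefore sum exactly to zero,
so their 6-dimensional scatter matrix is singular. The outlier test
projects deltas onto an orthonormal basis of the zero-sum subspace (a
Helmert contrast) and uses χ² with **F − 1 = 5 degrees of freedom**; a raw-F
mode exists for comparison but will reject the singular scatter. Location
and scatter are estimated by the Minimum Covariance Determinant with
support fraction 0.75; per protein, the median of the squared robust
Mahalanobis distances over 31 refits with consecutive random states
stabilizes the stochastic subset search. `support_fraction = 1` means no
trimming and is implemented as the classical estimator (mean, ML
covariance) directly — the MCD consistency correction and reweighting would
otherwise make the untrimmed case disagree with classical Mahalanobis
distances.

The three replicate p-values combine by Fisher's method (X² = −2Σln p, 6
df); p-values of exactly 0 are clamped at 1e-300 with a warning.
Benjamini–Hochberg adjustment runs across **all** tested proteins (post
consistency filter), and M = −log₁₀(q); FDR 5% corresponds to M > 1.3. The
R score is the median pairwise Pearson correlation of a protein's replicate
deltas (undefined, and reported missing, for zero-variance deltas).
Significance requires M > 1.3, R > 0.75, and at least two replicate
p-values below 0.1.

## Downstream analyses

Significant shifts are clustered by complete linkage on 1 − r of their mean
delta profiles; the signed distance (not 1 − |r|) keeps anti-correlated —
biologically opposite — shifts apart. The flat-cluster threshold has no
default and must be supplied: the reference workflow chooses it by visual
inspection of the dendrogram. Enrichment uses a one-sided (greater) Fisher
exact test of each term in each cluster against the full set of
transitioning proteins, BH-corrected across all (cluster, term) tests at
10% FDR; clusters without a passing term stay unlabeled.

The cycling analysis clusters a curated candidate list by the Euclidean
distance between **rows of the pairwise delta-correlation matrix** —
phenotype similarity to all other candidates — which is more robust than
clustering the raw deltas for subtle, correlated shifts.

Endosomal shift magnitude: per condition, the mean endosomal profile is the
element-wise mean of the endosome markers' replicate-mean profiles; per
protein, Δcorr is the condition-matched difference of Pearson correlations
with that reference (treated minus control; the reference is matched to
each condition, not pooled). Δcorr is robustly z-scored, z = (Δcorr −
median) / (1.4826 · MAD) — 1.4826 being the normal-consistency constant —
and binned: z < 0.5 no relevant shift, then very small / small / medium /
large at unit steps, > 4 very large.

## Synthetic maps

The generator emulates the structure the analysis assumes: 11 compartments
with unit-sum prototype profiles over six fractions, 50 proteins and 30
markers per compartment by default, ~10 stable complexes whose members
share one jittered profile (tightness 0.02), per-protein jitter 0.05 around
the compartment prototype, and planted translocations
`(1−λ)·source + λ·destination` with λ ∈ [0.5, 1].

Prototype design: each compartment has a distinct dominant fraction; two
pairs deliberately overlap (Golgi/endosome in the 12K–80K range,
nucleus/chromatin in 1K) to emulate the compartment blending seen in real
HeLa maps. No prototype component exceeds ~0.5: under compositional
closure, the dominant component of a profile absorbs the profile's summed
measurement noise, so extreme dominance would give those proteins
systematically wider null deltas than the rest and bias the outlier test's
calibration.

Noise has two components, mirroring how comparative maps are produced:

1. **Batch (fractionation) noise** — multiplicative log-normal per protein
   and fraction, sigma 0.1, drawn once per replicate and shared by the
   cognate control/treated maps of that replicate. Maps of one replicate
   are fractionated in parallel, which is exactly why the MR method
   subtracts profiles within cognate pairs: this shared component cancels
   in the delta. It drives inter-replicate scatter and the SVM's noise
   burden.
2. **Per-map measurement noise** — drawn isotropically in the zero-sum
   tangent space of the simplex with scale 0.01 and truncated at the
   detection floor of zero. A perturbation of a composition is zero-sum by
   definition; modeling the residual per-map error this way makes null
   deltas exchangeable across proteins, which is the regime in which the
   χ² calibration of the robust outlier test holds.

Optional DDA-like missingness is independent Bernoulli per (protein,
fraction, replicate); profiles losing the required consecutive run drop
from that map, and survivors renormalize over their observed fractions.
Planted movers are sampled from non-marker, non-complex proteins whose
compartment has a destination at total-variation distance ≥ 0.6 (so that
λ ≥ 0.5 always displaces a substantial share of profile mass); the
separation threshold is configurable.

What the generator does **not** emulate: protein-abundance-dependent noise
(intensity-CV relationships), correlated missingness along chromatographic
runs, batch effects across days or instruments, and shared-peptide
quantification artifacts between protein groups. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated generative model, not performance guarantees on any
particular real dataset.

## Problem sizes and numerical choices

The calibration and recovery analyses use 2000-protein collections
(182/compartment) and 30 planted movers; classifier evaluation uses the
default 550-protein maps. These sizes give binomial standard errors of
about 0.005 on a tail probability of 0.05, small enough to detect
meaningful miscalibration while keeping a full run in minutes on one CPU.
Other numerical choices: profile sums are validated to 1e-9; session
archives round-trip numerically to 1e-12 (JSON decimal text); BH q-values
and p-values are floored at 1e-300 before logs; eigenvector signs in PCA
are arbitrary (tests compare up to sign); MCD refits use consecutive seeds
`seed+0 … seed+30`.

## Known limitations

* The degrees-of-freedom policy for the outlier test (zero-sum projection,
  df = F−1) is this package's documented choice; raw-F mode is provided for
  comparison but is not meaningful on exactly zero-sum deltas.
* Group alignment relies on a user-supplied accession→(canonical, locus)
  table; no online lookups are performed.
* The benchmark command matches sessions by stored protein ids; run the
  alignment module first when comparing searches with incompatible group
  definitions.
* Enrichment treats annotation terms as independent; no term-hierarchy
  (e.g. GO graph) correction is attempted.
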