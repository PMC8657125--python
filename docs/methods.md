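# Methods

## Scoring pipeline

### ER status from ESR1

ER status is inferred from the marker gene's cohort distribution, which is
bimodal in any cohort mixing ER-positive and ER-negative disease. A
two-component one-dimensional Gaussian mixture is fitted (scikit-learn, 10
random restarts, fixed seed) and the component with the larger mean is
taken as ER-positive; a sample's status is the component with posterior
probability ≥ 0.5, and the reported threshold is the marker value where the
posteriors are equal (solved between the two component means). The fit is
declared degenerate — and the caller told to supply IHC-based status
instead — when the smaller component weight falls below 0.05 or the
component means are closer than 0.5 log2 units: below that separation the
equal-posterior threshold is numerically meaningless and the "bimodal"
premise has failed. Labels are invariant under adding a constant to the
marker (the threshold shifts with it).

### ER-weighted centering

Nearest-centroid subtyping assumes the incoming profile is centered the
way the centroid training population was. The reference population was 60%
ER-positive; a cohort that is, say, 80% ER-positive drags plain per-gene
means toward the ER-positive expression pattern and biases every
correlation. The correction: for each gene compute the ER-positive and
ER-negative class means and center on `w·mean_pos + (1−w)·mean_neg` with
`w = 0.6` (configurable). With both classes present this reproduces a 60%
ER+ pseudo-population exactly; by definition the weighted class means of
the centered data are zero per gene (asserted to 1e-9 in tests). Each
platform/preparation is centered separately — centering is a within-cohort
operation, so macro and bulk matrices are never pooled. If one class is
empty the weighted reference is undefined and the code requires an
explicit flag to fall back to plain mean centering.

### Subtyping on 46 genes

Pearson correlation of each centered 46-gene profile against the five
centroids; four genes (BIRC5, CCNB1, GRB7, MYBL2) are excluded from the
panel for classification, a reduction established for the clinical assay.
The normal-like centroid participates in the call but its correlation is
never an input to the risk score; the result type exposes the four
risk-score correlations through a separate accessor so the exclusion is
structural, not conventional. Ties in the argmax are broken by the fixed
subtype order (Basal, Her2, LumA, LumB, Normal) and flagged; they cannot
occur on continuous data but the tie-break must be deterministic.
Zero-variance profiles make the correlation undefined and raise an error
naming the sample.

### Proliferation and ROR

The proliferation score is the unweighted arithmetic mean of 18
proliferation-associated genes, computed on the same ER-weighted centered
matrix as the centroid correlations — the risk formula mixes the two, so
they must share a coordinate system. (`prolif` on uncentered data would
shift every score by a cohort constant.) All 18 genes are required; a
17-gene mean would silently rescale the score. The continuous ROR is the
fixed linear form

    ROR = 54.7690 · (−0.0067·Basal + 0.4317·HER2 − 0.3172·LumA
                     + 0.4894·LumB + 0.1981·prolif + 0.1133·T + 0.8826)

with the constants frozen in an immutable dataclass. The 0–100 statement
is treated as the calibrated range, not a transform: raw values are
reported with a `clipped` flag when outside [0, 100], and truncation is
opt-in for display parity with the commercial report.

### Risk categories

Cutoffs are (40, 60) for node-negative disease, (15, 40) for 1–3 positive
nodes, and ≥ 4 positive nodes is high risk at any score. The published
statements give cutoffs without inequality directions; the printed
categorized scores pin the convention (a score of 39.94 is low, 60.06 is
high), giving low ≤ lower < intermediate ≤ upper < high. All 26 published
category assignments for the 13 packaged discordant cases reproduce under
this convention, which the test suite asserts.

## Concordance statistics

`r²` is the square of the Pearson correlation coefficient over shared
samples, not a regression R² through the origin. Signed score differences
are always first argument minus second (so a macro-vs-bulk comparison
reports macro − bulk, matching the packaged reference table's sign).
Comparisons run on the intersection of sample IDs and warn with counts
when cohorts mismatch. Discordance records are sorted by signed difference,
descending; the eligibility preset `er_pos_her2_neg_pn0` (ER-positive,
HER2-negative, node-negative — the population eligible for commercial risk
testing) is a named filter rather than a free-form expression so the
subset selection is auditable. Per-gene cross-platform correlation reports
one Pearson r per shared gene across shared samples, flags genes at or
below 0.75 (configurable), marks the 18 proliferation genes, and reports
zero-variance genes as NaN-flagged rather than raising — one degenerate
gene should not abort a 50-gene report.

## The synthetic centroid set

The published centroid matrix is proprietary-adjacent supplementary data
that cannot be redistributed here, so the packaged file
`data/synthetic_pam50_centroids.tsv` is a constructed stand-in, labelled
synthetic. It encodes the documented qualitative structure: a 21-gene
proliferation block high in basal-like and luminal B and low in luminal A
and normal-like; a luminal/ER block (ESR1, PGR, FOXA1, ...) high in the
luminal subtypes; the ERBB2/GRB7 amplicon defining HER2-enriched; basal
keratins and associated genes (KRT5/14/17, SFRP1, FOXC1, ...) high in
basal-like and moderately elevated in normal-like; plus small seeded
jitter so no two centroids are colinear. Values are in centered log2
units roughly in [−2, 2]. Every loader accepts an external centroid TSV,
so analyses of real data can drop in the published file.

## The purity simulator

### What it emulates

Each simulated tumor has a true subtype `k` drawn from configurable
proportions (defaults: basal 0.14, HER2 0.06, luminal A 0.52, luminal B
0.28, normal-like 0 — the composition of the 94-tumor study cohort). Its
latent tumor profile is `centroid_k + N(0, noise_sd)` per gene on the
50-gene log2 panel; a latent normal-epithelium profile is the normal-like
centroid plus the same noise (the centroid is the only in-scope
representation of normal breast epithelium). The two preparations are
convex mixtures at per-sample tumor purity:

- **macro**: purity ~ Uniform(0.85, 1.0) — macrodissection enriches but
  does not perfect tumor content;
- **bulk**: purity ~ Beta(4, 1.5) (mean 0.73, long left tail) — biopsies
  without enrichment, occasionally dominated by normal tissue;

and the bulk matrix additionally receives a per-gene affine platform
distortion (slope ~ N(1, 0.1), offset ~ N(0, 0.3)) plus a second noise
draw, emulating the systematic differences between hybridization counting
and RNA-seq. Measurement noise defaults to sd 0.3 log2 units, a typical
replicate-level spread for either platform. Clinical covariates are drawn
to match the study cohort: P(tumor > 2 cm) = 0.37, node classes
(0.68, 0.32, 0) for pN0/pN1–3/pN4+. ER truth follows the generative model
(luminal ⇒ ER-positive), which at the default proportions yields the
cohort's 80% ER-positive fraction; the `er_pos_fraction` field is validated
against the luminal share rather than sampled independently, since ESR1
levels come from the centroids. All draws come from one seeded generator;
identical configs are bit-identical.

Mixing is performed directly in log2 space. The centroids exist only in
centered log-ratio coordinates, so linear-space mixing would require an
arbitrary inverse transform; log-space mixing is a stated simplification
that keeps profiles on the interpolation line between tumor and normal
centroids. A `linear_mix` option mixes `2^x` values instead for
sensitivity checks.

`replicate_assay` simulates an independent high-purity re-measurement of
an existing cohort (fresh noise, fresh macrodissection purities, no
platform distortion) and serves as the stand-in for an external reference
assay of the macrodissected preparation.

### What it does not emulate

No FFPE RNA degradation, probe-level counting noise, lymphocyte
infiltration, intra-tumor subtype heterogeneity, or per-subtype purity
differences (real normal-like-called tumors have systematically lower
cellularity; the simulator draws purity independently of subtype).
Passing simulation tests therefore demonstrate that the pipeline's
machinery responds correctly to purity dilution and platform distortion —
not that real-cohort statistics are reproduced quantitatively. In
particular the simulated reference assay shares this package's classifier,
so reference-vs-pipeline subtype concordance is near-perfect in simulation,
unlike comparisons against an independent proprietary algorithm.

### Contamination curves

`contamination_curve` generates single-subtype replicate sets along a
descending purity grid. A single-subtype set has no cohort structure, so
the ER split and weighted centering are undefined there; replicates are
generated in centroid (centered) coordinates and scored directly against
the centroids with T = 0. The curves show mean ROR falling and the
normal-like call rate rising as purity falls — the mechanism behind the
bulk-tissue effects.

## Numerical choices and degenerate inputs

- Pearson correlations are computed by a vectorized kernel checked against
  a plain-Python textbook implementation to 1e-12.
- TSV round-trips use 6-decimal formatting (read-back tolerance 1e-6).
- Matrices must be finite; duplicate genes (including collisions created
  by alias resolution) and duplicate samples are hard errors with the
  offending name in the message.
- Gene aliases resolve legacy symbols (ORC6L→ORC6, KNTC2→NDC80,
  CDCA1→NUF2, ERS1→ESR1, ...) idempotently before any validation.
- Test problem sizes: cohorts of 94 samples (the study size; 200 for the
  normal-like inflation property), 20–50 seeds for stochastic properties,
  100 replicates per contamination-curve point.

## Known limitations

- The synthetic centroids preserve structure, not measured values;
  absolute correlation magnitudes and subtype-boundary geometry differ
  from the published centroids.
- The ER-status threshold is a cohort-level model fit; cohorts with
  extreme ER imbalance will trip the degeneracy guard and need external
  ER labels.
- The commercial assay's own algorithm is not implemented; its outputs
  can only enter as reference columns in the clinical table.
- Risk categorization uses published cutoffs only; no survival modelling
  or treatment-recommendation logic is included.
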