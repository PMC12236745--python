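# Methods

`periomics` implements the analysis layer of a two-cohort perinatal
antibiotic study in mice: dams receive ampicillin (AMP) or vehicle (PBS)
for two consecutive days either before delivery (antepartum cohort) or
shortly after (postpartum cohort), and fecal samples are profiled
longitudinally by untargeted LC-MS/MS metabolomics and shallow shotgun
metagenomics. This note describes the models and procedures, the
parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Exact-mass chemistry

All m/z arithmetic is monoisotopic, with atomic masses pinned in-code to
the IUPAC 2021 evaluation for reproducibility without external lookups.
Adduct deltas are electron-corrected: the proton is 1.007276 Da (not the
hydrogen atom's 1.007825), and [M+NH4]+ adds 18.033823 Da. The correction
matters — it is what places computed values within 2 mDa of 4-decimal
instrument-reported ions such as protonated ampicillin (computed 350.1169)
and the ammonium adducts of the hexose-conjugated bile acids (695.3783 and
588.3742). Conjugation is formula addition with loss of one water, e.g.
taurocholic acid C26H45NO7S + hexose C6H12O6 − H2O → C32H55NO12S.

The bile-acid diagnostic ions derive from the C24 steroid core with *n*
hydroxyls, formula C24H40O(n+2): in positive mode the characteristic
fragments are [M+H−(n+1)·H2O]+ and [M+H−(n+2)·H2O]+, reported at 2-decimal
rounding (337.25/319.24 for the trihydroxylated core). The two carnitine
diagnostic fragments are computed as electron-corrected cations,
trimethylammonium C3H10N+ (60.0808) and the dehydrated carnitine acylium
C4H5O2+ (85.0284). Instrument-calibrated literature values for these two
ions differ by 0.3–0.5 mDa from the computed cation masses; the query
engine's 0.01 Da tolerance covers both conventions and the package does
not adjudicate between them.

## Modified cosine and cross-cohort tracing

The modified cosine between two MS/MS spectra allows a fragment pair to
match either directly (|Δm/z| ≤ 0.02 Da) or shifted by the precursor mass
difference; over the resulting candidate set a one-to-one peak assignment
maximizing the summed products of weights (intensity^0.5, the molecular
networking convention; configurable) is scored against the product of the
two spectra's weight norms, bounding the score in [0, 1] by
Cauchy–Schwarz.

The assignment is solved exactly with the Hungarian algorithm on the
candidate weight matrix rather than by the common greedy
sort-and-accept heuristic. For centroided stick spectra of ≤ tens of
peaks the cost is negligible, and exactness makes the score provably
equal to exhaustive assignment enumeration — a property the test suite
checks on 1,000 random spectrum pairs.

Cross-cohort tracing scores all feature pairs with precursor difference
< 0.02 Da and retains those with |ΔRT| < 0.3 min, cosine > 0.7 and ≥ 5
matched peaks (all boundaries strict on the stated side). The
minimum-matched-peaks condition is stated for networking but not
explicitly for the pair filter; it is applied by default and can be
disabled (`apply_min_peaks=False`, `--no-min-peaks`). Pairs within one
cohort are excluded; a feature with several cross-cohort partners keeps
all passing pairs. Each pair carries the treatment direction of both
members (from VIP selection for metabolites, from the differential test
for taxa) and a concordance flag (both up or both down).

## Diagnostic fragment-ion queries

A query is a conjunction of MS2PROD clauses — target m/z, tolerance
(default 0.01 Da) and intensity floor as percent of the base peak
(default 5%) — matching a spectrum iff every clause finds a qualifying
peak. The parser accepts the run-together spellings (`WHEREMS2PROD=`,
`ANDMS2PROD=`) found in shared query lists. Matching is invariant to
global intensity scaling. Five built-in queries cover the mono- through
penta-hydroxylated bile-acid cores; should a dense water-loss ladder
match two of them, the more-hydroxylated label wins, as the
higher-water-loss ions are the more specific evidence. The carnitine
query reuses the bile-acid tolerance and floor since only the two target
m/z values are conventionally specified.

## Compositional statistics

Peak areas and taxon counts are compositions, so all multivariate
statistics run on the robust centered log-ratio (rclr) transform: per
sample, observed (non-zero) entries become ln x minus the mean log of
that sample's positive entries; zeros are recorded in a mask and left at
0. This keeps the transform scale-invariant per sample without a
pseudocount; masked zeros contribute nothing to downstream Euclidean
distances (the masked-as-zero convention of the robust-clr literature —
pairwise-observed distances are a documented alternative not
implemented).

PCA is centered SVD on the transformed matrix. PERMANOVA computes the
permutational pseudo-F from squared Euclidean distances (Aitchison
geometry on rclr data) with seeded label permutations and
p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1), so p is never 0 and its
minimum is 1/(n_perm + 1). Permutations are unrestricted; the study's
repeated-measures structure (multiple timepoints per dam) would call for
within-dam strata, which is left as a limitation — treatment-phase
testing uses few timepoints per animal, limiting the distortion.

Shannon diversity is −Σ p ln p (natural log) on proportions after
rarefaction to the minimum sample depth (multivariate hypergeometric
subsampling, seeded). Group contrasts of diversity use the two-sided
Wilcoxon rank-sum test, exact for ≤ 25 total observations without ties.

## PLS-DA and VIP selection

Two-class PLS-DA regresses a {0, 1} arm indicator on the centered,
unit-variance-scaled feature matrix with 2 latent components (matching
common practice and 2-D ordination figures; model selection is out of
scope). Constant features are dropped with a warning. Variable
importance in projection is

VIP_j = sqrt( p · Σ_k SS_k (w_jk/‖w_k‖)² / Σ_k SS_k ),

with SS_k the class variance explained by component k; the definition
forces mean(VIP²) = 1 exactly, which the tests assert on every fit.
Features with VIP > 1 are labelled up/down by the sign of the
treated-minus-control mean difference on the scaled data (ties are
non-significant). Model quality is the leave-one-out classification
error rate (CER; prediction threshold 0.5), with an optional
label-permutation p-value; CER < 0.5 marks a discriminatory model.
Discriminant models are fit on treatment-phase samples only, mirroring
the study design of classifying during administration; a flag includes
all timepoints.

## Dirichlet–CLR differential abundance

The taxon-level two-group test is a Monte-Carlo Dirichlet–CLR procedure:
for each of 128 instances, each sample's composition is drawn from
Dirichlet(counts + 0.5), CLR-transformed, and Welch-tested per taxon
between arms. The per-taxon p-value is the mean over instances (the
expected p-value), corrected by Benjamini–Hochberg across taxa; the
effect size is the median over instances of the standardized CLR
difference (group-mean difference over the pooled SD). Instances are
drawn before the group split, so swapping labels flips every effect sign
exactly. GLM modes and alternative denominators (e.g. iqlr) of richer
differential-abundance frameworks are out of scope — the study design
needs only the two-group test with BH.

## Longitudinal log-ratio statistic

The normalization-free longitudinal summary is, per sample,
ln(Σ areas of treatment-associated features / Σ areas of
control-associated features), with the sets supplied by VIP selection
(metabolites) or the differential test at q < 0.05 (taxa). Per timepoint
a two-sided Welch test compares arms, with BH applied across the
timepoint family within one cohort (not pooled across cohorts, matching
per-cohort panels). Samples with an empty numerator or denominator sum
are dropped with a warning. For cross-cohort display the second cohort's
series can be shifted by the difference of pre-treatment means so both
cohorts share a pre-treatment baseline.

"Repeated Welch's t-test" is read as independent per-timepoint tests
rather than a repeated-measures model; with 5 dams per arm per timepoint
a mixed model would be poorly identified and the per-timepoint reading
matches the reported analyses.

## Cross-omics correlation network

Multiblock integration is reduced to its interpretable core: the top 20
features per omics block by |effect|, Pearson correlation across samples
present in both blocks, and edges where |r| > 0.7 with their sign. This
is a deliberate surrogate for latent-variable multiblock models (DIABLO
and kin), which are out of scope.

## The synthetic study generator

The generator emulates the study design so that every stage has a known
answer: two cohorts × two arms × 5 dams, longitudinal timepoints tagged
pre/treatment/post (antepartum GD14→PND21, postpartum PND1→PND21,
configurable since reported grids vary slightly between figures), blanks
with contaminants, and paired taxon tables.

Key parameters (defaults):

| parameter | default | meaning |
|---|---|---|
| baseline areas | log-normal, μ = ln 1e6, σ = 1 | per-molecule peak-area scale; the standard untargeted-metabolomics intensity assumption |
| measurement noise | CV 20% (log-normal) | per-sample multiplicative noise |
| dropout | 5% | zero-inflation of the feature table, exercising rclr zero handling |
| carnitine / bile / hexose folds | 8 / 0.125 / 8 | treatment effects during dosing |
| persistence | antepartum 0.6/timepoint, postpartum 0 | geometric decay of the log-fold effect into the post phase; reproduces the cohort contrast (antepartum effects persist to weaning, postpartum truncate) |
| m/z jitter | ≤ 4 ppm | cross-cohort batch shift, within the 5 ppm alignment budget |
| RT jitter | σ = 0.05 min | chromatographic batch shift |
| peak dropout | ≤ 15%, intensity-scaled | fragment loss between cohorts |
| cohort intensity rescale | log-normal σ = 0.3 | batch response factor |
| taxa | 40 (8 shared depleted at 6%, 3 cohort-specific enriched at 1% each, log-normal background) | mirrors reproducible depletion of abundant commensals with cohort-dependent enrichments |
| library size | log-normal, median 50,000 | desk-scale stand-in for real sequencing depth (~2M reads); 10% of samples generated under-depth to exercise read-count exclusion |
| Dirichlet concentration | 200 | overdispersion of the community around its expected composition |

Spectra are ≤ 12-peak stick spectra from chemistry-aware class templates:
carnitines carry the two diagnostic cations plus acyl-dependent losses;
a bile acid with n hydroxyls carries the [M+H−k·H2O]+ ladder for
k = 1..n+2; hexose conjugates add the 162.0528 Da neutral-loss aglycone
peak and the core ladder; remaining capacity is filled with reproducible
molecule-specific fragments so twin spectra share enough peaks to match.
Templates are generated per molecule and shared across cohorts before
jitter. Peak dropout scales inversely with relative template intensity —
weak peaks are the ones lost to the acquisition noise floor — so twin
recoverability is a design property rather than a coin flip; uniform
dropout at the same average rate would leave a material fraction of true
twins below the 0.7 cosine threshold by construction, defeating the
generator's purpose. Retention times of exact-mass isomers are spaced
≥ 0.8 min apart so identity is chromatographically resolvable, as it is
for real isomer series.

The ampicillin feature appears only in treated dams during dosing,
decaying steeply afterwards (5% carried to the first post timepoint),
emulating drug detection up to about two days after the final injection.
Because drug detection alone separates the arms, pure-null constructions
(`include_drug=False`) omit it.

What the generator does **not** emulate: isotope envelopes and adduct
networks, chimeric spectra, RT drift within a batch, compositional
correlation between metabolites and taxa beyond the designed effects,
inter-animal baseline variation (dams are exchangeable draws), and any
chromatographic peak-shape phenomena. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability under the
designed noise model — not performance on real instrument data, where
annotation transfer, batch drift and library-matching ambiguity dominate.

## Numerical choices and degenerate inputs

- Blank filter: kept iff mean(sample areas) ≥ 5 × mean(blank areas);
  blank mean exactly 0 keeps the feature unconditionally (avoids 0×fold
  comparisons); the boundary case (exactly 5×) is kept. Blank means use
  blank injections only, not QC-mix injections.
- "Relative abundance in any sample < 0.0001%" is read as a
  max-over-samples floor of 1e-6 as a fraction; configurable.
- Welch's test falls back to p = 1 when both groups are constant and
  equal; rank-sum returns p = 1 for identical multisets.
- rclr requires ≥ 2 positive entries per sample and rejects otherwise.
- PERMANOVA p can never be 0 (add-one permutation convention).
- Rarefaction above the shallowest sample's depth is an error, not a
  silent drop.
- All randomness flows from explicit integer seeds (numpy Generator);
  the pipeline derives per-stage child seeds from the global seed so
  stages can be rerun in isolation.

## Known limitations

Unrestricted PERMANOVA permutations ignore repeated measures; the
Dirichlet–CLR test assumes exchangeable samples within arm; LOO-CER on
small n has high variance and its permutation null is mildly
anti-conservative near 0.5; the cross-omics network is marginal
(pairwise) and does not model indirect correlations; headline counts of
a real study (numbers of matched or differential features) depend on the
deposited raw data and instrument scale and are not reproduced at desk
scale — the synthetic study recovers the qualitative design contrasts
instead.
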