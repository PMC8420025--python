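# Methods

This note documents the models and procedures tpakit implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model

The pipeline starts from a protein-group table with per-run raw and LFQ
(label-free-quantification-normalized) intensities. Zero intensity means
"not quantified" and is stored as missing; on output, missing cells are
written empty so the distinction survives round trips. Two parallel tracks
mirror standard practice: the **LFQ track** (log2, filter, impute, test,
cluster) carries the relative statistics, while the **raw track** feeds TPA
absolute quantification. Run metadata distinguishes biological samples from
technical replicates; every permutation procedure and per-sample summary
respects that hierarchy.

## Preprocessing

* **Presence filter** (`min_fraction`, default 0.70): protein kept iff some
  group quantifies it in ≥ 70% of that group's runs. Technical replicates
  count individually, since filtering happens before any replicate
  collapsing. Lowering the threshold provably retains a superset.
* **Imputation** (`width` = 0.5, `downshift` = 1.8, in units of the run's
  observed SD): per run, missing cells draw independently from
  N(μ_c − 1.8σ_c, (0.5σ_c)²). μ_c and σ_c use observed values only, with
  sample SD (n−1). Per-column is the default mode (the upstream software's
  default); a whole-matrix mode exists behind `per_column=False`. Observed
  cells are never altered and an `imputed_mask` records every replacement.
* **Row z-scoring** uses the population SD (n), the upstream convention;
  zero-variance rows are an error rather than silently NaN.
* **Run correlation** is pairwise-complete Pearson; pairs sharing < 3
  proteins yield a missing entry with a warning.

## TPA absolute quantification

c(i) = I(i) / (I_total · MW(i)) in mol per g total protein, reported as
pmol/mg (×10⁹ exactly). Design choices:

* The denominator sums raw intensity over the **full quantified table**
  (after decoy/contaminant removal, before the presence filter); the LFQ
  filter is a property of the statistical track, not of total protein mass.
  `restrict_to=` switches to the filtered set when wanted.
* **Average** (isotope-abundance-weighted) residue masses, not monoisotopic
  — appropriate at protein scale; one water per chain. Cross-checked against
  Biopython in the tests. Ambiguous residues (B/J/X/Z) are an error by
  default; a lenient policy substitutes the mean canonical residue mass with
  a warning.
* Protein groups (`;`-separated accessions) use the leading accession's MW.
* Mass conservation Σ c(i)·MW(i) = 1 g/g per run is the defining identity
  and is asserted in the tests at 1e−9 relative tolerance. Concentrations
  are invariant to any per-run intensity rescaling.

Note that TPA is compositional: raising one protein's abundance raises the
run's total signal and depresses every reported concentration in that run.
Measured fold changes of strong markers are therefore slightly smaller than
the planted intensity ratios.

## Differential statistics and permutation FDR

The two-sample statistic is SAM-style: d = (mean₁ − mean₂)/(SE_pooled + s0)
with s0 = 0.1 by default, damping low-variance/low-effect proteins. The
parametric p-value reported alongside is the classical pooled t at s0 = 0
(volcano axes only); significance comes exclusively from permutation. The
multi-group statistic is the one-way F with runs as observations.

FDR control: labels are permuted over biological samples — both technical
replicates of a sample always carry the same permuted label. Permutations
are **distinct** (sampled without replacement; all distinct relabelings are
enumerated with a warning when fewer than `n_perm` = 250 exist). Sampling
with replacement would occasionally duplicate the identity assignment, whose
contribution of the full observed signal to the null pool makes the
estimator erratic in small designs. For a threshold t,
FDR̂(t) = (mean null exceedances per permutation) / (observed exceedances),
the plain SAM ratio with no π₀ correction, clipped to [0, 1]. A protein's
q-value is the smallest FDR̂ over all thresholds that would reject it —
monotone in the statistic — so the significant set at a target FDR is
exactly the largest threshold set whose estimate meets the target, and
`significant ⇒ q ≤ target` holds by construction.

Two small-design caveats, both visible in the tests: with very few
group-size configurations (e.g. 3 groups × 3 samples) random permutations
reconstruct the true grouping often enough that the plain ratio cannot fall
below a floor of a few percent; and exact Mann-Whitney p-values at 5-vs-5
samples bottom out at 2/252 ≈ 0.0079, so a pairwise threshold of 0.01
demands complete separation.

Mann-Whitney U uses midrank ties; p is exact by enumeration when
n₁+n₂ ≤ 16 and tie-free, otherwise the tie-corrected normal approximation
(scipy's implementation; the exhaustive-enumeration oracle lives in the test
suite).

## Panels

A protein joins subtype s iff every pairwise Mann-Whitney comparison of s
against each other group (normal tissue included) on per-biological-sample
TPA concentrations has p ≤ 0.01 **and** the median differences share one
sign. The all-pairs rule does not by itself guarantee disjointness — a
protein can be consistently *up* in one subtype and consistently *down* in
another — so a doubly-qualifying protein is kept only in the panel with the
larger fold change. Fold change is the ratio of the subtype's median
concentration to the median over all other samples (inverted for down
markers); shortlists keep members above the per-subtype threshold
({ccRCC: 5, pRCC: 9, chRCC: 4, RO: 3}), ranked by fold change with ties
broken by concentration then accession, top k = 6. Dropout concentrations
count as 0 in the ranking — "not quantified" reads as "below detection".

## IHC diagnostics

Ordinal scores 0–3 encode percent tumor-cell positivity (0 negative, 1:
1–10%, 2: >10–50%, 3: >50%); LAMP1 uses staining patterns
(negative/diffuse/apical/focal). Dichotomization rules: PLIN2 and TUBB3
positive at score ≥ 2 (the ">10% of cells" reading), LAMP1 positive only
when diffuse, HK1 positive at score 3. HK1's published cutoff combines a
score threshold with a ">90% cell positivity" clause that the 0–3 abundance
scale cannot represent; score 3 ("abundant") is the closest ordinal reading
and is flagged here rather than asserted as exact. Metrics round half away
from zero to one decimal. Undefined ratios (zero denominator) are reported
as missing, never as 0.

## Synthetic cohort generator

The generator emulates the study design the pipeline assumes: five groups
(7 + 5 + 5 + 5 tumor samples + 5 normal), technical duplicates, ~2,500
proteins. On the log2 scale a cell is
base(protein) + effect(protein, group) + N(0, σ_bio) per biological sample
+ N(0, σ_tech) per technical replicate, with σ_tech < σ_bio enforced.

* **Base abundance** is log-uniform over 7 decades (default center 10^7.5)
  — chosen over log-normal to guarantee dynamic-range coverage.
* **Noise defaults** σ_bio = 1.0, σ_tech = 0.25 put technical-replicate
  correlations near 0.99 and same-group biological correlations near 0.95,
  preserving the qualitative ordering real cohorts show.
* **MNAR dropout**: P(missing) = expit(slope·(midpoint − log2 I)), defaults
  midpoint 20, slope 0.5, giving ≈ 30% overall missingness so the 70% filter
  is exercised non-trivially; slope = 0 disables dropout. Dropout
  probability is monotone non-increasing in intensity by construction.
* **Sequences** draw residues uniformly with lengths ~N(450, 150) truncated
  at 50, so the molecular-weight and TPA path runs end to end.
* Raw and LFQ tracks are identical by default; `lfq_scale_jitter` adds
  per-run scale noise to decouple them. `marker_log10_min` plants markers
  at quantifiable abundance when an experiment needs them clear of the
  dropout zone.

The IHC generator emits one score per case per marker from per-subtype
distributions, either multinomially (seeded) or deterministically by
largest-remainder rounding; the shipped default distributions encode the
validation cohort's staining patterns (40/26/12/30 tumor cases; normal
tissue is excluded from the 2×2 tables, matching the published
denominators — e.g. 77/78 specificity for HK1).

What the generator does **not** emulate: peptide-level digestion and
LFQ normalization artifacts, batch effects, correlated protein modules
(beyond planted markers), or per-case staining heterogeneity. Passing tests
therefore demonstrate the correctness and calibration of the procedures
under the assumed noise model, not robustness to real-data pathologies.

## Validation experiments (problem sizes)

The experiments module backs both the test suite and
`scripts/acceptance.py`; sizes are chosen to run in seconds on one CPU:

* **Null calibration**: 20 cohorts, 500 proteins, 5 groups × 5 samples × 2
  technical replicates, full pipeline (MNAR → filter → impute → permutation
  ANOVA at FDR 1%); mean significant fraction must stay ≤ 2%.
* **Marker recovery**: same design, 32 planted markers (|log2FC| = 2, half
  down-regulated, σ_bio = 0.3), run on complete data (no dropout): this is a
  power experiment for the statistics and panel rules, deliberately isolated
  from the missingness mechanism. ≥ 90% of markers must be significant and
  correctly paneled, ≤ 5% of nulls assigned anywhere.
* **Topology recovery**: cohorts with a shared ccRCC/pRCC program split into
  the proximal vs distal meta-groups at the k = 2 cut in ≥ 18/20 seeds.
* **Imputation moments**: 10⁵ draws in a μ = 20, σ = 2 column must match
  N(16.4, 1.0) within 0.02 on mean and SD; a KS test (α = 0.001, n = 10⁴)
  guards the full distribution.

## Known limitations

* Markers whose abundance sits near the MNAR midpoint lose power under the
  default dropout + imputation settings: a single down-shifted imputed cell
  inflates within-group variance by design. This is a real property of the
  downshifted-normal approach, not an implementation artifact.
* The plain permutation-FDR ratio is conservative when many strong effects
  exist (their permuted residual signal inflates the null) and saturates in
  very small designs; no π₀ correction is applied.
* The panel-membership rule is one operationalization of "distinguishes the
  subtype from every other group"; post-hoc contrasts or profile clustering
  would give different panel sizes on the same data.
* Diagnostic metrics carry no confidence intervals.
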