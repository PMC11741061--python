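# Methods

This note documents the models, conventions and design choices behind
`amidasekit`, in the order the pipeline runs.

## Synthetic study generator

The generator (`amidasekit.synthetic`) emulates a promiscuity screen of
amidase-signature (AS) enzymes at the statistical level the downstream
stages rely on. It is a first-class, tested component, not a fixture.

**Alignment.** Defaults: 16 enzymes, 200 alignment columns, a 160-column
signature region spanning columns 20–180. The catalytic lysine sits at
column 60 (0-based), the Gly/Ser-rich motif at columns 95–107 (conserved,
60/40 G/S), and the catalytic serines at columns 114 and 138 — the
K…motif…S…S layout of the AS family. Forty variable columns model
surface positions (per-enzyme residues drawn uniformly from the 20
amino acids); planted columns (default: one at column 150) are resampled
until at least two residues differ. Conserved background columns draw
from an 18-letter alphabet excluding K and S so that the triad and motif
are the only conserved landmarks of those letters; this is what makes
the triad detector in `trim_to_signature` well-posed on generated data.
A couple of columns outside the signature region carry gaps.

**Substrate panel.** Substrates come from a curated template list — nine
substituted anilides, a metoclopramide-like N-alkyl benzamide, two
primary benzamides, an acesulfame analogue, two 4-nitrophenyl esters and
three colorimetric anilides — mirroring a realistic panel: 12 HPLC
substrates and 5 plate-reader substrates with the evaluation times
100 min (4NP-butyrate), 600 min (4NP-trimethylacetate), 1250 min
(nitroacetanilide and the flutamide analogue) and 2600 min
(paracetamol). Requests beyond 17 substrates are filled by enumerating
para/meta-substituted anilides over acyl chain lengths, which spans
amide-tail masses widely. Templates are never random molecular graphs,
so every structure parses and carries a known special-case class.
Formal charges arise from three independent sources (nitro groups,
a sulfonate, a protonated amine) so the charge count is not collinear
with any single functional-group count.

**Planted activity.** `P(active) = σ(β₀ + Σ βc·z(descriptor) +
Σ βe·z(factor value at planted column))` with descriptors standardized
across the panel (population SD; a zero-variance descriptor with a
nonzero coefficient is an error) and factor values standardized across
enzymes. Defaults: β₀ = −0.5, β(MW_bond) = −3.0 (small amide tails
favoured), β(formal charge) = +2.0 (electron-withdrawing, charged aryl
substituents favoured), β(MW) = 0, and one molecular-size (factor 3)
column effect of +2.5. These are deliberately strong, low-noise effects:
the generator's purpose is to test whether the pipeline recovers a known
rule, not to imitate the weaker effect sizes of real screens. Activity
is Bernoulli-sampled by default; `deterministic_activity=True`
thresholds at 0.5 for exact-recovery tests.

**Measurements.** HPLC peak areas carry multiplicative lognormal noise
(σ = 0.05); removal is drawn per replicate, N(85, 3)% for active pairs
and N(0, 5)% for inactive pairs and the dead-enzyme control. Plate OD
series follow `OD_ref·(1 − e^{−3t/t_eval})` for active pairs (≈95 %
conversion at the evaluation time) and a linear self-hydrolysis drift
reaching 2 % of the reference at the evaluation time for inactive pairs
and the control, with additive Gaussian noise (σ = 0.01 OD). Reference
replicates carry the complete-turnover OD. Every random stream derives
from `(seed, stage offset)`, so identical configurations reproduce
byte-identical outputs.

**What the generator does not emulate** — chromatography physics,
absorbance spectra, folding, expression failures, batch effects,
plate-position effects, or realistic correlation structure between
enzyme phylogeny and activity. Passing tests demonstrate that the
pipeline's statistics and bookkeeping are correct under controlled
conditions; they do not certify performance on real screens.

## Hit calling

Relative removal is `100·(A_t0 − A_t24)/A_t0`, unclamped (negative
removals mean area increase). Yield is `100·OD_sample/OD_reference`.
Both formulas follow the standard reading of control-referenced
screening statistics; blank subtraction is left to upstream processing.

Conventions fixed for reproducibility:

* Quantiles use linear interpolation (type 7).
* "Outside the 1.5 IQR" means Tukey fences applied to the control
  replicates only; the filtered controls then define the hit statistic
  `median + 1.5·IQR` (a separate multiplier from the fence one, both
  configurable).
* The HPLC conditions use strict inequalities ("higher than", "over
  50 %"), evaluated on the per-pair median.
* The plate condition is `mean_sample ≥ mean_ctrl + 2·SD_ctrl` with a
  strict `mean_sample > mean_ctrl` guard that only matters when the
  control SD is exactly zero — "at least 2 SD *higher*" requires a
  positive margin; without the guard a noise-free inactive pair would
  tie the control and be called a hit.
* Evaluation times must lie on the measured grid; the caller never
  interpolates OD series (interpolation would fabricate data).
* Control SD uses the sample convention (ddof = 1).

The activity matrix records per-cell provenance (route, statistic,
thresholds). The modelling inclusion rule — drop enzymes active on no
substrate, since their inactivity may reflect misfolding or wrong assay
conditions rather than specificity — is flag-controlled and records the
dropped identifiers.

## Library design

Percent identity follows the greedy-clustering convention: global
alignment (BLOSUM62, gap open 10, extend 0.5), identical aligned
residues over the shorter sequence length. Clustering visits sequences
longest-first (lexicographic ties) and joins the first cluster whose
representative matches at ≥ 60 %.

Hamming distances require equal lengths; members are projected onto the
representative's coordinates (pairwise alignment to the representative;
representative positions with no aligned residue become gaps; insertions
are ignored). Gap-vs-residue counts as a mismatch, gap-vs-gap as a
match.

Cluster thinning keeps ⌈n/2⌉ members (singletons always survive) chosen
to maximize the minimum pairwise Hamming distance. For clusters of ≤ 10
members the optimum is found by exhaustive subset enumeration (≤ 252
subsets), anchored on the representative when it survived the earlier
filters; larger clusters fall back to greedy farthest-point selection
seeded on the representative. Exact enumeration was chosen over pure
greedy because greedy max-min selection is not optimal in general and
small clusters are cheap to solve exactly; the greedy path only
approximates the optimum and is documented as such. All ties break
lexicographically, which together with internal canonical sorting makes
the selection invariant to input row order.

The "GSS" motif check is a literal substring on the unaligned sequence —
the simplest reading of the family motif requirement; a profile-based
motif model was considered out of scope. EC predictions and
literature-characterization flags are inputs, not computed.

## Featurization

The amino-acid encoding uses the first four published factor-analysis
scores per residue (polarity, secondary structure, molecular size, codon
diversity); the bundled 20 × 4 table is asserted injective. Gaps map to
the zero vector by default (configurable), a neutral choice in the
absence of a principled gap embedding. Feature names carry 1-based
original-alignment column numbers (`AA151_f3`) so importances can be
read against published alignment coordinates; the trim operation returns
the trimmed→original column map.

Chemical fragmentation cuts the amide C–N bond into acyl substituent R
(`MW_bond`), the `C(=O)NH` unit (43.03 Da) and the N-side part
(`MW_ring`), giving the conservation law `MW_bond + MW_ring + 43.03 =
MW` (±0.05 Da) for secondary anilides. When several amide bonds exist,
the one whose nitrogen bears an aryl substituent wins; remaining
ambiguity is resolved by the substrate's special-case annotation, the
same per-compound resolution a manual curation applies:
`acesulfame_rule` (both masses = MW/2), `primary_amide_rule` (MW_bond =
one hydrogen; the carbonyl-side fragment plays the ring role),
`ester_as_amide` (aryl esters cut at the ester bond as if amide),
`treat_as_anilide` (aromatic fragment assigned to MW_ring, ANILIDE
forced on). The functional-group vocabulary (amide, ester, nitro,
hydroxyl, primary amine, halogen, sulfonamide, aromatic rings) is a
fixed SMARTS list versioned in the code.

Zero-variance features are always removed; the optional near-zero-
variance screen removes a feature when its most-common/second-most-common
frequency ratio exceeds 95/5 **and** its unique-value percentage is
below 10 — the common screening convention.

## Modelling

Ten XGBoost classifiers are trained, each on its own stratified 80/20
resample (seeds 1–10, shared hyperparameters). Resampling is what varies
across models: it is the natural reading that makes "presence across
models" an informative stability notion. "Present" means nonzero gain
importance. The consensus keeps features present in ≥ ⌈0.7·10⌉ = 7
models; the final model trains on the consensus features over a separate
fixed stratified split (seed 0) so selection and evaluation do not share
a split, and reports importances divided by their maximum.

Default hyperparameters: max depth 4, learning rate 0.1, 200 rounds,
subsample 1.0, histogram trees, one thread, and **minimum split loss
reduction γ = 5.0**. The γ term is essential to the consensus design:
without it, boosted trees spend late splits on noise, nearly every
feature attains nonzero gain in most resamples (the resamples share ~80 %
of rows, so chance correlations persist across models), and the
consensus degenerates. With γ = 5 the planted determinants are recovered
in 100 % of seeded replicates while permuted labels leave a median
consensus of ≤ 1 feature. γ was set by this calibration on the
generator's default conditions, jointly with nothing else.

Grouped validation trains one model per held-out substrate (LOCO) or
enzyme (LOEO). Held-out groups are often single-class, so the metric
conventions are explicit: the recall of a class absent from the truth is
1 if no predictions of that class are made, else 0; F1 is 1 when truth
and predictions both contain no positives, 0 when positives are
predicted for an all-negative truth. If a training fold collapses to one
class, the fold predicts that class constantly (the only fit). Balanced
accuracy below 0.5 is attainable (anti-learning folds), as observed in
real screens. No hyperparameter search or calibration is attempted: the
goal is interpretable feature recovery, not generalization to unseen
chemistry.

## Analytics

The dendrogram uses Jaccard distance `1 − |A∩B|/|A∪B|` between enzyme
profiles after dropping substrates hit by no enzyme, with average
linkage (a common default for binary profiles; configurable). Two empty
profiles are at distance 0, an empty vs non-empty profile at 1. A
`min_substrates` flag optionally restricts clustering to enzymes above
an activity floor, since clade interpretation is often limited to
enzymes active on several substrates. Substrate correlations are plain
Pearson on columns with ≥ 1 hit; all-ones columns have undefined
correlation and are reported as missing, never coerced to 0. PCA centers
but does not scale (binary columns share a range); scores × loadingsᵀ +
column means reproduces the matrix at full rank to ~1e-12.

Promiscuity classes: ≥ 8 substrates promiscuous, ≤ 2 narrow, otherwise
intermediate; intermediate enzymes are excluded from logo contrasts
because the two named classes do not cover them. Logos are per-class
residue frequency vectors at requested original-alignment columns
(frequencies sum to 1 including gaps); plotting uses stacked
matplotlib bars.

## Orchestration

Runs are described by a strictly validated YAML config (unknown keys are
errors — silent typos corrupt analyses). One global seed drives the
whole run: the synthetic stage consumes it directly and derives
per-stage streams from fixed offsets; modelling uses the fixed resample
seeds 1–10 and final-split seed 0. The manifest lists every artifact
with a SHA-256 digest; a completed run directory is never overwritten
without `force`. The `force` flag is excluded from the echoed config so
reruns of the same scientific configuration produce identical
manifests.

## Problem sizes

The test suite and `scripts/acceptance.py` exercise the pipeline at the
screen's native scale — 16 × 17 modelling tables (272 pairs), a 40 × 17
screening grid (680 cells), 20 seeded replicates for consensus recovery,
11 permuted-label replicates, 1000 (tests) / 300 (script) randomized
measurement tables for oracle agreement, 500 random profiles for the
metric axioms and homolog sets of 48 sequences — sizes at which every
check runs exactly, not approximately, on a single CPU.

## Known limitations

* The identity convention approximates, not reproduces, CD-HIT's
  short-word heuristics; at 60 % thresholds the greedy order rule
  dominates either way.
* Atchley-factor encoding ignores column covariation; gaps as zero
  vectors shrink toward the factor mean.
* Amide-bond fragmentation assumes one hydrolyzable bond of interest;
  molecules with several competing amides need a special-case
  annotation, as in manual curation.
* The consensus γ calibration is tied to tables of a few hundred rows;
  much larger tables would support smaller γ.
* Synthetic LOCO/LOEO scores are not comparable to real-screen scores;
  only their structure (fold counts, metric bounds, single-class
  conventions) transfers.
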