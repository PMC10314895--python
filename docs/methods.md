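# Methods

## Differential abundance model

Protein intensities from DIA-MS quantification are treated as
log-normally distributed around a protein-specific mean. After a log2
transform (zeros floored at 1, a documented convention that avoids −∞
without imputation machinery) and per-sample median centering, each
treatment-vs-vehicle contrast is tested per protein with an unpaired
two-sample t-test. "Unpaired t-test" is ambiguous between the
pooled-variance (Student) and unequal-variance (Welch) forms; the
default is Student, with Welch behind a flag, because with n = 4 per
arm and a common measurement process the equal-variance assumption is
reasonable and the pooled form is what mainstream DIA software reports.
Degenerate zero-variance proteins are resolved deterministically
(equal means → p = 1; unequal means → p = 0 with a warning status), and
proteins with fewer than two observed values in a group are flagged
`untested`, never silently dropped.

Q-values are Benjamini–Hochberg step-up adjusted p-values, computed per
contrast (matching the per-volcano presentation of such analyses;
whether a global adjustment across contrasts would be preferable is a
design question with no stated answer, and per-contrast is the
conservative reading). Both the t statistic and the BH adjustment are
implemented directly in `diffstat`; `scipy.stats.ttest_ind` and
`statsmodels.multipletests` act only as independent cross-checks in the
test suite, keeping the dual-route verification intact.

## Hit-calling funnel

The deconvolution logic is a four-stage funnel with strict threshold
comparisons throughout (matching the printed "<" and ">"):

1. first tier: |log2FC| > log2 1.5 and Q < 0.05, two-sided (an
   up-regulated protein can be a legitimate hit);
2. exclusivity against the parent-compound and E3-ligand arms;
3. intersection across replicate experiments, requiring concordant
   direction (a protein degraded in one replicate and induced in the
   other is not a coherent target);
4. stringent tier on down-regulated shared hits only:
   log2FC < −1 and −log10 Q > 2.5.

Two design choices deserve explanation.

**Control screening is more permissive than treatment hit calling.**
`call_arm_hits` applied symmetrically (same thresholds for controls as
for the treatment) is available and is the default of that function,
but the end-to-end `deconvolution_funnel` screens control arms at
Q < 0.25 with no fold-change floor. The reason is the asymmetry of the
two error types: a confounder that narrowly misses Q < 0.05 in its
control arm while passing in the PROTAC arm would masquerade as an
exclusive hit. Monte-Carlo analysis of the simulated design (effects of
−2 log2 units, CV 0.2, n = 4/arm) shows symmetric screening leaks on
average ~1.4 shared-pharmacology/neosubstrate proteins into the
exclusive list, while the permissive screen leaks none across 200
simulation runs, at negligible cost in direct-target sensitivity. The
`control_q_max` parameter exposes the choice.

**The stringent tier is evaluated on a pooled DiffTable.** A single
4-vs-4 Student t-test (df = 6) essentially cannot reach
Q < 10^−2.5 after BH adjustment over ~4,000 proteins at realistic
effect sizes — the per-replicate power of that cut is below 5% even for
a 4-fold depletion. The stringent criteria are therefore applied to a
DiffTable computed on the shared-protein set with the samples of both
replicate experiments combined (n = 8 per arm, df = 14), which is also
the natural reading of a single combined volcano over the
shared-protein set with replicate-overlapping hits marked. Per-protein
baselines are a property of the protein and carry across experiments;
per-experiment batch offsets cancel in the group difference and only
mildly inflate the pooled within-group variance.

## Synthetic degradomics generator

`simgen.proteome` emulates the four-arm study design: vehicle, parent
inhibitor, free E3-ligase ligand, PROTAC; 4 replicates per arm; ~5,000
proteins; two replicate experiments with partially overlapping
detection. Defaults:

| parameter | default | rationale |
|---|---|---|
| `baseline_log2_mean`, `baseline_log2_sd` | 20, 2 | typical DIA log2 intensity scale and spread |
| `noise_cv` | 0.2 | linear CV of label-free protein quantification; σ_log2 = √ln(1+CV²)/ln 2 ≈ 0.286 |
| `batch_log2_sd` | 0.25 | per-protein, per-experiment offset; experiments run months apart do not share exact protein means |
| `n_direct_targets` | 6 | the size of a stringent hit list in this kind of study |
| `n_shared_pharmacology`, `n_neosubstrates` | 30, 10 | plausible footprints of warhead pharmacology and ligase-ligand neosubstrate degradation |
| effect sizes | −2 log2 (4-fold) in the responsive arms for every planted class | strong degradation for direct targets; confounders are given the same magnitude so the exclusivity filter is tested on detectable confounders — a confounder too weak to detect anywhere is not a test of the exclusion logic |
| `detect_prob` / pair overlap | per-experiment detection p = 2f/(1+f) for requested intersection/union fraction f | makes E[∩]/E[∪] equal the requested overlap exactly |

Planted (non-null) proteins are detected in both experiments by
default (`always_detect_planted`). Detection dropout is
missing-completely-at-random at the protein × experiment level; if
ground-truth targets were allowed to drop out of an experiment
entirely, recovery studies would measure detection luck rather than
the hit-calling method. Intensity-dependent dropout is a noted config
extension, not implemented.

What the generator does **not** emulate: peptide-level variation and
rollup, intensity-dependent missingness, correlated protein modules,
heavy-tailed contaminants, or normalization artifacts. Passing recovery
tests therefore demonstrates the correctness and calibration of the
inference and set logic under the stated noise model, not robustness to
every pathology of real DIA data.

## Microscopy simulation and quantification

Simulated fields place non-overlapping elliptical nuclei (DNA channel)
and curved-rod cilia: quadratic Bézier centerlines (smooth, analytically
parameterizable arc length) with Gaussian cross-section (σ = 1.6 px),
lengths 40–80 px, one γ-tubulin punctum at each base. The signal
channel deposits a per-cilium total along the centerline with a
piecewise-constant linear density such that the distal half carries
exactly the planted `tip_fraction`. Constant background (100) and
additive Gaussian noise (σ = 2) are applied last.

Quantification: local background subtraction by grayscale morphological
opening with a disk (rolling-ball equivalent; the radius must exceed
the largest object's half-width). Nuclei: Otsu threshold, hole filling,
connected components, minimum-area filter, optional distance-transform
watershed for touching nuclei (off by default). Cilia: Otsu threshold
floored at a robust noise estimate (median + 6 MAD — plain Otsu on a
field dominated by background fragments the noise into spurious
components), rod-shape filtering (length bounds, mean width =
area/length, elongation), skeletonization with the longest
endpoint-to-endpoint path (tree diameter by double BFS). Orientation:
the endpoint nearer the closest γ-tubulin punctum becomes the base;
puncta are local maxima above both a relative threshold and the robust
noise floor; cilia with no punctum within 10 px are flagged
`unoriented` and excluded from tip statistics.

Binning divides the skeleton into 10 equal arc-length segments and
assigns every mask pixel to the bin of its nearest skeleton point (ties
resolve deterministically toward the base because `argmin` takes the
first minimum along the base→tip ordering). The bins partition the
mask, so bin sums conserve the masked total exactly. The tip read-out
is the summed fluorescence of the final five bins, regardless of
length; `tip_fraction` = tip sum / total, defined as 0 for an empty
cilium. The equal-arc-length geometry of the bins is this package's
convention — "divided into 10 bins" does not itself prescribe the
pixel-to-bin map. Recovery on simulated fields is biased slightly
toward 0.5 (Gaussian blur across the half-way boundary mixes proximal
and distal signal); the mean absolute error is ~0.025, well within the
±0.05 round-trip tolerance. Coordinates are pixel-centered, row-major,
0-based.

## Dose-response models

The 4PL model is `bottom + (top − bottom)/(1 + (c/IC50)^hill)`, fitted
by nonlinear least squares in log10-concentration space with a fixed
multi-start grid (5 starting log-IC50 values across the tested range ×
both hill signs), making the fit deterministic. The parameterization is
canonicalized to top ≥ bottom (swapping top/bottom and negating the
hill leaves the curve unchanged). A fit whose span is within twice the
residual RMSE is flagged `unidentifiable` and reports no IC50. pIC50 is
−log10 of the molar IC50.

The bell model for Hook-effect curves is the product of an ascending
and a descending logistic around a baseline — the standard biphasic
parameterization; the falling EC50 is written as the rising EC50 times
10^gap with gap ≥ 0, which enforces rising < falling structurally. The
peak concentration is located numerically on a dense log grid and
refined locally. Monotone data (best fit peaking at the edge of the
tested range) is flagged `degenerate`; vanishing amplitude `flat`.

Model selection uses AICc with k = model parameters + 1 (residual
variance): k = 5 for 4PL, 7 for bell. The small-sample correction
requires n > k + 1 data points, so selection needs at least 9 points —
an 8-point single-replicate curve supports fitting but not selection,
and the error message says so.

## Problem sizes and numerical choices

The validation suite uses the study-scale design throughout: 5,000
proteins (5,343 where the realized replicate overlap is itself the
quantity of interest), 4 replicates per arm, CV 0.2, two replicate
experiments at detection overlap 0.725; 10,000 proteins for null
calibration; ~100–120 simulated cilia across 7–8 fields of 512² px; 20
seeded repeats for dose-response recovery and 40 for model selection.
Null calibration is judged within 3 binomial SDs of the nominal 0.05
and by a Kolmogorov–Smirnov uniformity test at p > 0.01. BH agreement
with the brute-force oracle is exact (identical floating-point
operations up to associativity; observed max deviation 0 across 1,000
random vectors). Monte-Carlo analysis of the full funnel puts the
probability of recovering ≥5 of 6 direct targets in the stringent list
at ~0.86 per seed under these conditions — the residual failures come
from per-replicate first-tier BH power at df = 6, which is a property
of the emulated design, not of the implementation.

## Known limitations

* No peptide-to-protein rollup, no mzML/raw parsing, no batch
  correction beyond median centering, no moderated (empirical-Bayes)
  variance shrinkage — with n = 4 per arm, a limma-style moderated test
  would raise power; the plain t-test is kept to match the emulated
  analysis.
* Image analysis is 2D only: no z-stacks, deconvolution, flatfield
  correction, or time-lapse tracking. Cilia crossing each other or a
  nucleus boundary in real images would need masking logic this package
  does not implement (the simulator places cilia without overlap).
* Dose-response fitting assumes homoscedastic Gaussian noise; no
  amplification-efficiency correction is applied to ΔΔCt.
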