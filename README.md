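# degradomap

Target deconvolution for phenotypic-screen hits via PROTAC degradomics.

When a small molecule from a phenotypic screen has no known cellular
target, one powerful strategy is to convert it into a
proteolysis-targeting chimera (PROTAC) — the hit compound linked to an
E3-ligase ligand — and ask, proteome-wide, which proteins are degraded.
A true direct target is depleted under PROTAC treatment but **not**
under the parent compound (which only binds, shares the warhead
pharmacology) and **not** under the free E3-ligase ligand (which only
recruits the ligase and can degrade its own neosubstrates).
`degradomap` implements that comparative analysis end to end, together
with the downstream cell-biology read-outs used to validate a Hedgehog
pathway target: nuclear and ciliary fluorescence quantification and
dose-response fitting, including bell-shaped Hook-effect curves.

The package is aimed at chemical-biology and proteomics groups running
multi-arm DIA-MS degrader experiments, and at anyone who wants a tested,
simulation-backed reference implementation of the hit-calling logic.

## The analysis

For each replicate experiment with arms *vehicle*, *parent*,
*e3ligand*, *protac* (4 samples per arm):

1. **Differential abundance** (`diffstat`): per protein, an unpaired
   two-sample t-test (pooled-variance Student by default, Welch by
   flag) on median-centered log2 intensities,
   log2FC = mean(treatment) − mean(vehicle); Benjamini–Hochberg
   step-up Q-values per contrast. Both are implemented from first
   principles and verified against independent oracles.
2. **First-tier hits** (`deconv.call_arm_hits`): |fold change| > 1.5
   and Q < 0.05, i.e. |log2FC| > log2 1.5 ≈ 0.585 (strict
   inequalities).
3. **Exclusivity** (`deconv.exclusive_hits`): drop any protein showing
   evidence of change in a control arm. The end-to-end funnel screens
   controls at a deliberately permissive Q < 0.25 with no fold-change
   floor — for exclusion, sensitivity matters more than a calibrated
   error rate.
4. **Replicate intersection** (`deconv.intersect_replicates`): hits
   must reproduce across both experiments with concordant direction.
5. **Stringent tier** (`deconv.stringent_filter`): down-regulated
   shared hits with log2FC < −1 and −log10 Q > 2.5 (equivalently
   Q < 10^−2.5 ≈ 3.16 × 10^−3), evaluated on a pooled DiffTable over
   the shared-protein set using the samples of both experiments.

`simgen` generates all three data modalities with known ground truth:
degradomics matrices with planted direct-target / shared-pharmacology /
neosubstrate / null classes (log-normal noise of configurable CV,
detection-level missingness, partial replicate overlap), microscopy
fields with curved-rod cilia and planted tip fractions, and
dose-response tables. `hcquant` quantifies nuclei (Otsu masks on the
DNA stain) and cilia: ARL13B segmentation, skeletonization,
base-to-tip orientation by the nearest γ-tubulin punctum, 10 equal
arc-length bins, and the tip read-out = summed fluorescence in the
final five bins regardless of length. `assayfit` normalizes reporter
data to stimulated/unstimulated vehicle controls, fits 4-parameter
logistic and biphasic bell (product-of-two-logistics) models with
AICc-based selection, and computes ΔΔCt fold changes and ChIP
bound/input enrichment normalized to intergenic controls.

## Worked example

```python
from degradomap import simgen, deconv

cfg = simgen.SimProteomeConfig(seed=0)   # 5000 proteins, 4 arms, 4 reps/arm
exp_a, exp_b, truth = simgen.simulate_replicate_pair(cfg, overlap_fraction=0.725)
res = deconv.deconvolution_funnel([exp_a, exp_b])

print("shared hits:", len(res["shared"]))
print("stringent hits:", len(res["stringent"]))
hits = res["stringent"].table
hits["class"] = truth.loc[hits.index, "class"]
print(hits[["log2fc", "q", "class"]])
```

prints

```
shared hits: 6
stringent hits: 6
            log2fc        q          class
protein_id
P00001       -2.12  9.1e-09  direct_target
P00002       -2.15  3.3e-07  direct_target
P00003       -1.79  3.3e-07  direct_target
P00004       -2.06  1.6e-06  direct_target
P00005       -2.40  7.6e-09  direct_target
P00006       -1.92  1.1e-06  direct_target
```

All six planted direct targets (log2 effect −2, CV 0.2) survive the
funnel; none of the 30 shared-pharmacology or 10 neosubstrate
confounders do — they are hits in the protac arm but are screened out
by the parent / e3ligand control arms.

## Command line

A thin CLI wraps the library:

```
degradomap simulate-proteome --config cfg.yaml --overlap 0.725 --out sim/
degradomap diff --quant sim/quant_expA.tsv --design sim/design_expA.tsv \
    --treatment protac --reference vehicle --out protac_A.tsv
degradomap hits --diff protac_A.tsv --controls parent_A.tsv,e3_A.tsv --out hits.tsv
degradomap simulate-images --n-fields 2 --out fields/
degradomap quantify-images --images fields/ --out measurements/
degradomap fit-dose --data dose.csv --model auto
```

File formats: quant TSV (`protein_id` + one column per sample, `NA` or
empty = missing), design TSV (`sample_id  arm  experiment_id`),
multi-page TIFF with a YAML sidecar mapping pages to channel roles,
dose CSV (`concentration_M,response,replicate`).

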