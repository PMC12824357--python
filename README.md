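# hiergrad

Tools for asking how a dopaminergic drug reorganizes the brain's
macroscale functional hierarchy, at desk scale and with every stage
verifiable against planted ground truth.

Psychostimulants such as methylphenidate raise extracellular dopamine
and norepinephrine. One way to quantify their effect on cortical
organization is the **principal functional-connectivity gradient**: the
dominant axis of variation in resting-state functional connectivity,
ordering regions from unimodal (sensorimotor, visual) to transmodal
(default-mode, frontoparietal) cortex. A narrowing of this axis's range
— *gradient compression* — means reduced segregation between the
sensory and associative poles. This package implements the full
computational chain needed to measure that, relate it to striatal
dopamine receptor availability, and validate every step on synthetic
cohorts with known ground truth:

1. **Gradients** (`hiergrad.gradients`). Per scan: Pearson connectome →
   retain the top 10% of positive edges per row → cosine similarity of
   the sparsified connectivity profiles → diffusion-map embedding
   (anisotropy α = 0.5): the affinity *W* is normalized to
   *W′ = D⁻ᵅ W D⁻ᵅ*, row-normalized to a Markov matrix *P*, and the
   non-trivial eigenvectors ψₖ of *P* (scaled by λₖ/(1−λₖ) by default)
   are the gradients. Per-scan components are matched to group
   templates by greedy maximum |Pearson r| with sign correction.
2. **Group statistics** (`hiergrad.group_stats`, `hiergrad.lmm`).
   Per-parcel drug contrast `gradient ~ condition + covariates +
   (1 | subject)` by profiled-REML, Benjamini–Hochberg FDR, paired
   Cohen's d, a covariate-adjusted two-group (ANCOVA-style) contrast for
   large cohorts, and the compression summary (condition ranges, MP/PL
   range ratio, cross-condition *R*, per-network shifts).
3. **Spatial nulls** (`hiergrad.spatial_null`). Spin tests: random
   rotations of the spherical parcel centroids (right hemisphere
   mirrored), nearest-centroid reassignment, permutation p-values that
   preserve spatial autocorrelation.
4. **PLS prediction** (`hiergrad.pls_predict`). Partial least squares
   from parcel-wise gradient maps to scalar dopaminergic measures, with
   leakage-free leave-one-out cross-validation and cross-condition
   (PL↔MP) transfer.
5. **PET kinetics** (`hiergrad.pet_kinetics`). Simplified reference
   tissue model (SRTM; basis-function fit for R1, k2, BPnd), Logan
   reference-region graphical analysis (slope = DVR = BPnd + 1), and
   the dopamine-increase score ΔDA = BPnd(PL) − BPnd(MP).
6. **Synthetic data** (`hiergrad.synthetic`). Spherical atlases,
   paired-condition connectome cohorts with a planted one-dimensional
   hierarchy whose spread differs between conditions, hierarchy-coupled
   scalar targets, smooth spherical maps for spin-test calibration, and
   SRTM-generated time–activity curves with known BPnd.

`hiergrad.pipeline.run_study` orchestrates 1–4 end to end from files on
disk, deterministically for a fixed config and seed, stamping every
output table with the config hash.

## Worked example

The numbered scripts under `analysis/` reproduce a complete synthetic
study (38 subjects × 3 scans × 2 conditions, 100 parcels, planted
MP/PL hierarchy-spread ratio 0.60):

```bash
python analysis/01_simulate_cohort.py   # writes results/study_inputs/
python analysis/02_run_study.py         # writes results/study_outputs/
python analysis/03_pet_kinetics.py      # writes results/pet_kinetics.tsv
```

`02_run_study.py` prints:

```
principal-gradient range PL  [-15.617, 15.712]
principal-gradient range MP  [-10.087, 9.991]
range ratio MP/PL            0.641 (planted 0.60)
cross-condition correlation  R = 0.993
parcels with FDR-significant drug effect: 99 / 100
spin test t-map vs reference map: r = 0.227, p = 0.1660 (10000 rotations)
PLS within PL: LOO R = 0.635 (k_opt = 1), training R^2 = 0.491
PLS within MP: LOO R = 0.662 (k_opt = 1), training R^2 = 0.524
PLS transfer PL->MP: r = 0.681, p = 0.0000
PLS transfer MP->PL: r = 0.698, p = 0.0000
```

Reading this: the cohort-mean principal gradient's range under the drug
condition is 0.64× the placebo range — the pipeline recovers the
planted compression (0.60) — while regional ordering is preserved
(R = 0.993). Nearly all parcels show an FDR-significant condition
effect (the planted compression moves every parcel off its placebo
value). The contrast t-map correlates r = 0.227 with a
transporter-density-like map that was built with a mild planted
coupling; at 100 parcels the rotation null is wide, so the spin test
does not call this significant. A 2-component PLS on the subject-level
principal gradients predicts the hierarchy-coupled D1R availability
out-of-sample within each condition and transfers across conditions in
both train/test directions.

`03_pet_kinetics.py` prints:

```
fitted 38 subjects x 2 conditions (3% frame noise, t* = 20 min)
BPnd(PL) recovery: median |error| 1.0%
DVR - BPnd: mean 0.990 (sd 0.015; reference-tissue identity: 1.0)
dopamine increase: mean 0.402 BPnd units = 15.7% (planted 10-20% reductions)
```

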