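# Methods

## Scope and model of the data

`ecmorph` implements an end-to-end analysis of endothelial-cell (EC)
morphological responses to patient plasma: synthetic data generation,
seeded segmentation, single-cell feature extraction, a factor-analysis /
linear-discriminant profiling spine, extracellular-flux respiration
metrics, and clinical cohort statistics. The study design it emulates:
HUVEC monolayers exposed to 25% plasma from healthy controls (HC),
compensated cirrhosis (CC) or decompensated cirrhosis with hypoalbuminemia
(DC), 20 plasma samples per group, three replicate wells per condition,
with albumin arms — DC plasma supplemented to physiological albumin, HC
plasma to supraphysiological — and five stains (HOECHST nuclei,
VE-cadherin junctions, phalloidin F-actin, MitoTracker mitochondria, vWF).

## Synthetic data

Two generators share one phenotype parameterisation
(`PhenotypeParams`: mitochondrial fragmentation and perinuclear bias,
junction irregularity, actin stress, Weibel-Palade-body count, cell
density, SNR). The default condition phenotypes encode the study's
qualitative biology: severity-ordered parameters (HC < CC < DC),
physiological albumin returning only the mitochondrial parameters of DC to
HC levels, and supraphysiological albumin a strict no-op for HC.

**Field renderer.** 2D, already-projected 16-bit fields (the analysis
operates on max-projections, so z-stacks are never needed). A jittered
grid of nucleus seeds is Voronoi-tessellated into a confluent monolayer —
cells tile the field exactly, giving pixel-exact ground-truth masks.
Nuclei are ellipses (equivalent radius ≈ 6.3 µm, capped at 0.40× the
nearest-seed distance so nuclei never touch); VE-cadherin is drawn on cell
boundaries with gaps and intensity modulation scaled by junction
irregularity; F-actin has a cortical rim plus Poisson-distributed oriented
stress fibres; mitochondria are a connected perinuclear ring with
persistent-random-walk tubules whose length shrinks with fragmentation,
eroded by fragmentation-proportional breaks and replaced by puncta
sampled into the perinuclear annulus with probability `mito_perinuclear`;
vWF bodies are short rods. Noise is Poisson shot noise plus Gaussian read
noise with SD = amplitude / SNR (default SNR 12; `inf` = noiseless).
Default geometry 512 px² at 0.33 µm/px (typical 20×/0.75 NA sampling) and
45 cells/field. The renderer is a phenomenological phantom: no PSF,
no chromatic registration error, no illumination falloff, no debris or
multinucleated cells. Segmentation and feature tests passing on it
demonstrate correctness of the algorithms, not robustness to every
artifact of real microscopy.

**Latent-factor feature tables.** The fast generator used for
cohort-scale statistics: cell features = Λ·f + ε with simple-structure
loadings (each feature loads on one factor, communality ≈ 0.82 jittered
±0.04, unique variance the complement). Factor scores are condition mean +
per-sample effect (SD 0.35, drawn once per plasma sample and shared across
albumin arms — the same plasma is split across arms) + per-well effect
(SD 0.15) + unit cell noise; per-plate feature offsets (SD 0.25) simulate
batch effects. The leading factors are tagged mitochondria, vWF, junction,
actin, nucleus; condition factor means interpolate the phenotype
parameters linearly between HC and DC values, reaching
(4.0, 1.0, 1.6, 1.6) score units at DC. The 4.0 mitochondrial effect
against 1.6 for the unrestored junction/actin axes encodes the study's
central qualitative finding — the disease contrast, and its albumin
reversal, are dominated by mitochondria — and is what makes the DC+albumin
condition score nearer HC than DC on the discriminant axis. Effect sizes
are free parameters of the emulation (no published quantitative effect
sizes exist to calibrate against); they are fixed once here.

**Study layout.** The full design (100 conditions × 3 replicates) spans
four 96-well plates. Plates are balanced: all albumin arms of one sample
stay on one plate, and samples are dealt round-robin across plates within
group strata. This matters because per-plate z-scoring removes plate
means; with unbalanced plates, plate composition aliases into condition
effects and produces spurious arm shifts of ~0.3 SD in the null HC
contrast. Balanced plate layouts are standard practice for exactly this
reason.

## Segmentation

Nuclei: Gaussian smoothing (1 µm), Otsu threshold (a fixed threshold is
available for reproducibility studies), hole filling, optional
distance-transform watershed splitting of touching nuclei (peaks at least
one minimum-nucleus-radius apart on the smoothed EDT), then an area band
filter of 40–400 µm² (HUVEC nuclei sit near 120–150 µm²; the band is
configurable and logged). Cells: marker-controlled watershed on the
smoothed VE-cadherin landscape seeded at nuclei, restricted to a
foreground mask — the union of per-channel *triangle*-threshold
foregrounds, closed and hole-filled. Triangle rather than Otsu because a
confluent monolayer has little true background and Otsu carves away dim
cell interiors. Border-touching cells are retained but flagged in QC.
Labels are inherited from seeds, so nuclei and cells are in bijection.

## Features

A fixed inventory of ~125 features, each tagged with a cellular
compartment (nucleus, cell, mitochondria, vwf, actin, junction):

* shape (area, perimeter, equivalent radius, eccentricity, axes,
  solidity) for nucleus and cell, in µm via the pixel size;
* intensity (mean, SD, MAD, q05/q50/q95, integrated) per channel in the
  cell, plus the nuclear stain within the nucleus;
* Haralick texture (contrast, correlation, entropy, angular second
  moment) at 1- and 2-px offsets averaged over four directions, on
  intensities quantised to 32 levels within the compartment; pixel pairs
  leaving the compartment are excluded; the correlation of a constant
  region is reported as 0;
* radial distribution for mitochondria, vWF and actin: four equal-width
  rings of normalised radial position d_nuc/(d_nuc + d_border) between
  nucleus and cell boundary, as fractions of total cell intensity, plus
  the perinuclear fraction over the annulus [nucleus boundary, 1.5×
  nucleus equivalent radius] — the same constant the renderer uses;
* colocalisation (Pearson within the cell; Manders M1/M2 with per-cell
  Otsu thresholds per channel) for mito–vWF, junction–actin, mito–actin;
* mitochondrial morphology from a per-cell Otsu mask (components ≥ 3 px):
  object count, mean/total area, fragmentation index = count / total area
  (µm⁻²), mean object eccentricity, perinuclear fraction; an empty mask
  emits zeros plus a `mito_empty` flag.

NaN policy: any cell with an undefined feature is dropped and counted in
extraction QC — downstream z-scoring and factor analysis need complete
rectangular data.

## Profiling spine

Single cells are z-scored per plate (features constant on any plate are
dropped globally), plates concatenated. Maximum-likelihood factor analysis
is fitted at increasing factor counts; the kept model is the smallest k
whose common factors explain ≥ 80% of *total* sample variance, measured
as Σ squared loadings / Σ feature variance. ("Explained common variance"
read as a fraction of the common variance alone would be self-defeating:
for an 11-factor model with equal shares, 9 factors already carry > 80% of
the common variance, so the criterion could never return the true count.
The implemented reading recovers it.) Rotation is off by default —
attribution reads raw regression coefficients — with varimax available.
If the target is unreachable (near-isotropic data) the n_max model is
returned flagged, not an error.

Per-cell regression (Thomson) factor scores are averaged per well; wells
under `min_cells` (default 50) are excluded and logged; well profiles are
rescaled to zero mean / unit variance per factor. LDA (eigen solver,
Ledoit-Wolf shrinkage by default — ~60 training wells against 11 factors)
is fitted on wells passing `albumin_arm == 'none'` and used to *score*
all wells; LD1 is signed so that mean(HC) < mean(DC). Condition
comparisons use Welch's t-test on LD1. Per-factor albumin effects use the
paired Wilcoxon signed-rank test — pairs are plasma samples across arms,
after averaging replicate wells per sample; exact null for ≤ 25 non-zero
pairs without ties, normal approximation with continuity correction
otherwise; an all-zero difference vector is degenerate with p = 1 by
convention — with Benjamini-Hochberg q-values across factors.

The albumin-arm shift statistic (`arm_shift`) is the mean over samples of
the paired per-sample difference, in units of the pooled within-condition
SD. Arms are paired within sample *and* plate by the layout, so the paired
mean is the design's minimum-variance estimate; a median-of-wells
estimator ignores the pairing and its sampling noise alone is of the
order of the 0.2-SD null bound at this cohort size.

Factor attribution sums |loadings| per compartment tag, normalised per
factor; exact ties are broken alphabetically and flagged. The PCA path
mirrors the LDA path (fit on albumin-free wells, project the rest) with a
centroid-distance permutation test (default 1000 permutations, seeded).

## Respiration and superoxide

Mito-stress metrics follow the standard definitions anchored at the last
glucose-phase measurement (injection order glucose → oligomycin → FCCP →
rotenone/antimycin A; a pre-glucose baseline phase is carried but unused):
non-mito = mean(rot/AA); basal = last(glucose) − non-mito; ATP-linked =
last(glucose) − min(oligomycin); maximal = max(FCCP) − non-mito; spare =
maximal − basal (an identity, asserted on every output). Metrics are also
emitted per 1000 cells ("normalised to cell number" needs a unit; 1000
cells is the convention here). Negative derived metrics are emitted with a
warning flag, not clipped. ECAR columns are carried but no glycolysis
metrics are defined. MitoSOX superoxide signal is normalised as the ratio
to MitoTracker Red (membrane potential); records with non-positive
denominator are excluded and counted. Group comparisons use Mann-Whitney U
with BH correction — consistent with the non-parametric stance of the
cohort statistics, since the per-panel test is otherwise unspecified.

## Clinical statistics

Two-sided Fisher exact p-values use the probability-mass definition (sum
of hypergeometric probabilities of all tables with the observed margins no
more probable than observed, with a 1e-7 relative slack at the boundary) —
the convention that reproduces the published cohort table to three
decimals. The selection rule is chi-square unless any expected count is
strictly below five; for 2×2 tables the Fisher p is reported regardless
(the published table is consistent with Fisher even where expectations
exceed five, e.g. the oral-anticoagulant row). Two printed rows
(cardiovascular disease 0.041; overt hepatic encephalopathy 0.003) match
no standard test computable from their printed counts — Fisher gives 0.751
and < 0.001 respectively — and are treated as typographical or procedural
inconsistencies: they are excluded from verification and nothing is tuned
to them. Mann-Whitney U is exact (enumeration) for combined n ≤ 20 without
ties. IQRs use linear-interpolation (type-7) quantiles. P-values display
as three decimals with "< 0.001" below.

## Problem sizes and numerical choices

The acceptance script and tests use: the full default cohort (300 wells,
60 cells/well, 110 features) for end-to-end behaviour; 20 seeds × 1500
cells × 110 features for factor-count recovery; 10-level fragmentation
sweeps at 25–30 cells/field for monotonicity; two 512-px fields for
segmentation recovery; 50 Monte-Carlo traces for OCR recovery. Well counts
per cell (60) are a deliberate scale-down of a confluent well (6 fields ×
~100 cells); all conclusions asserted are stable across seeds at these
sizes. EM factor analysis uses up to 1000 iterations; non-convergence
warns. Degenerate inputs (blank fields, empty masks, all-zero differences,
zero-variance features) return defined values or flagged records rather
than raising, except where the input violates the data model (missing
channels/phases, shape mismatches, unpaired samples), which raise with
named offenders.

## Known limitations

Ground-truth "polygons" are label images (exact for the Voronoi phantom).
The renderer's phenotype axes are independent by construction; real
disease plasma likely induces correlated remodelling. Factor attribution
on unrotated ML loadings concentrates the dominant compartment in the
leading factor but spreads weaker ones; varimax sharpens attribution at
the cost of the regression-coefficient reading. The 2×k Fisher extension
is not implemented (k-level tables with small expectations fall back to
chi-square with a warning). ECAR/glycolysis metrics, ACLF/MELD score
computation, batch correction beyond per-plate z-scoring, and
deep-learning segmentation are out of scope.
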