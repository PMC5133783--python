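# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want to know.  No number quoted
here is asserted anywhere the code does not compute it.

## Imaging model and foci detection

Stacks follow the (z, y, x) convention, 0-based, half-open bounding boxes.
The default voxel geometry is 47 × 47 × 200 nm (confocal resonant scanning
with 0.2 µm z-steps, 42 planes); a voxel is 4.418 × 10⁻⁴ µm³, so the
50-voxel γH2AX minimum equals 0.022 µm³.  Size thresholds are inclusive
(≥ 50 γH2AX, ≥ 10 SMC6 voxels) and "pixels" are interpreted as 3D voxels,
because only that reading reproduces the 0.022 µm³ figure on this grid.

Nucleus segmentation: global Otsu on the DNA channel, 3 × 3 × 3 closing
(erosion run with border_value=1 so components meeting the image border are
not etched back from it), hole filling, 26-connected labeling, removal of
components below a voxel minimum or touching the XY border.  Border
exclusion avoids truncated-cell bias; the z border is not checked because
fields are acquired to contain the nuclei axially.

Focus isolation is nucleus-local.  The intensity threshold default is
`mean + 3·SD` of the intranuclear voxels.  A nucleus-local Otsu is
available, but it is *not* the default: on low-noise images the background
class has near-zero variance, Otsu then sits just above the background
level, blob footprints inflate to ~3σ and nearby foci merge.  The
mean + k·SD rule keeps footprints near the blob half-width, is robust to
inter-cell intensity variation, and recovers generator ground truth
exactly on noiseless phantoms.  Connectivity is 26 (blob-like objects);
the labeling is tested against a brute-force flood-fill oracle.

Colocalization is object-based: a γH2AX focus is SMC6-positive when its
voxel set shares ≥ 1 voxel with an SMC6 focus of the same nucleus, counted
at most once per γH2AX focus.  Cells need ≥ 2 SMC6 foci to enter
summaries — an automated stand-in for manual pre-selection.  The
SMC6-positive fraction is averaged per cell (matching mean ± SEM per-cell
reporting); a pooled-over-foci mode is exposed.

### Richardson–Lucy deconvolution

The restoration step is classic Richardson–Lucy with a truncated (±3σ)
anisotropic Gaussian PSF (defaults σ_xy = 0.1 µm, σ_z = 0.3 µm —
placeholders of the right order for a 1.4-NA oil objective, flagged in the
config), reflective (edge-repeating) boundaries, a hard cap of 40
iterations, and an optional early stop when the relative L1 update falls
below 1/SNR² (SNR 12 green, 10 red).  RL preserves non-negativity and
approximately conserves flux for interior-supported signal; on noiseless
input the Kullback–Leibler divergence between the data and the blurred
estimate is non-increasing (tested).  Deconvolution is off by default in
the pipeline: detection thresholds are nucleus-local, so restoration
changes counts by ≤ 10% on default phantoms (checked in the demo).

## Synthetic phantoms

Nuclei are axis-aligned ellipsoids (default radii 1.4 × 2.4 × 2.4 µm,
z-flattened like adherent cells) placed on a jittered tile grid so they
never touch each other or the XY border.  Foci are Gaussian blobs,
isotropic in µm (σ = 0.2 µm) and therefore anisotropic in voxels, which
exercises the voxel-geometry handling.  Focus centers are drawn inside a
0.75-shrunk copy of the nucleus with a minimum pairwise separation of
0.9 µm (relaxed geometrically to a floor of 0.55 µm if placement stalls),
so that rendered blobs remain separable at the detection threshold.  Each
γH2AX focus carries a co-centered SMC6 focus with probability
`coloc_prob` (default 0.5); SMC6-only foci can be added.

Intensities: DNA 10/100 (outside/inside), focus-channel background 5/20,
blob amplitude = SNR·√(background + read-noise²) with SNR (10, 12) for
(γH2AX, SMC6).  Noise is Poisson shot noise plus additive Gaussian read
noise (SD 2).  The generator does *not* emulate optical sectioning
physics, PSF blur of the rendered structures, nucleoli or chromatin
texture, touching nuclei, or camera-specific noise calibration — so
passing recovery tests demonstrates correct geometry, thresholding,
labeling and bookkeeping, not detector performance on real micrographs.

Counts may be fixed or Poisson-distributed.  A single master seed drives
spawned child seeds per stage, so any stage regenerates independently and
bit-identically.

## Clonogenic survival

Colonies ~ Binomial(n_plated, PE·exp(−αD − βD²)) in the generator.  The
analysis computes PE per experiment from the dose-0 plates, averages the
two plating densities within an experiment with equal weight (the density
design guards against colony-merging artifacts; equal weighting is the
simplest unbiased combination), and aggregates experiments as mean ± SEM.
The mean colony fraction is divided by PE once, which equals the mean of
per-density survival ratios and makes S(0) = 1 exact in floating point.
The genotype comparison is a per-dose one-tailed paired t-test (pairing by
experiment); the direction is a configuration flag.  The LQ fit is an
extension, off by default, with non-negativity bounds.

## Cell-cycle analysis

DNA-content samples are per-event fluorescence values.  The 2N peak is the
mode of a smoothed 256-bin histogram; when both 2N and 4N peaks are
present the pair with position ratio ≈ 2 disambiguates them.  The peak CV
comes from the FWHM with the histogram smoothing deconvolved, clipped to
[0.01, 0.12].  Gates: G0/1 = 2N·(1 ± 2.5·CV), G2/M = 4N·(1 ± 2.5·CV),
S between; the gates must not intersect (asserted).  Because an S phase
uniform in DNA content leaks into both gates (≈ 20–40% of its ends at
CV = 0.04), the S density is estimated from the unambiguous inter-gate
region and its expected spill-in is subtracted from the G0/1 and G2/M
counts; without this correction the gated fractions are biased by up to
≈ 0.04.  Fractions may sum to < 1 (debris excluded).

Colcemid traps cycling cells in M phase.  The time course of the G0/1
fraction is fitted with f(t) = r + (f₀ − r)·exp(−t/τ); the plateau r is
the non-cycling fraction.  This decay-to-plateau form is the package's own
formalization of "a resistant subpopulation remains".  Gating of the
series is anchored on the t = 0 sample (its 2N position and CV), because
late samples can lose the 2N peak entirely and mode-finding alone would
lock onto 4N.  A flat series (range < 0.02) returns τ = ∞ with the mean as
plateau.  At the standard sampling (0, 24, 48, 72, 96 h, τ ≈ 12 h) plateau
recovery bias is below 0.03 (tested over 200 simulated series).

Division intervals are lognormal in the generator (default WT mean 17 h —
a typical U2OS doubling time — CV 0.15, 50 lineages × 6 generations).
The fold change is the ratio of sample means; the test between lines is a
two-tailed unpaired Student t on the pooled intervals (the convention used
for the imaging comparisons).  Generation alignment shifts each lineage so
that a shared anchor event (e.g. a medium refresh, by default generation
3) coincides; gaps are preserved, never imputed.

## CRISPR verification arithmetic

Protospacers are exact 20-nt matches followed by NGG (or NAG when
enabled), searched on both strands with reverse-strand hits reported in
forward-frame coordinates.  The blunt cut sits between protospacer
positions 17 and 18 (3 bp 5′ of the PAM) — canonical for SpCas9 and the
placement that reproduces a 304 + 113 bp fragment split of a 417 bp
amplicon.  In-silico PCR is exact-match only (this is a verification tool,
not a primer-design tool); the reverse primer may be supplied in either
orientation, and 0 or > 1 products raise descriptive errors.  The Surveyor
indel estimate uses f_cut = (b + c)/(a + b + c) and
indel% = 100·(1 − √(1 − f_cut)); the square root accounts for cleaved
heteroduplexes forming between one edited and one unedited strand.  The
estimate is monotone in f_cut and inverts exactly (tested to 10⁻¹²).

The bundled template builder produces a *synthetic* stand-in for the
targeted genomic region: random sequence with the real primer pair and
both overlapping exon-3 protospacers embedded so the amplicon is 417 bp
and the first guide cuts 304 bp from the forward primer.  The true locus
sequence is not distributed with the package.

## Statistics

`two_sample_t` computes the classic pooled-variance Student t (Welch by
flag), paired or unpaired, one- or two-tailed with an explicit direction.
Zero-variance inputs are handled deterministically (identical samples give
t = 0, two-sided p = 1).  Type-I error is calibrated by simulation in the
test suite (2000 null replicates per variant).  The multi-time-point foci
comparisons are reported per time point without correction, mirroring
common practice, but a Holm-adjusted column is emitted alongside.  Both
cell-level tests (cells pooled across replicates) and experiment-level
tests (n = replicate experiments) are reported, since nesting cells inside
experiments is a genuine analysis choice.

## Problem sizes and determinism

Default stacks are 42 × 336 × 448 voxels with 10 nuclei (tests and the
demo use 4–10 nuclei per stack and 1–3 replicate experiments); the
acceptance script uses 100 nuclei for the colocalization recovery, 3
replicate experiments × 6 doses × 2 densities for survival, 5 × 5000-event
histograms per colcemid series, and 600 division intervals.  These sizes
were chosen so every claim is testable in minutes on a single CPU while
keeping Monte-Carlo error well inside the stated tolerances.  All
randomness flows through `numpy.random.SeedSequence` spawning, so every
result in this package is reproducible bit for bit from one seed.

## Known limitations

- No watershed separation of touching nuclei (the phantoms never touch;
  real clumped cultures would need it).
- Focus crowding: above ~20 foci per nucleus, blobs closer than the
  detection footprint merge and counts saturate — visible in phantoms with
  high focus densities, and a real phenomenon in saturated damage
  conditions.
- The DNA-histogram gater is peak-anchored gating with S-spill correction,
  not a full Dean–Jett–Fox mixture fit; strongly aneuploid or multi-clone
  histograms are out of scope.
- FCS binary files are not parsed (CSV event exports only); vendor image
  formats (LIF/CZI) are not read (TIFF only).
- Off-target work is limited to re-locating given sequences; no scoring or
  genome-wide search.
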