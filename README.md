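# fociquant3d

Quantitative analysis of DNA double-strand-break (DSB) repair experiments in
human cells, built around the SMC5/6-complex biology of U2OS cells: 3D
γH2AX/SMC6 focus detection and object-based colocalization in confocal
z-stacks, clonogenic survival curves, DNA-content cell-cycle gating with
colcemid depletion kinetics, division-interval statistics, and the sequence
arithmetic used to verify CRISPR-Cas9 edits.  Every stage is paired with a
seeded synthetic-data generator that produces inputs with known ground
truth, so the whole pipeline is testable end to end without raw microscopy
or FACS data.

Intended users: cell biologists and image analysts who want a reproducible,
scriptable replacement for ad-hoc foci-counting and survival spreadsheets,
and methods developers who need phantoms with ground truth to benchmark
focus detectors.

## What it computes

**3D foci and colocalization.**  Nuclei are segmented from the DNA
counterstain (Otsu threshold, 3D closing, hole filling, 26-connected
labeling; nuclei touching the XY border are discarded).  Within each
nucleus, foci are 26-connected components above an intranuclear intensity
threshold, kept if they reach a minimum size: 50 voxels for γH2AX — on the
47 × 47 × 200 nm acquisition grid this is 0.022 µm³ — and 10 voxels for
SMC6.  A γH2AX focus is *SMC6-positive* when its voxel set shares at least
one voxel with an SMC6 focus of the same nucleus.  Cells with fewer than two
SMC6 foci are excluded.  Per condition the package reports mean ± SEM foci
per cell and the mean per-cell SMC6-positive fraction, with two-tailed
unpaired Student t-tests between genotypes.

**Deconvolution.**  Optional Richardson–Lucy restoration (reflective
boundaries, default cap of 40 iterations, optional SNR-based early stop)
with an anisotropic Gaussian PSF sampled on the voxel grid.

**Clonogenic survival.**  Plating efficiency PE = colonies/cells plated at
dose 0; relative survival S(D) = (colony fraction at D)/PE, so S(0) = 1.
Two plating densities per dose are averaged within an experiment, curves
aggregate experiments as mean ± SEM, and genotypes are compared per dose
with a one-tailed paired Student t-test.  An optional linear-quadratic fit
S(D) = exp(−αD − βD²) is included.

**Cell cycle.**  DNA histograms are gated with peak-anchored gates at
2N ± 2.5 CV and 4N ± 2.5 CV, with an S-phase spill-in correction.  For a
colcemid time course, f<sub>G0/1</sub>(t) is fitted with
r + (f₀ − r)·exp(−t/τ); the plateau r estimates the non-cycling
subpopulation.  Division-interval tracks give mean ± SEM cycle length per
line, the fold change between lines, and a two-tailed unpaired t-test.

**CRISPR verification.**  Protospacer localization (20-nt guide + NGG PAM,
optionally NAG), the canonical SpCas9 blunt cut 3 bp 5′ of the PAM,
exact-match in-silico PCR, Surveyor cleavage-fragment prediction, and the
indel estimate indel% = 100·(1 − √(1 − f_cut)) with
f_cut = (b + c)/(a + b + c) from band intensities.

## Worked example

```python
from fociquant3d.synthetic import FociPhantomParams, gen_foci_stack
from fociquant3d import foci

params = FociPhantomParams(n_nuclei=4, stack_shape=(42, 224, 224),
                           n_gh2ax_per_nucleus=10, coloc_prob=0.5, seed=1)
stack, truth = gen_foci_stack(params)

mask = foci.segment_nuclei(stack.channel("DNA"))
gh = foci.detect_foci(stack.channel("gH2AX"), mask, foci.MIN_VOXELS_GH2AX,
                      voxel_size_nm=stack.voxel_size_nm)
smc = foci.detect_foci(stack.channel("SMC6"), mask, foci.MIN_VOXELS_SMC6,
                       voxel_size_nm=stack.voxel_size_nm)
records = foci.per_cell_records(mask, gh, smc)
for r in records:
    print(r.nucleus_label, r.n_gh2ax, r.n_smc6, r.n_overlap,
          round(r.frac_smc6_positive, 2), r.selected)
summary = foci.summarize_condition(records)
print(f"mean gH2AX foci/cell = {summary.mean_gh2ax:.2f} ± {summary.sem_gh2ax:.2f} (SEM)")
```

prints

```
1 10 6 4 0.4 True
2 10 7 5 0.5 True
3 10 6 4 0.4 True
4 10 4 2 0.2 True
mean gH2AX foci/cell = 10.00 ± 0.00 (SEM)
```

Each row is one nucleus: its γH2AX focus count, SMC6 focus count, how many
γH2AX foci overlap an SMC6 focus, the per-cell SMC6-positive fraction, and
whether the cell passes the ≥2-SMC6-foci selection.  The phantom was built
with 10 foci per nucleus and a 50% co-staining probability, and the
detector recovers exactly those counts (here 4/5/4/2 co-stained foci,
matching the generator's ground truth).

A command-line interface covers the same stages:

```bash
fociquant3d simulate --seed 1 --out out/           # phantom TIFF + ground truth
fociquant3d foci --input out/phantom.tif --out cells.csv
fociquant3d demo --seed 0 --out out/demo           # every stage end to end
```

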