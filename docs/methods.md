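# Methods

`dixbone` simulates and quantifies the PET bias caused by omitting bone
from MR-derived attenuation maps in brain PET-MRI, and implements the
bone-augmented correction that removes it. Everything runs on a synthetic
digital head, so every number the package reports is reproducible from a
seed with no scanner data.

## The attenuation-correction problem

PET reconstruction must correct each line of response (LOR) for photon
attenuation: the correction factor is ACF = exp(+∫ μ dl) with μ the
511 keV linear attenuation coefficient along the LOR. PET-MRI systems
derive μ from MRI. The standard 2-point Dixon method segments the water
and fat channels into air / fat / soft tissue (μ = 0, 0.086,
0.10 cm⁻¹) — but cortical bone is nearly invisible on Dixon images and is
classified as soft tissue (μ = 0.10 instead of 0.143 cm⁻¹). Every LOR
through the head crosses the skull twice, so activity is underestimated,
and LORs grazing the skull at large impact parameters accumulate the
longest bone paths, so the bias grows from the brain centre to the
cortex.

The bone-augmented map ("Dixon+bone") segments a T1-weighted image into
six tissue classes, extracts a bone mask from the bone posterior, and
overlays μ = 0.143 cm⁻¹ on the Dixon map inside that mask.

## Digital head phantom (`dixbone.phantom`)

Concentric layers carved from an ellipsoidal scalp surface by
distance-to-surface bands, so each shell has uniform thickness in mm:
scalp fat (3 mm), soft tissue (4 mm), skull (configurable, default
7 mm for the bare builder), subarachnoid CSF (2 mm), a GM shell (5 mm)
and a WM core containing two CSF lateral ventricles. Per-tissue
properties:

| tissue | T1 (a.u.) | fat fraction | μ (cm⁻¹) | emission (a.u.) | perfusion (ml/100 g/min) |
|---|---|---|---|---|---|
| air | 0 | 0 | 0 | 0 | 0 |
| scalp fat | 0.95 | 0.90 | 0.086 | 0.1 | 0 |
| soft tissue | 0.70 | 0.10 | 0.10 | 0.3 | 0 |
| skull | 0.15 | 0 | 0.143 | 0.05 | 0 |
| CSF | 0.35 | 0 | 0.10 | 0.1 | 0 |
| GM | 0.55 | 0 | 0.10 | 3.0 | 43.82 |
| WM | 0.85 | 0 | 0.10 | 1.0 | 21.9 |

T1 intensities are ordered bone < CSF < GM < WM ≈ fat (skull dark on
T1); the GM:WM emission contrast of 3:1 is a conventional FDG ratio; GM
perfusion is set to a healthy-adult group-mean CBF so the ASL round trip
is a parameter-recovery experiment. The T1 render multiplies tissue
intensity by a 2nd-order polynomial bias field (default amplitude ±10%)
and adds Gaussian noise with SD = 5% of the tissue mean; the Dixon
render splits the same signal by fat fraction, which leaves the skull
with low signal in both channels — the premise of the whole exercise.
The 13-region ROI atlas is deliberately geometric (deep azimuthal
sectors plus cortical sectors and a cerebellar cap) under the
conventional a-priori region names: only the statistics machinery needs
labelled regions, anatomical fidelity is a non-goal.

What the phantom does **not** emulate: MR sequence physics, partial
voluming (labels are crisp), motion, skull-base anatomy and sinuses,
scatter/randoms in PET. Passing tests therefore demonstrate the internal
consistency of the method and the attenuation physics, not performance
on clinical data.

## Tissue segmentation (`dixbone.segmentation`)

An atlas-free stand-in for unified segmentation: a 6-class Gaussian
mixture over intensities with a jointly estimated multiplicative
polynomial bias field (default order 2), fitted by generalized EM.
Spatial atlas priors are replaced by user-supplied class-intensity
seeds, which is appropriate for phantom data whose class intensities are
separable by construction; a distance prior for air/bone disambiguation
proved unnecessary for the same reason. The observed-data log-likelihood
is non-decreasing per iteration (asserted in tests); variances are
floored at 1e-6 of the data variance and flagged (the air class, which
is exactly zero in the renders, always hits the floor); convergence
tolerance 1e-6 relative, default cap 100 iterations.

Rigid coregistration maximizes Studholme normalized mutual information
on a 32×32 joint histogram with Powell search from three seeded starts.
In the default experiment all renders share one grid, so the step is
skipped (config-exposed); it exists for data that needs it.

## μ-map synthesis (`dixbone.mumap`)

Dixon map: air below 5% of the robust (99th-percentile) total signal,
else fat where the fat channel dominates, soft tissue otherwise; ties
break to soft tissue. Bone-mask chain, in fixed order: resample the bone
posterior to the μ-map grid → Gaussian smooth (4 mm FWHM) → threshold
strictly >0.80 → binary erosion with a 3×3×3 all-ones element → drop
26-connected components smaller than 27 voxels. Composition overlays
μ = 0.143 cm⁻¹ inside the mask; it is idempotent and can only raise μ.

**Grid caveat, and why the default experiment adapts the chain.** The
4 mm smooth + >0.8 threshold retains only the central ±(t/2 − 0.84σ)
band of a uniform shell of thickness t (σ = 1.70 mm), and the 3×3×3
erosion removes one more voxel from each side. At 2 mm voxels a 7–8 mm
skull shell is erased entirely — a regression test documents this
collapse. Erosion-element size is exactly the kind of parameter that is
tuned empirically to the grid at hand; the default experiment therefore
runs the same chain with grid-adapted parameters (no smoothing,
threshold 0.5, no erosion, component filter retained), which recovers
the skull with Dice ≥ 0.9 against ground truth. All parameters are
config-exposed; the published defaults remain the function defaults.

## PET simulation and reconstruction (`dixbone.petsim`)

Desk-scale, slice-parallel 2-D parallel-beam geometry (default 192
angles over [0, π), one radial bin per voxel column, 5 central axial
planes). The in-plane radial bias of interest needs no oblique LORs. The
system matrix is assembled sparsely from bilinear ray samples (step =
half a voxel), so forward and back projection are exact transposes —
adjointness holds to machine precision, which is what OSEM correctness
rests on. Attenuation enters as Beer–Lambert survival factors; expected
data = survival × (A x). OSEM uses 3 iterations × 21 interleaved angular
subsets with a 2 mm FWHM Gaussian post-filter (the clinical protocol);
denominators are epsilon-guarded so no NaN/Inf is ever emitted and
output is nonnegative by construction. Scatter, randoms, normalization,
decay, dead time and hardware attenuation are deliberately omitted: they
are orthogonal to the attenuation-map comparison.

The headline experiment projects the noiseless emission attenuated by
the **true** μ-map, then reconstructs three times with ACFs from the
true, Dixon, and Dixon+bone maps. The percent relative difference
%RD = 100·(PET_dxbone − PET_dx)/PET_dx is evaluated voxelwise in the
brain, and summarized as shell averages over the normalized in-slice
brain radius (shell 1 of 10 = "centre", shell 10 = "cortical rim").

Two observed behaviours worth noting. First, with 3 OSEM iterations the
low-frequency component of the mismatch bias is not fully converged, so
the centre %RD (~2.5%) sits below the single-LOR Beer–Lambert estimate
(~6% for a 16 mm bone path); more iterations raise it, but the 3×21
protocol is the study condition. Second, the under-estimation is
voxelwise strict in GM and WM, but ventricular CSF (emission 1/30 of GM)
can locally invert: count redistribution inflates cold structures. Tests
assert the direction on metabolically active tissue.

## pCASL quantification (`dixbone.aslquant`)

Pairwise control−label subtraction, time averaging, and the standard
single-compartment solution

CBF = 6000 λ ΔM e^{PLD/T1b} / (2 α T1b M0 (1 − e^{−τ/T1b}))  [ml/100 g/min]

with defaults τ = 1.5 s, PLD = 1.2 s, λ = 0.9 ml/g, T1b = 1.65 s and
α = 0.85 × 0.75² (two background-suppression inversions each costing a
factor 0.75). These constants are config-exposed; the generator uses the
exact inverse of this formula, so CBF recovery is a self-consistency
(generator ↔ quantifier) check, not a claim about any particular
clinical implementation. Default series: 64 pairs, frame noise SD = 1%
of mean head M0. tSNR is the masked mean of the temporal mean of the
pair-difference series divided by the masked mean of its temporal SD.

## Statistics (`dixbone.stats`)

6 mm FWHM Gaussian smoothing, strict >80% GM masking, global-GM-mean
scaling ("relative" images), ROI mean/SD tables and %RD tables, paired
t-tests (two-sided, df = n−1, zero-variance differences rejected),
Pearson correlation within ROI masks, and voxelwise pooled-variance
two-sample t-maps with Benjamini–Hochberg FDR (independence variant) at
q = 0.05 followed by 26-connectivity clustering with a strict >50-voxel
extent threshold. BH and cluster labelling are verified against
independent sort-rule and flood-fill oracles.

Design choices where the convention was open: pooled-variance (not
Welch) t; strict inequalities at both the 80% and the extent thresholds;
BH rather than topological FDR; 26-connectivity. Regional %RD is
computed on smoothed reconstructions both before and after global-mean
scaling, since scaling can legitimately flip the sign of regional
differences (a constructed counterexample is in the test suite).

## Default experiment and problem sizes

`ExperimentConfig()` encodes the study conditions: 128³ grid at 2 mm,
skull 8 mm (within the 5–8 mm adult calibration range; chosen so the
simulated radial bias matches the observed ~5→20% cortical amplitudes),
noiseless emission, 192 angles × 5 central slices, OSEM 3×21 + 2 mm
filter, segmentation from a 5%-noise/10%-bias T1, 64 ASL pairs at 1%
noise. One full run takes a few minutes and under 3 GB on a single CPU;
the unit suite uses 48–64³ phantoms of the same construction. All
randomness flows from one master seed through named substreams
(phantom, t1, dixon, counts, asl), so stages are independently
reproducible.

## Known limitations

- 2-D slice-parallel geometry: no oblique LORs, no skull-base bone, so
  absolute bias amplitudes are not transferable to 3-D scanners.
- The ROI atlas is geometric; regional results index sectors, not
  anatomy.
- The Dixon classifier stands in for an unpublished vendor
  implementation; only its class/LAC convention is shared.
- CBF recovery validates the quantifier against the generator's own
  forward model; it cannot validate the model constants themselves.
- The bone-mask chain with published parameters is grid-sensitive (see
  above); on coarse grids it must be re-tuned or it erases thin bone.
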