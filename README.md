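# dixbone

Bone-aware MR-based attenuation correction (MRAC) for brain PET-MRI, on a
fully synthetic, seed-reproducible digital head.

PET quantification needs a 511 keV attenuation map (μ-map). PET-MRI
systems build it from MRI: the standard 2-point Dixon method segments
water/fat images into air (μ=0), fat (0.086 cm⁻¹) and soft tissue
(0.10 cm⁻¹) — and misses bone, which ends up as soft tissue instead of
μ=0.143 cm⁻¹. Because every line of response through the brain crosses
the skull twice, and lines grazing the skull accumulate the longest bone
paths, the reconstructed activity is biased low, increasingly so from
the brain centre to the cortex. The package implements both the plain
Dixon μ-map and the bone-augmented "Dixon+bone" variant (T1-based tissue
segmentation → bone posterior → smoothing/threshold/morphology chain →
μ=0.143 overlay), a desk-scale attenuated-emission simulator with OSEM
reconstruction (3 iterations × 21 subsets, 2 mm post-filter) to measure
what the missing bone costs, single-compartment pCASL CBF
quantification, and the evaluation statistics (ROI %RD tables, paired
t-tests, voxelwise FDR-corrected comparisons with cluster-extent
thresholds).

Who it is for: researchers studying MRAC bias and anyone needing a
self-contained, oracle-tested simulation bench for attenuation-correction,
reconstruction and perfusion-quantification pipelines.

The key summary statistic is the percent relative difference

    %RD = 100 · (PET_dxbone − PET_dx) / PET_dx

between reconstructions of the *same* attenuated data corrected with the
bone-inclusive vs the bone-free μ-map.

## Worked example

```python
import json
from dixbone.experiment import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig())   # ~2-4 min, <3 GB
print(json.dumps(report.metrics, indent=2))
```

prints

```json
{
  "center_rd_percent": 2.6882492140883754,
  "cortex_rd_percent": 20.73284452200309,
  "brain_mean_rd_percent": 8.130421102149576,
  "bone_mask_dice": 1.0,
  "gm_cbf_ml_per_100g_min": 43.60741825113383,
  "gm_tsnr": 0.22919866017369717
}
```

Reading: ignoring bone costs ~8% of the whole-brain signal on this
phantom, ranging from ~2.7% at the brain centre to ~20.7% at the
cortical rim (`report.shell_means` holds the full radial profile, which
rises monotonically through the outer shells); the bone mask recovered
from the noisy T1 matches the true skull (Dice 1.0); and the 64-pair
pCASL series quantifies back to 43.6 ml/100 g/min against the phantom's
ground-truth GM perfusion of 43.82. The regional table
(`report.roi_rd`) shows the same gradient — cortical sectors ~9–10.4%,
deep-grey sectors ~3.4–4.3%.

The same pipeline is scriptable stage by stage:

```
dixbone phantom --shape 128 --spacing 2 --skull 7 --seed 42 --out ph/
dixbone segment --t1 ph/t1.nii.gz --init 0,0.15,0.35,0.55,0.70,0.85 --out seg/
dixbone mumap --water ph/dixon_water.nii.gz --fat ph/dixon_fat.nii.gz \
    --bone-prob seg/prob_class1.nii.gz \
    --fwhm 0 --threshold 0.5 --erosion 1 --out mu_dxbone.nii.gz
dixbone experiment --seed 0 --out results/
```

## Layout

- `src/dixbone/phantom.py` — digital head, renders, ROI atlas
- `src/dixbone/segmentation.py` — GMM+bias-field EM, NMI rigid registration, resampling
- `src/dixbone/mumap.py` — Dixon μ-map, bone-mask chain, composition
- `src/dixbone/petsim.py` — projector/ACFs/OSEM, %RD maps, radial profiles
- `src/dixbone/aslquant.py` — pCASL subtraction, CBF model, tSNR
- `src/dixbone/stats.py` — smoothing, masking, ROI/%RD tables, t-tests, FDR clusters
- `src/dixbone/experiment.py`, `cli.py`, `io.py` — driver, CLI, NIfTI I/O
- `docs/methods.md` — model assumptions, defaults, numerical choices, limitations
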