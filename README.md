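# pddc

Dual-domain cascaded CNN reconstruction for undersampled brain MRI, with the
downstream susceptibility-weighted imaging (SWI) and neurovascular analysis
chain: phase-mask SWI processing, cerebral microbleed (CMB) and lacunar
infarction detection, vertebrobasilar artery morphometry, and two-group
cohort statistics.  Everything runs end-to-end on synthetic phantoms
generated by the package itself, so no acquired data is needed to exercise
or validate any stage.

## Who this is for

Researchers prototyping compressed-sensing MRI reconstruction networks with
data-consistency layers, and anyone who needs a tested, self-contained
reference implementation of the classic SWI processing chain and the
clinical reading rules for microbleeds, lacunes and vertebrobasilar
morphometry.

## The model

**Reconstruction.** The cascade has five stages.  Stage *m* maps the running
image/k-space pair through a convolutional feature extractor per domain
(no parameter sharing within or across stages), applies a hard
data-consistency layer in k-space, cross-fuses each domain with the
Fourier(-inverse) transform of the other, and adds the stage input through a
residual connection:

    a_{m+1} = g(a_m) + K(a_m, c_m)

where `g` is the identity direct path and `K(·, c_m)` the learned residual
branch with weights `c_m`.  Telescoping the recursion, the stage-M output is
the stage-1 input plus the sum of all residual updates, and the loss
gradient at the input carries the unit identity term

    ∂θ/∂a_m = ∂θ/∂a_M · (1 + ∂/∂a_m Σ K(a_h, c_h))

so gradients never vanish through the cascade.  Hard data consistency
guarantees the reconstructed spectrum equals the measurement at every
sampled location, after every stage and at the terminal output.

**SWI.**  From magnitude MI and phase PI: homodyne high-pass filtering with
a Hann-apodized central k-space window (32×32 or 64×64) removes background
phase; the negative-phase mask `w(φ) = ((π + φ)/π)^m` for `φ < 0` (else 1,
default `m = 4`) weights the magnitude; minimum-intensity projection over a
slab renders veins and microbleeds as continuous dark structures.

**Readings.**  CMBs: compact hypointense components with equivalent diameter
1.5–6.5 mm; elongated structures traced across contiguous slices are
excluded as vessels.  Lacunes: cavities < 15 mm, T1-hypointense and
T2-hyperintense.  Vertebral dominance: three-point averaged diameters
(samples 0.3 cm apart from the confluence), dominant side at ≥ 0.3 mm
difference, graded I (0.04–0.70 mm), II (0.71–1.17 mm), III (1.18–2.67 mm).
Basilar curvature: BAL = endpoint chord, BL = maximal perpendicular
deviation, typed normal / C / reverse-C / S from the signed deviation
profile.  Cohort statistics: Welch t, chi-square with automatic Fisher
fallback, Wilcoxon rank-sum, all at α = 0.05.

## Worked example

```python
>>> from pddc.stats import ContingencyTable2x2, chi_square, positivity_rates
>>> tab = ContingencyTable2x2(14, 16, 4, 26)   # positives/negatives per group
>>> positivity_rates(tab)
{'group1_positive': 14, 'group1_n': 30, 'group1_rate_percent': 47,
 'group2_positive': 4, 'group2_n': 30, 'group2_rate_percent': 13,
 'total_positive': 18}
>>> round(chi_square(tab).statistic, 3)
7.937
```

14 of 30 case subjects (47%) and 4 of 30 controls (13%) are CMB-positive;
the uncorrected chi-square for the 2×2 table is 7.937, significant at
α = 0.05.

A desk-scale reconstruction experiment (numbers printed by
`scripts/acceptance.py --seed 1`):

```
zero_filled_mean_psnr_db : 22.645   # baseline on 16 held-out slices
recon_mean_psnr_db       : 34.758   # five-stage cascade, 4x acceleration
recon_psnr_gain_db       : 12.113   # cascade improvement over zero-filling
```

The cascade, trained about a minute on one CPU on 64×64 phantom slices at
4× Cartesian undersampling, beats the zero-filled baseline by roughly 12 dB
of mean PSNR on held-out phantoms (the exact figure varies a little with
the seed).

## Command line

```bash
pddc simulate --seed 1 --n-per-group 30 --out cohort/
pddc train    --slices 24 --epochs 30 --seed 1 --out model.npz
pddc recon    --model model.npz --kspace slice.h5 --out recon.nii
pddc swi      --mag mag.nii --phase pha.nii --window 64 --m 4 --mip 8 --out swi.nii
pddc detect   --swi swi.nii --t1 t1.nii --t2 t2.nii --out lesions.csv
pddc morph    --centerline basilar.csv --left-mm 3.5 --right-mm 2.5 --out morph.csv
pddc stats    --cohort cohort/cohort.csv --out report/
pddc run-all  --seed 1 --out run/
```

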