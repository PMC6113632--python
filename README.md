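# dtbz — infarct border-zone microstructure from LGE + diffusion tensor MRI

`dtbz` is a tested re-implementation of a DT-MRI analysis of microstructural
remodeling in the infarct border zone (BZ) of the post-infarct heart. Late
gadolinium enhancement (LGE) MRI segments the myocardium into remote, BZ and
infarcted tissue; co-registered diffusion tensor MRI (DT-MRI) quantifies the
microstructure of each region through three rotation invariants of the
diffusion tensor **D**:

- **ADC** — apparent diffusion coefficient, `tr(D)/3` [mm²/s]; rises as
  cellularity falls;
- **FA** — fractional anisotropy, `√(3/2)·‖Ã‖/‖D‖` with `Ã = D − ADC·I`,
  on [0, 1]; falls with fibrosis;
- **tissue mode** — `3√6·det(Ã/‖Ã‖)`, on [−1, 1]; +1 rod-like, 0
  sheet-like/orthotropic, −1 planar; falls with fiber disarray.

Because voxelwise imaging data is spatially correlated and non-Gaussian, all
inference is distribution-free: per-region samples are spatially decorrelated
by decimation at each region's 1/e autocorrelation length, then compared with
bootstrapped histograms, bootstrapped median CIs, a bootstrap two-group median
comparison, and a bootstrap analog to repeated-measures ANOVA across regions
within hearts.

A synthetic phantom — an LV annulus with an infarct wedge, a BZ shell,
per-region LGE signal plateaus, per-region invariant distributions with
controlled spatial correlation, Rician noise, and a hidden rigid offset
between the LGE and DT-MRI frames — makes every stage testable end to end
with known ground truth.

## Worked example

```python
from dtbz import RunConfig, run_pipeline

report = run_pipeline(RunConfig(n_infarcted=2, n_normal=2, seed=7))
print(report.median_table())
for inv, a in report.anova.items():
    print(f"ANOVA {inv}: F={a['f']:.1f} p={a['p']:.3g}")
```

prints (ADC in mm²/s):

```
         adc_median  adc_ci_low  adc_ci_high  fa_median  fa_ci_low  fa_ci_high  mode_median  mode_ci_low  mode_ci_high
region
normal    0.0005627   0.0005604    0.0005653     0.4739     0.4728       0.475       0.7404       0.7391        0.7419
remote    0.0005747   0.0005712    0.0005783     0.4673     0.4659      0.4684       0.6582       0.6566        0.6597
bz        0.0006465    0.000644    0.0006493     0.4194     0.4174      0.4214       0.6172       0.6072        0.6238
infarct     0.00079   0.0007853    0.0007951     0.3326     0.3313      0.3337       0.5076       0.5021        0.5127

ANOVA adc: F=1291.4 p=0.0006
ANOVA fa: F=942.9 p=0.0018
ANOVA mode: F=1160.9 p=0.0015
```

Each row is the pooled bootstrapped median (with 95% CI) of the spatially
decorrelated invariant samples for one region: ADC increases and FA decreases
monotonically from remote through BZ to infarct — the microstructural
remodeling gradient the analysis is designed to detect — and the
repeated-measures ANOVA analog confirms the region effect across hearts.

There is also a thin CLI:

```bash
dtbz simulate --out phantom/ --seed 3     # one synthetic heart (NIfTI + bvec/bval)
dtbz run --out results/ --seed 7          # full study; writes report.json + CSVs
dtbz report --in results/                 # pretty-print the pooled medians
```

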