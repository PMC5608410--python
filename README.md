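# wmhdti

White-matter hyperintensities (WMH) — the T2/FLAIR-bright lesions of
cerebral small-vessel disease — locally elevate mean diffusivity (MD) and
reduce fractional anisotropy (FA). When two groups differ in WMH burden
(as prodromal Alzheimer's disease patients and elderly controls typically
do), tract-averaged DTI comparisons mix two very different signals: true
alterations of normal-appearing white matter (NAWM) and the incidental
lesion load running through the tract. `wmhdti` implements the complete
analysis pipeline needed to study and correct this confound, exercised
entirely on synthetic data:

* **image level** — diffusion phantoms with known tensor fields, bundle
  geometries and lesions; Rician-noise DWI simulation (b = 0 and
  1 ms/µm², 64 directions, 2 mm isotropic); heteroscedasticity-corrected
  weighted linear least-squares (WLLS) tensor fitting; MD/FA maps;
  deterministic streamline tractography (FA ≥ 0.2, turn ≤ 30° per step);
  atlas-style AND-ROI / dilated-shell NOT-ROI tract segmentation and
  per-tract averaging;
* **subject level** — WMH and ventricle volumes as % of intracranial
  volume; lower (≤ 0.5 % ICV) vs higher (≥ 1 % ICV) load classification;
* **cohort level** — simulated cohorts (132 controls + 83 prodromal AD)
  whose per-tract metrics combine a lesion-load component and a
  disease-specific NAWM component; covariate-matched subgroup contrasts
  with Cohen's *d*; and nested standardized regressions
  (model 1: metric ~ group + ventricle load; model 2: + WMH load) with
  ΔR² and its F-change test.

The statistical core in the field's notation: for tract *t* and subject
*j*,

```
y_jt = μ_t + γ s_t L_j + a_t AD_j + b_v VV_j + ε_jt
```

where `L_j` is WMH load (% ICV), `s_t` the tract's lesion susceptibility,
`a_t` the NAWM disease effect, and `VV_j` ventricle load. Cohen's
*d* = (m₂ − m₁)/s_pooled with the usual pooled SD;
ΔR² = R²₂ − R²₁ is tested with
F = (ΔR²/q) / ((1 − R²₂)/(n − p₂ − 1)).

## Worked example

The matched-subgroup effect size from printed summaries — left SLF MD
0.73 ± 0.03 (lower load) vs 0.79 ± 0.06 (higher load), n = 21 + 21:

```python
>>> from wmhdti import cohens_d_from_summary
>>> cohens_d_from_summary(0.73, 0.03, 21, 0.79, 0.06, 21)
1.2649110640673529
```

A WMH load difference alone is a *large* effect by conventional
standards — on par with reported disease effects.

The confound-recovery demonstration: simulate a cohort in which the
SLF-analog group difference is carried entirely by WMH load while the
VC-analog difference is a pure NAWM effect, then compare the unadjusted
(model 1) and adjusted (model 2) regressions:

```python
from wmhdti.cohort import confound_recovery_spec, simulate_cohort
from wmhdti.stats import run_table3, table3_frame

df = simulate_cohort(confound_recovery_spec(seed=0))
frame = table3_frame(run_table3(df, metrics=("md",)))
```

which prints (formatted):

```
slf_left_md: beta_group m1=+0.57 (p=1.6e-20) m2=+0.02 (p=0.67) beta_WMH=+0.80 (p=5.2e-38) dR2=0.318
vc_left_md:  beta_group m1=+0.29 (p=2.6e-05) m2=+0.25 (p=0.01) beta_WMH=+0.06 (p=5.2e-01) dR2=0.002
```

Unadjusted, both tracts show a "disease effect". Adjusting for WMH load
removes the SLF effect entirely (β 0.57 → 0.02, n.s.) and transfers it to
the WMH coefficient (β = 0.80, ΔR² = 0.32), while the genuine NAWM effect
in the VC survives adjustment (β = 0.25, p = 0.01). This is the
qualitative signature that distinguishes lesion-driven from
disease-specific tract differences.

The same pipeline is scriptable from the shell:

```bash
wmhdti phantom --out run/ph --seed 3 --grid 24 --no-noise
wmhdti fit     --dwi run/ph/dwi --mask run/ph/brain_mask.nii.gz --out run/fit
wmhdti track   --dwi run/ph/dwi --mask run/ph/brain_mask.nii.gz --out run/trk
wmhdti cohort  --out run/cohort --seed 1
wmhdti stats   --cohort run/cohort/cohort.tsv --out run/stats
wmhdti demo    --out run/demo --seed 0
```

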