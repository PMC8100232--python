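# dtialps

Glymphatic-function quantification for a diffusion-MRI study of peritumoral
brain edema (PTBE) in meningiomas: the DTI-ALPS index, planimetric lesion
volumetry, and the cohort statistics that relate them — all exercisable on
synthetic phantoms and simulated cohorts, so the entire analysis chain is
testable without any patient data.

## Who this is for

Neuroimaging researchers who want a reproducible, scripted implementation of
the ALPS ("analysis along the perivascular space") analysis: per-voxel
diffusion-tensor estimation from single-shell DWI, extraction of fiber-ROI
axis diffusivities, the index itself, inter-observer agreement, and the
group-level statistical battery (covariate-adjusted ANCOVA, Pearson
correlation, variance-inflation screening, stepwise regression).

## The index

At the level of the lateral ventricle body the perivascular spaces of the
deep medullary veins run right–left (the image *x*-axis), nearly
perpendicular both to the corticofugal projection fibers (principal axis
craniocaudal, *z*) and to the superior-longitudinal-fasciculus association
fibers (principal axis anterior–posterior, *y*). With ROI-mean diagonal
tensor elements `D_xproj, D_yproj` (projection-fiber ROI) and
`D_xassoc, D_zassoc` (association-fiber ROI):

```
ALPS = mean(D_xproj, D_xassoc) / mean(D_yproj, D_zassoc)
```

An isotropic medium gives exactly 1; water movement along the perivascular
(*x*) direction pushes the index above 1. The package's synthetic
periventricular phantom makes this identifiable by construction: an additive
right–left diffusivity component `boost` inside both fiber slabs gives the
closed-form ground truth `ALPS = (λ⊥ + boost) / λ⊥`.

## Worked example

Simulate the study-structured cohort (80 meningioma patients in four
side-by-edema groups plus 44 controls, ALPS marginals and the ALPS–PTBE
correlation calibrated to the study's printed group parameters) and run the
group comparison and correlation flows:

```python
import dtialps as d

cohort = d.generate_cohort(d.default_cohort_config(seed=7))
grid = d.run_group_comparison(cohort)
print(grid[(grid.tumor_side == "right") & (grid.response == "alps_right")]
      [["group_a", "group_b", "adj_diff", "p_adj", "ci_low", "ci_high"]])

corr, vifs, reg = d.run_correlation_analysis(cohort)
print(reg.selected, reg.std_coefficients, round(reg.r_squared, 3))
```

Output (seed 7):

```
           group_a         group_b  adj_diff        p_adj    ci_low  ci_high
meningioma_no_ptbe meningioma_ptbe  0.237109 3.962788e-09  0.152252 0.321966
meningioma_no_ptbe         control  0.252656 2.396126e-10  0.169796 0.335515
   meningioma_ptbe         control  0.015546 1.000000e+00 -0.047500 0.078593

('alps_ipsi',) {'alps_ipsi': -0.675} 0.455
```

Reading it: edema-free meningiomas sit ~0.24 units above the edema group and
~0.25 above controls on the right ALPS index (Bonferroni-adjusted p < 0.001
for both), while the edema group is indistinguishable from controls — and in
the PTBE+ subset the tumor-side ALPS index is the only stepwise-selected
correlate of edema volume (standardized β = −0.675, R² = 0.455), i.e. lower
perivascular diffusivity goes with larger edema.

The same flows run from the shell:

```bash
dtialps simulate-cohort --out cohort.csv --seed 7
dtialps report --cohort cohort.csv --out results/ --plots
dtialps simulate-phantom --out phantom/ --boost 2e-4 --snr 30
```

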