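# tmsfield

Dual-target TMS electric-field analysis on synthetic spherical head models.

## The problem

Repetitive transcranial magnetic stimulation (rTMS) of the left dorsolateral
prefrontal cortex (DLPFC) is targeted in clinical practice by one of three
methods: a **functional** target from resting-state connectivity, an
**anatomical** target at fixed stereotaxic coordinates (−38, 44, 26) projected
to the nearest cortical surface, or the 10–20 EEG **F3** electrode position.
The three sites are close — the anatomical and F3 targets nearly coincide,
while functional targets scatter widely across subjects — so a figure-8 coil
placed over one target also stimulates the others. This package models that
interplay quantitatively: how dispersed each targeting method is across a
cohort, what normalized E-field (E_ROI, E_⊥) each target receives for a given
coil position, and how the coil **handle orientation relative to the line of
interest (LOI)** — the segment joining the anatomical and functional targets —
can preserve the functional-target field while suppressing the anatomical one.

Because patient MRIs and finite-element head models are not distributable, the
package works on a *synthetic* testbed: perturbed concentric-sphere heads
(scalp/skull/CSF/cortex at 85/80/75/73 mm) with a cohort generator calibrated
to the measured target statistics (functional dispersion ≈ 13.6 mm, anatomical
≈ 5.2 mm, F3 ≈ 4.6 mm; functional–anatomical separation ≈ 24.5 mm,
anatomical–F3 ≈ 4.8 mm).

## The model

The E-field of a figure-8 coil (two opposed windings, discretized as magnetic
dipoles with moments **m** normal to the coil plane) inside a spherically
symmetric conductor has a closed form obtained from the Sarvas
magnetoencephalography formula by reciprocity. For a dipole rate **ṁ** at
position **r**<sub>c</sub> and field point **r** (relative to the sphere
center),

    E(r) = −(μ₀ / 4πF²) [ F (r × ṁ) − (∇F · ṁ)(r × r_c) ],

with `F = a (r_c a + r_c² − r·r_c)`, `a = |r_c − r|`, and ∇F the Sarvas
gradient. The total field is exactly tangential (the secondary charge field
cancels the radial component) and independent of the radial conductivity
profile, so the tissue conductivities are carried as metadata only. The
implementation is validated against an independent spherical-harmonic
boundary-value solver to < 10⁻⁴ relative error.

ROI metrics follow the clinical convention: a 10-mm-radius sphere centered on
the cortical target collects surface samples ("voxels"); `E_ROI` is the mean
|E| over the ROI and `E_⊥` the mean unsigned normal component, both normalized
by the field at the primary-motor-cortex (M1) reference site at di/dt = 1 A/μs
(the treatment site uses 0.8 A/μs ≙ 80 % of resting motor threshold). The
statistics layer reproduces the field's standard effect sizes: one-way ANOVA
with η² = (k−1)F / ((k−1)F + N−k), Fisher's LSD post-hoc tests, Cohen's
d = |m₁−m₂| / √((s₁²+s₂²)/2), and r = d / √(d²+4).

## Worked example

```python
from tmsfield import DualTargetExperiment, RunConfig

exp = DualTargetExperiment.from_config(RunConfig(n_subjects=30, seed=0))
res = exp.fit()
print(res.summary())
```

```
Dual-target TMS E-field experiment
subjects: 30 (failed: 0); M1 reference: 3.435 V/m

Targeting dispersion (ANOVA F=35.67, eta2=0.45; fold change 2.57)
===============================================
  target   dispersion mm  sd  voxels volume mm3
-----------------------------------------------
functional         13.67 7.01   47.1        785
anatomical          5.32 2.75   46.1        789
        f3          4.69 2.58   45.5        785
-----------------------------------------------
      Inter-target distances
==================================
         pair         mean mm  sd
----------------------------------
functional-anatomical   24.12 8.51
        functional-f3   23.93 9.96
        anatomical-f3    5.32 2.93
----------------------------------
                 Coil over the functional target
=================================================================
 orientation  E_ROI func E_ROI anat ratio E_perp func E_perp anat
-----------------------------------------------------------------
      initial      0.647      0.394  1.64       0.008       0.003
     parallel      0.647      0.437  1.48       0.006       0.003
perpendicular      0.647      0.221  2.93       0.009       0.003
-----------------------------------------------------------------
parallel->perpendicular drop: functional +0.02%, anatomical -49.43% (E_ROI)
sweep ratio extrema: max 3.75, min 1.55 (paired t=8.46)
```

Reading the output: functional targets scatter 2.57× more than anatomical ones
(13.67 vs 5.32 mm mean distance to the cohort centroid), and the anatomical
and F3 targets sit ~5 mm apart while the functional target is ~24 mm away.
With the coil over the functional target, the functional ROI receives
E_ROI ≈ 0.65 of the motor-threshold reference field at every orientation,
while the anatomical neighbor's field depends strongly on the handle
direction: rotating the handle from LOI-parallel to LOI-perpendicular leaves
the functional target essentially unchanged (+0.02 %) but suppresses the
anatomical target by ~49 %, raising the functional/anatomical selectivity
ratio from 1.48 to 2.93. (E_⊥ is near zero here because the field in a
concentric sphere is tangential to the cortex — see `docs/methods.md`.)

The same pipeline is scriptable from the shell:

```bash
tmsfield generate-cohort --out cohort.csv --n-subjects 30 --seed 0
tmsfield simulate --seed 0 --out run/          # full report bundle
tmsfield sweep --seed 0                        # orientation-ratio summary
tmsfield stats reproduce-reference             # published effect sizes
```

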