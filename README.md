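# lamsim

Finite-element simulation of stress in the levator ani muscle (LAM) during
the second stage of vaginal delivery.

During birth the pelvic-floor muscles are stretched far beyond any other
physiological loading, and stretch-related levator injury — typically at
the pubic origin of the pubovisceral muscle — is a major cause of
long-term pelvic-floor dysfunction.  `lamsim` is for biomechanics
researchers who want a fully reproducible, parametric version of the
classic delivery-simulation pipeline: no MRI segmentation, no commercial
solver, every stage scriptable and testable.

The pipeline:

1. **Material** — an N-term Ogden hyperelastic law in principal stretches,

       W = Σᵢ Σⱼ (2μⱼ/αⱼ)(λ̄ᵢ^αⱼ − 1) + (K/2)(J−1)²,  λ̄ᵢ = J^(−1/3)λᵢ,

   with reference levator parameters μ₁ = 8·10⁻⁵ MPa, μ₂ = 1.7·10⁻⁴ MPa,
   α₁ = 1.81, α₂ = 17.25, ν = 0.499, and constrained nonlinear
   least-squares identification of (μⱼ, αⱼ) from uniaxial stress–stretch
   data, P(λ) = Σⱼ 2μⱼ(λ^(αⱼ−1) − λ^(−αⱼ/2−1)).
2. **Synthetic anatomy** — parametric rigid fetal head and bony pelvis
   whose landmark pairs realize the standard obstetric diameters
   (suboccipitobregmatic 100.3 mm, occipitofrontal 105.7 mm,
   occipitomental 131.9 mm, biparietal 93.7 mm; pelvic inlet 113.4 mm,
   outlet 145.1 mm, transverse inlet 148.8 mm, interspinous 146.7 mm),
   plus a labeled tetrahedral levator shell (ICm / PVm / PRm subdivisions
   and attachment node sets).
3. **Kinematics** — the cardinal movements of labor as a prescribed
   rigid-head trajectory: descent along the curve of Carus with 100.0 mm
   net anterior displacement, straightening of a 28.66° lateral deviation,
   40.13° internal rotation completed at station +3, and 80.25° extension.
4. **Solver** — quasi-static large-deformation FE (linear tets,
   mean-dilatation volumetric treatment, analytic spectral Ogden tangent)
   with frictionless penalty contact against the rigid head.
5. **Analysis** — per-station, per-region von Mises summaries
   (mean/min/max/SD, volume-weighted), regional loading order, and the
   mediosagittal elongation of the shell.

## Worked example

Identify the material from synthetic uniaxial data, report the
trajectory, and run a coarse simulation:

```sh
$ lamsim fit --synthetic -o fit_out
fit: alpha = (1.81, 17.25), mu = (8e-05, 0.00017) MPa, E = 2.91e-32 MPa^2
```

The fit recovers the generating two-term Ogden set exactly (sum-of-squares
stress error E at machine precision), demonstrating that the uniaxial
curve identifies both exponents when the data are clean.

```sh
$ lamsim trajectory -o traj_out
{
 "net_anterior_displacement_mm": 99.99999999999999,
 "extension_deg": 80.25000000000001,
 "internal_rotation_deg": 40.130000000000024,
 "lateral_straightening_deg": 28.66000000000001,
 "n_frames": 27,
 "first_station": -3.0,
 "last_station": 12.02105763561644
}
```

The decomposed net head motion reproduces the configured cardinal
movements exactly; the head vertex runs from station −3 (3 cm above the
interspinous plane) to 12 cm below it at complete extension.

```sh
$ lamsim simulate -o run_out            # full run, several minutes
$ lamsim report run_out                 # re-derive tables from saved states
```

`run_out/` then contains `stress_table.csv` (station × region von Mises
summaries), `elongation.json` (mediosagittal stretch ratio per frame and
the caudal excursion of the distal puborectal loop), `trajectory.csv`, a
VTK series of the deforming shell, and a manifest with the config hash.
On the default synthetic geometry the head first indents the
iliococcygeal plate during descent; the pubic-attachment zones of the
PVm/PRm complex reach their mean-stress peak during extension (around
station +7), after the onset of extension as in the reference
description; and the run is truncated at station +8.5, the deepest
crowning pose the quasi-static continuation can hold (the truncation is
logged).  Absolute stress magnitudes depend on the (synthetic) geometry
and are deliberately not calibrated; the material-trace elongation of
the posterior midline reaches about 1.1 under these conditions (see
docs/methods.md for why the literature's ≈2.5 figure cannot be a
material stretch under this constitutive law).

Everything is a library call too:

```python
from lamsim import config, pipeline
cfg = config.default_config()
cfg["geometry"]["mesh_edge"] = 8.0          # coarser, faster
result = pipeline.run_simulation(cfg)
print(result.order, result.elongation.max_stretch_ratio)
```

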