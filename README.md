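# tdcsphere

Voxel finite-element simulation of transcranial direct-current stimulation
(tDCS) electric fields, with electrode-montage optimization over midline
10-10 sites, exercised on synthetic layered-sphere head phantoms with a
closed-form analytic oracle.

## The problem

tDCS drives a weak direct current (here 2 mA) through the head between two
35 cm² sponge electrodes. How much field reaches a cortical target depends
on the resistive path through scalp, skull, CSF and brain, and therefore on
where the electrodes sit. To stimulate the leg areas of primary motor
cortex (M1) and the supplementary motor area (SMA) **bilaterally and
symmetrically**, both electrodes must sit on the head midline — and the
best midline pair is not the one directly above the targets. Selecting it
requires solving the volume-conduction problem for every candidate montage
and ranking montages by the field strength they deliver to the targets.

`tdcsphere` implements that pipeline end to end for users who want to study
the *procedure* — solver behaviour, montage ranking machinery, conductivity
sensitivity — without access to private MRI-derived head models:

* **Phantoms** (`tdcsphere.phantom`) — concentric-sphere head models with
  skin/fat, compact (optionally spongy) bone, dura, CSF, gray- and
  white-matter shells; the tissue conductivity table (gray matter 0.2,
  white matter 0.14, CSF 1.8, compact bone 0.008 S/m, …); populations of
  phantoms with truncated-normal jitter of layer thicknesses and head size
  standing in for inter-individual anatomy.
* **Montage geometry** (`tdcsphere.montage`) — midline 10-10 sites at fixed
  fractions of the nasion–inion arc, sponge/rubber electrode assemblies
  conforming to the scalp, and enumeration of the candidate montage set
  with the footprint-overlap exclusion rule (23 montages survive).
* **Solver** (`tdcsphere.fem`) — the electrostatic equation ∇·(σ∇φ) = −i
  with homogeneous Neumann boundary conditions, discretized with first-order
  (trilinear) elements on the cubical voxels, solved by preconditioned
  conjugate gradients with the constant nullspace projected out;
  E = −∇φ per element; built-in current-conservation verification.
* **Analytic oracle** (`tdcsphere.oracle`) — the Legendre-series potential
  of an N-layer concentric sphere with surface point electrodes, used as an
  independent reference for solver verification.
* **Cortical mapping** (`tdcsphere.cortex`) — |E| sampled on the surface
  1 mm below the gray-matter boundary on a deterministic, mirror-symmetric
  golden-angle lattice; 1 cm-radius ROIs for left/right M1 ([±9, −39, 54])
  and SMA ([±3, −9, 60]) mapped from template coordinates.
* **Optimization** (`tdcsphere.optimize`) — per-montage, per-model ROI
  means; population mean ± SD; ranking by the four-ROI average; per-model
  optimum counts; sensitivity re-runs under bone ±50% and CSF ±10%
  conductivity perturbations.

The governing equation is

> ∇·(σ∇φ) = −i,  with σ ∂φ/∂n = 0 on the head surface,

where σ (S/m) is the tissue conductivity, i (A/m³) the volumetric current
source density on the electrode rubber sheets, and the stimulation field is
E = −∇φ (V/m). The montage objective is the unweighted mean of |E| over the
four M1/SMA ROIs, averaged over the model population.

Reproducing published per-montage field values from real anatomies is a
non-goal: those depend on private MRI data. The package reproduces the
procedure and its invariants on phantoms and verifies the solver against
the analytic sphere solution.

## Worked example

Rank four montages over a three-phantom population at the coarse 4 mm
exploration grid:

```sh
tdcsphere optimize --out demo --resolution 4 --seed 3 --quiet --config cfg.yaml
```

with `cfg.yaml`:

```yaml
n_models: 3
thickness_cv: 0.08
size_cv: 0.04
h_mm: 4.0
montages: ["FCz-POz", "Fz-Pz", "Cz-Extracephalic", "Cz-POz"]
```

prints

```
 rank          montage  average_mean  average_sd
    1            Fz-Pz      1.039923    0.020961
    2           Cz-POz      1.002945    0.019173
    3          FCz-POz      1.001765    0.025555
    4 Cz-Extracephalic      0.766629    0.015013
```

`average_mean` is the population mean (n = 3) of the four-ROI average |E|
in V/m at 2 mA; `average_sd` the across-model SD. The two montages that
straddle the vertex symmetrically (Fz–Pz, FCz–POz) deliver ~1 V/m to the
M1/SMA targets on these phantoms and clearly beat the conventional
electrode-above-target choice with an extracephalic return. On smooth
spheres the Fz–Pz/FCz–POz ordering is nearly tied (≈4% apart); which of the
two wins on a given head is an anatomy-level detail, which is exactly why
per-model optimum counts and conductivity sensitivity are part of the
pipeline. A single montage on a single phantom, with φ and |E| NIfTI
volumes, a cortical-surface CSV and ROI means:

```sh
tdcsphere simulate --out sim --resolution 4 --montage FCz-POz
cat sim/roi_means.csv
#   roi,mean_EF_V_per_m
#   M1_left,1.11036
#   M1_right,1.11036
#   SMA_left,0.840119
#   SMA_right,0.840119
```

Bilateral means agree to machine precision because both the phantom and the
surface sampling lattice are mirror-symmetric. `tdcsphere validate
--resolution 2` solves the 4-layer verification sphere with point
electrodes and compares against the Legendre-series oracle;
`tdcsphere sensitivity` repeats the optimization under perturbed bone/CSF
conductivities.

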