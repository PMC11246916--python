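# Methods

## Physical model

Stimulation currents at DC are quasi-static: the potential φ obeys
∇·(σ∇φ) = −i in the head volume with homogeneous Neumann boundary
conditions (no current crosses the scalp–air boundary except through the
electrodes), where σ is the isotropic tissue conductivity in S/m and i the
volumetric source density in A/m³. The stimulation field is E = −∇φ; its
magnitude |E| on the cortical surface is the quantity of interest.

Conductivities (S/m): gray matter 0.2, white matter 0.14, blood 0.7,
compact bone 0.008, spongy bone 0.027, dura 0.16, CSF 1.8, muscle 0.16,
skin and subcutaneous fat (one label) 0.08, eye 1.5, saline-soaked sponge
1.6. The rubber current-feed sheet has no standard published value; the
default is 0.1 S/m, and because the source is injected volumetrically and
uniformly over the sheet, its conductivity has no leading-order effect on
the tissue field (a 10× change moves cortical ROI means by ~0.5%, far
below the discretization error; it only redistributes current within the
sponge — verified by a sensitivity test). All values are overridable per
tissue.

## Electrodes and montages

Each electrode is a 7 cm × 5 cm (35 cm²) sponge, 5 mm thick below and above
a rubber sheet, conforming to the scalp: its footprint is bounded in
scalp-arc coordinates around the site (±2.5 cm along the midline arc,
±3.5 cm laterally, long edge perpendicular to the posterior–anterior
direction). The rubber sheet is nominally 1 mm thick; on grids with h > 1 mm
it occupies one voxel layer at mid-sponge depth — the injected current is
spread uniformly over the rubber voxels with the anode/cathode totals
enforced to ±I exactly, so sheet-thickness quantization does not change the
injected current.

Midline 10-10 sites sit at fixed fractions of the nasion–inion arc (Fpz
10%, Fz 30%, FCz 40%, Cz 50%, CPz 60%, Pz 70%, POz 80%, Oz 90%, Iz 100%);
on a sphere the arc is the anterior–posterior great circle and Cz is the
vertex. The "extracephalic" return — physically off the head, exact
location unspecified in practice — is modelled as a patch antipodal to Cz
on the inferior surface; for midline cortical targets its precise position
is immaterial, and it is configurable.

Candidate montages cross first-electrode sites {Fz, FCz, Cz, CPz, Pz} with
second-electrode sites {extracephalic, Iz, Fpz, POz, Pz}; POz additionally
appears as a first electrode with Fpz, matching the published candidate
table (which lists POz–Fpz but no POz–extracephalic; the generating rule
stated alongside that table does not produce POz–Fpz — the enumeration here
follows the table and surfaces the discrepancy rather than resolving it).
Pairs whose 5 cm footprints would overlap on the scalp (center-to-center
arc distance < 5 cm) and same-site pairs are excluded; for any plausible
head (midline arc between 25 and 50 cm) exactly the adjacent-site pairs
overlap, leaving 23 montages. Montage order is (anode, cathode): swapping
reverses the current direction (anterior→posterior vs posterior→anterior)
and negates E everywhere, leaving |E| unchanged — the two polarities of a
pair are one montage for optimization purposes.

## Discretization and solver

The FEM uses first-order (trilinear) shape functions on the cubical voxels
themselves; the element stiffness is σ_e·h·K̂ with K̂ the exact 8×8
reference matrix of the unit cube (2×2×2 Gauss quadrature). Element
conductivities come from the voxel tissue label, with one refinement: the
sphere voxelizer also records, for voxels straddling a shell interface, the
tissue volume fractions from a 4³ subsampling of the continuous geometry,
and the assembler uses the volume-weighted conductivity for those elements.
This partial-volume treatment matters on coarse grids — a 3 mm CSF shell
quantizes to 1–2 voxels at h = 2 mm, and with pure label-per-voxel
conductivities the |E| verification error on the gray-matter shell is 11.9%
(relative L2 vs the analytic oracle) versus 6.9% with fractions. Externally
supplied label volumes carry no fraction data and fall back to plain
label-per-voxel conductivity.

The assembled system is symmetric positive semi-definite with the constant
vector as nullspace (pure Neumann problem). It is solved by
Jacobi-preconditioned conjugate gradients with the constant mode projected
out of each preconditioned residual; convergence is declared at relative
residual 1e-6 (default; maximum 10 000 iterations, failure raises with the
residual history). The returned potential is zero-mean over the conducting
domain. Solutions are linear in the injected current and scale as 1/k under
a global conductivity scaling σ → kσ; both identities hold to solver
tolerance and are tested.

E is evaluated at element centers from the trilinear gradient (difference
of opposite-face averages over h). Cortical samples interpolate the three
components trilinearly from element centers and then take the norm
(component-then-norm convention); the interpolated magnitude therefore
never exceeds the largest |E| among the surrounding elements.

**Current conservation.** The discrete flux out of any closed node box is
the sum of (Aφ) over the enclosed nodes (discrete divergence theorem); for
a box enclosing one electrode it must equal ±I. At tol 1e-6 the relative
flux error is ~1e-8 at h = 4 mm; at tol 1e-2 it degrades accordingly, which
makes the check a useful convergence diagnostic.

**Grid sizes and runtimes** (one CPU): the default working resolution is
h = 2 mm (~4·10⁵ conducting voxels for a 92 mm head, ~1 min per solve);
exploratory runs and most tests use h = 4 mm (~5·10⁴ voxels, ~3 s per
solve). The 0.5 mm resolution of high-fidelity anatomical modelling is
configurable but needs ~2.5·10⁷ voxels and correspondingly more memory and
time.

## Analytic oracle

For an N-layer concentric sphere with two surface point electrodes ±I, the
potential separates into a Legendre series; in layer j the degree-l radial
part is A_j r^l + B_j r^-(l+1), with coefficients fixed by regularity at
the center, continuity of φ and σ∂φ/∂r at each interface, and the
point-source Neumann datum at the outer surface — a (2N−1)-dimensional
linear system per degree, solved with per-layer rescaled radial bases that
stay O(1) inside their layer (well-conditioned to truncation orders of
several hundred). The l = 0 mode is gauge and cancels between source and
sink. The series (default L = 200) carries a tail-convergence check and is
verified to 1e-6 against the independent closed form for the homogeneous
sphere, φ = I/(4πσR)[2/d̂ + ln(2/(1 − xμ + d̂))] with x = r/R and
d̂ = (1 − 2xμ + x²)^½, including the degenerate two-layer case with equal
conductivities (property-based test).

The FEM comparison voxelizes the default 4-layer geometry (brain 80, CSF
83, skull 87, scalp 92 mm; σ = 0.2, 1.8, 0.008, 0.08 S/m), injects ±2 mA
in the single non-air voxels nearest the electrode poles, and measures
relative L2/max errors of φ (gauge-aligned) and |E| on the sphere 1 mm
below the brain surface, excluding 10° caps around the electrodes; the
oracle field is differenced centrally at 0.2 mm. Point electrodes are used
because sponge patches have no convenient closed form. Measured errors:
|E| 16.4% at h = 4 mm, 6.9% at h = 2 mm (φ: 9.4% and 4.9%) — first-order
convergence dominated by interface staircase, as expected for a voxel
discretization.

## Cortical sampling and ROIs

|E| is sampled on the sphere 1 mm below the outer gray-matter radius at
10 000 quasi-uniform points (configurable). The lattice is a golden-angle
spiral wound about the left–right axis, built on one hemisphere and
mirrored, so it is *exactly* symmetric about the midsagittal plane.
Phantoms of a population share this angular parametrization, which makes
cross-model correspondence the identity on angles — the declared surrogate
for the surface registration step used with real cortices. Exact mirror
symmetry is a deliberate design choice: left/right ROI point sets are
mirror images, so bilateral means of a symmetric field agree to solver
precision instead of to ROI-quadrature noise (~40 points per ROI, which
would otherwise contribute percent-level spurious asymmetry).

ROI centers are given in template-space mm (M1 [±9, −39, 54], SMA
[±3, −9, 60]; the coordinate space is treated as MNI-style: x right,
y anterior, z superior, origin at the anterior commissure). The declared
template→phantom mapping re-centers by the template brain centroid
(0, −17, 9) mm, scales isotropically (template cortical extent 90 mm onto
the phantom gray-matter sphere), and projects radially onto the sampling
surface; because the projection is radial, only the re-centering affects
ROI placement. ROI membership is geodesic (≤ 10 mm on the sampling
surface); at this radius the geodesic/Euclidean difference is negligible
but the convention is fixed. ROI means are arithmetic means of per-point
|E|.

## Phantoms and populations

Default head: outer radius 92 mm with shells skin/fat 6, compact bone 4
(optionally 1/2/1 compact–spongy–compact), dura 1.5, CSF 3, gray matter
4 mm, white-matter core — anatomically plausible layer values; a real
anatomy provides far more geometric detail (gyri, skull thickness maps,
foramina), which is exactly what the phantom does not capture. Blood,
muscle, fat and eye compartments exist in the conductivity table; an
extended-phantom option adds a muscle split of the lower scalp and two eye
spheres, but the default phantom omits them since they barely affect
midline-montage ranking.

Populations jitter each shell thickness by independent truncated-normal
multipliers (CV 0.08) and the whole head by a size factor (CV 0.04),
resampling a draw (up to 100 times, then erroring) if it would thin a
layer below half a voxel — unless the base layer is already that thin, as
dura is at h = 4 mm. The CV defaults are in the range of reported
inter-individual variability of skull/CSF thickness (~10–20%) and head
size (~4%); they are a modelling choice, not fitted to any dataset. The
variation model is geometric only: real anatomical variability also moves
tissue composition and cortical folding, so across-model SDs here
understate biological spread.

Voxelization labels each voxel by the shell containing its center on a
grid symmetric about the sphere center; layers thinner than 2h warn (they
cannot be resolved as contiguous shells; their average radial extent is
still represented, and the partial-volume fractions carry the sub-voxel
information) and `strict=True` turns the warning into an error. Voxelized
shell volumes converge to the analytic values (max relative error 25% at
h = 4, 1.4% at h = 2, 0.5% at h = 1 mm).

## Optimization and sensitivity

For each montage and model: place electrodes → solve → element fields →
surface samples → four ROI means and their unweighted average (per-ROI
weighting is exposed in code but off by default). Population statistics
are mean and SD (ddof = 0, so a single-model population reports SD 0) per
ROI and for the average; montages are ranked by the population mean of the
four-ROI average, ties broken by candidate order and flagged. Per-model
optima use the same objective (the natural reading of "averaged over all
regions of interest"; flagged as a convention). Results are cached keyed
by (model content hash, montage, current, conductivity table, sampling
settings) so sensitivity scenarios only re-solve what changed.

Sensitivity scenarios perturb one parameter group at a time: bone ×0.5 and
×1.5 (applied jointly to compact and spongy bone — both are bone labels),
CSF ×0.9 and ×1.1, plus baseline; a 3×3 cross of bone and CSF factors can
be configured but one-at-a-time is the default since there is no stated
interaction structure to emulate. Each scenario yields a full ranked table
and the set of scenario winners summarizes robustness.

## What phantom results do and do not show

Passing tests demonstrate the correctness of the machinery: the solver
agrees with an independent analytic solution and conserves current; the
pipeline respects the linearity, polarity and scaling laws of
electrostatics; bilateral symmetry, population statistics, determinism and
the enumeration/exclusion logic behave exactly as specified. Phantom
field *values* (~1 V/m at the M1/SMA ROIs for vertex-straddling montages
at 2 mA) are in the physiological ballpark but systematically higher than
real-head values, because smooth spheres lack sulcal CSF shunting and
realistic skull geometry, and the near-tie between Fz–Pz and FCz–POz on a
sphere (≈4%) is resolved by individual anatomy, not by the phantom.
Montage *rankings* on phantoms therefore validate the optimization
procedure, not any clinical electrode recommendation.

## Numerical conventions and edge cases

* Units: mm for geometry, S/m for conductivity, mA for current at the
  interface (A and V internally); |E| reported in V/m.
* Zero injected current is valid (sham mode) and short-circuits to the
  zero potential.
* Degenerate ROI radius 0 returns the single nearest surface point.
* The gauge is zero-mean potential; comparisons between solutions align
  gauges before differencing, and E is gauge-invariant.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns of any seeded pipeline are
  bit-stable, and output tables are written with 6-significant-digit
  formatting to make that checkable at file level.
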