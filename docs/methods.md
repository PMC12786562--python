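# Methods

`ossicrimp` models the mechanical coupling between a stapes-prosthesis loop
and the long (lenticular) process of the incus during crimping. It answers
two questions: what interface pressure does a given loop geometry, material
and crimping force put on the bone, and does the resulting stress stay below
the strength of cortical bone (the standard proxy for the risk of incus
erosion and necrosis).

## 1. Analytical split-ring model

The loop is idealised as a thin elastic ring of inner diameter ID, outer
diameter OD (wall thickness t = (OD − ID)/2, mean radius r_m = (ID + OD)/4)
shrunk onto a rigid cylinder with radial interference Δr. The average
interface pressure of the *closed* ring follows the thin-ring (Lamé) form

    p = E Δr / ( r_m ( r_m / t + ν ) ).

A crimping loop is split: it covers only an arc θ (degrees) of the bone
circumference so that it can be slipped over the process. Opening the ring
removes circumferential stiffness approximately in proportion to the
missing arc, so the transmitted pressure is reduced by the covered
fraction:

    p_loop = p · θ/360,        Lc = (θ/360)·2π·r_i,   A_c = w·Lc,   F = p·A_c.

The inverse relations p = F/A_c and F = p·A_c convert between a clamp force
and the equivalent mean pressure (units mm–MPa–N, so 1 MPa × 1 mm² = 1 N).

Two modelling choices deserve comment:

* **Direction of the compliance correction.** A split ring is *less* stiff
  than a closed one, so the correction must reduce the pressure; we use the
  covered-arc fraction θ/360 (identity at θ = 360°). The reciprocal form
  2π/θ describes the closed-to-open *stiffness ratio*, not a pressure
  multiplier.
* **The coverage angle θ is not directly observable** on a crimped loop.
  The default θ = 216° (fraction 0.6) is calibrated so that the model
  reproduces the three published PTFE loop pressures
  (0.405 / 0.476 / 0.524 MPa for OD 1.2 / 1.4 / 1.8 mm at Δr = 2 µm,
  E = 0.5 GPa, ν = 0.46) simultaneously at three-decimal rounding. θ is an
  explicit parameter of `RingSpec` and can be set per configuration.

## 2. Geometry and meshing

The lenticular process is a cortical-bone cylinder (diameter 0.8 mm; length
3.0 mm by default, chosen so the published 1.3 mm crimp offset from the tip
is comfortably interior — the length itself is not a published quantity and
is exposed as a parameter). The loop is an annular band (bore = incus
radius − interference, width w, radial wall t) covering the arc θ, with a
prismatic stem extending radially from the middle of the covered arc; the
stem's far face stands in for the anchored distal end of the piston, and its
length is set so the overall span matches the 3.4 mm functional length. The
stem cross-section is the band width times an arc of the shaft diameter
(0.4 mm) — an idealisation of the cylindrical piston body, whose only
mechanical role here is to anchor the loop.

Meshes are structured: polar cross-sections extruded along the incus axis,
wedges split into tetrahedra with the minimum-global-vertex diagonal rule
(conforming by construction, verified by the shared-face test). Quadratic
10-node tetrahedra are the default — the published node/element ratio is
only consistent with quadratic elements — with midside nodes projected onto
the curved cylindrical surfaces; linear elements and straight-sided variants
are available (the straight-sided mode makes the uniform-stress patch test
exact, which is how it is verified). The axial grid refines near the loop
and coarsens elsewhere (factor 2.5).

Mesh resolutions: the test profile is 0.15 mm (≈6 k nodes, minutes for the
full grid on one CPU), chosen as the coarse end of the 0.10–0.15 mm range
used throughout the test suite; `fine` is 0.10 mm; the `published` profile,
0.05 mm, reproduces the published mesh scale (≈1.2× its 105 k nodes) and is
practical for meshing studies but slow to solve repeatedly. Meshing is fully
deterministic; the seed argument is recorded for provenance only.

## 3. Finite-element contact solver

Small-strain isotropic linear elasticity (bone E = 14 GPa, ν = 0.30;
titanium E = 110 GPa, ν = 0.30; PTFE E = 0.5 GPa, ν = 0.46). Stiffness uses
a degree-2 rule for linear and a degree-4 (Keast 11-point) rule for
quadratic elements; tractions integrate with mid-edge surface quadrature.
The sparse system is solved by direct LU factorisation; a residual check
guards against under-constrained models.

**Contact.** The loop bore and the incus surface are nearly coaxial
cylinders, so contact normals are radial and fixed by the reference
geometry, making every gap a linear function of the displacements
(node-to-surface, two-pass symmetric by default, each pass at half weight;
closest-facet pairing in (φ, z) surface coordinates with smallest-index tie
break). Non-penetration is enforced by an augmented-Lagrangian (Uzawa)
loop: penalty-regularised solves with active-set iteration inside, then
multiplier augmentation until residual penetration falls below
10⁻³ × element size. The penalty is 50 × the softer material's modulus per
local element size. Two stabilisations proved necessary and are worth
recording:

* **Hysteretic active set.** With a stiff penalty the release threshold of
  the classical sign-of-pressure rule (λ/ε, sub-nanometre here) is far
  below the attainable geometric resolution, and the active set thrashes.
  Pairs holding a multiplier therefore stay active within the inner loop;
  release happens when the augmentation projects their multiplier to zero.
* **Augmentation-level friction return mapping.** Coulomb friction
  (μ = 0.25) is carried by tangential multipliers with an elastic
  (stick-spring) regularisation inside the inner loop, anchored at the slip
  state of the previous augmentation; the projection onto the friction cone
  happens only at augmentations. Iteration-level stick–slip switching — and
  equally an explicit slip force tied to the penalty-scale pressure —
  diverges on this geometry because the open ring's radial compliance times
  μ·ε exceeds unity. With the augmentation-level mapping the final
  tractions satisfy |t_t| ≤ μ·p pointwise by construction.

**Kinematics.** The solver is small-strain with fixed contact geometry. The
original study activated large-deformation kinematics; at the micrometre
closures and sub-percent strains of these load cases the geometric update
is negligible for the equivalent-load cases computed here, and the flag is
deliberately not implemented rather than half-implemented (requesting it
raises with an explanation).

**Load cases.**

* *Self-crimping PTFE*: the split-ring pressure for the configuration is
  applied as an inward radial traction on the loop's incus-facing surface
  and transmitted to the bone through contact — the equivalent-load
  representation of elastic recovery. (A literal surface "pressure" on
  that face would act outward, away from the bone; the inward traction is
  the only reading consistent with the procedure it reproduces.) The
  geometric-interference route — meshing the 2 µm overlap and letting the
  contact algorithm resolve it — is also implemented (`interference_fit`
  mode) and serves as the press-fit verification oracle.
* *Titanium crimping*: a total force F (300/400/500 mN) applied as uniform
  inward radial traction over the loop's outer arc, consistent with the
  p = F/A_c averaging of the analytical model. A `pinch` mode concentrates
  the same force on two 30° jaw patches at the arc ends for sensitivity
  studies of the clamp grip; it raises local peaks noticeably, which is the
  main reason absolute peak values are implementation-sensitive (below).
* Boundary conditions in all cases: posterior incus face and stem tip fully
  fixed.

## 4. Safety evaluation

Nodal stresses are recovered per region (averaging never crosses the
bone–implant interface) and reduced to: the peak incus von Mises stress over
the contact neighbourhood (the loop band ± 0.25 mm axially, excluding the
fixed posterior face so constraint artifacts are never reported as peaks);
the area-weighted and plain nodal means over the contact surface (both are
reported because it is ambiguous which one a given post-processor prints);
and the prosthesis-body peak. The dominant stress mode at the peak is
classified from the principal triple (compressive when the most negative
principal dominates the most positive by a factor 2, tensile in the
mirrored case, mixed otherwise). Risk classes: `exceeds_threshold` above
60 MPa, `near_threshold` within 85–100 % of it (stresses of ≈53 MPa are
conventionally described as approaching the limit, hence the 85 % band),
`safe` below.

### Indicative reference peaks

Peak stresses reported by the original ANSYS analyses of these
configurations (up to ≈43 MPa for PTFE; ≈16–24, 31–53 and 57–64 MPa for
titanium at 300/400/500 mN) are carried in the reports as *indicative
references with a ±30 % band*, never as reproduction targets. Two solvers
that agree on resultants can legitimately disagree on local peaks: peak
von Mises values at a band edge are concentration- and discretisation-
dependent, and they respond strongly to how the clamp force is introduced
(uniform arc vs. pinch) and to large-deformation closure of an initially
open loop, which this package deliberately does not model. Under the
equivalent-load cases computed here the incus peaks remain on the scale of
the applied interface pressure (single MPa), far below the reference peaks;
the *trends* — monotone increase with crimping force and with PTFE loop OD,
lower stress for PTFE than titanium across the operating range, all PTFE
and 300 mN titanium cases safely below 60 MPa — are the reproducible
content, and those are what the test suite asserts. The 500 mN threshold
crossing is flagged in reports as sensitivity-dependent for the same
reason.

## 5. Crimping-force window and risk propagation

`max_safe_force` inverts a monotone stress–force response (verified on a
coarse scan, bisection to a force tolerance). The stress–force map used for
risk propagation is the monotone piecewise-linear interpolant through the
computed force levels (full FE per draw is possible but unnecessary for a
linear response). Surgeon crimping forces are modelled as normal
distributions truncated to [0, 1300] mN — non-negative, bounded by the
reported short-term maximum loads of the incudomalleolar joint — with
junior 433 ± 334 mN and senior 182 ± 169 mN presets. The exceedance
probability against the 60 MPa limit is Monte-Carlo with explicit seeds and
a binomial standard error; it is validated against the exact
truncated-normal tail. It is a mechanical-threshold proxy, not a calibrated
clinical risk.

## 6. What the synthetic inputs do and do not show

All inputs are parametric: the geometry generator *is* the data source.
Passing tests therefore demonstrate internal correctness (oracle agreement
with closed-form elasticity and press-fit solutions, force balance,
Coulomb consistency, reproduction of the published analytical table) and
the robustness of the published *directional* findings under an
independent discretisation — not patient-level accuracy. Real lenticular
processes are curved, rough and individually variable; bone is anisotropic
and PTFE viscoelastic; the ossicular suspension is compliant rather than
fixed. All of these are deliberately outside scope, matching the
limitations of the modelling approach itself.

## 7. Numerical defaults

| Parameter | Default | Note |
|---|---|---|
| coverage angle θ | 216° | calibrated to the published pressure table |
| interference Δr | 2 µm | published |
| friction μ | 0.25 | published |
| titanium band radial thickness | 0.1 mm | not published; free parameter of the loop cross-section |
| incus length | 3.0 mm | not published; crimp site interior |
| normal penalty | 50·E_soft/h | h = local element size |
| tangential/normal penalty ratio | 0.5 | |
| penetration tolerance | 10⁻³·h | |
| max augmentations / inner iterations | 8 / 12 | inner loop also exits on relative displacement change ≤ 10⁻⁴ |
| test / fine / published mesh size | 0.15 / 0.10 / 0.05 mm | |
| Monte-Carlo draws | 10⁵ | binomial SE reported |
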