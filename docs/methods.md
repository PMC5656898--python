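# Methods

This note documents the models and algorithms behind `qctviz`: what the
promolecular density emulates, how critical points, gradient paths,
rings and cages are computed, the numerical tolerances involved, and
what the synthetic fixtures do and do not show about real
quantum-chemical densities.

## The promolecular density

The scalar field is a sum of spherical atomic densities,

ρ(r) = Σ_A Σ_i c_i exp(−ζ_i |r − R_A|),

with one term per occupied shell group (1s, 2s2p, 3s3p, 3d, 4s4p) of
each element. Exponents are ζ = 2(Z − s)/n\*, with the screening
constant s and effective quantum number n\* from Slater's screening
rules (the factor 2 converts an orbital exponent into a density
exponent); coefficients are fixed by shell normalization,
4π∫c e^(−ζr) r² dr = n_e, i.e. c = n_e ζ³/8π. The table ships as a
versioned JSON file for H–Kr. For hydrogen this gives the familiar
c = 1/π, ζ = 2. Electron-count normalization is what makes the 0.001 au
envelope convention meaningful on this field.

Gradient and Hessian are closed-form: for a radial term f(d) = c e^(−ζd)
with unit vector u = (r − R)/d,

∇f = f′(d) u,  ∇∇f = f″(d) uuᵀ + (f′(d)/d)(I − uuᵀ).

Like the exact molecular density, this field has a **cusp at every
nucleus**: |∇ρ| tends to a finite non-zero limit there, so the gradient
field is attracted to the nucleus without a smooth stationary point
existing nearby. Nuclear attractors are therefore registered directly at
the nuclear positions as (3,−3) critical points carrying no Hessian
eigen-system; Newton search covers the smooth bond/ring/cage saddles,
where analytic and finite-difference Hessians agree and classification
is well defined. Evaluation of derivatives closer than 1e−10 bohr to a
nucleus raises.

## Critical-point search

Seeds are the off-cusp nuclei (offset 1e−3 bohr), midpoints of nucleus
pairs closer than 8 bohr, centroids of nucleus triples and quadruples of
diameter under 8 bohr, and the overall nuclear centroid (which catches
the central ring/cage CP of compact cyclic systems whose diameter
exceeds the pair cutoff — the S₈ crown is the canonical case). A damped
Newton iteration on ∇ρ with the analytic Hessian (step capped at
0.3 bohr, divergence beyond the system extent + 20 bohr discarded) runs
vectorized over all seeds.

A candidate is accepted when |∇ρ| < 1e−10 au **and** |∇ρ| < 1e−6·ρ. The
relative condition matters: in the exponential far tail |∇ρ| ≈ ζρ, so
sufficiently far from the molecule *any* absolute threshold is met
without a stationary point being present; requiring stationarity
relative to the local density scale rejects this underflow without
introducing a density cutoff.

Duplicates within 1e−3 bohr are merged keeping the smaller |∇ρ|.
Classification uses a degeneracy tolerance of 1e−8 au on Hessian
eigenvalues: rank = #{|λ| > tol}, signature = Σ sign λ. Points with
rank < 3 are labeled degenerate and excluded from interaction-line and
ring assembly.

## Gradient-path tracing

Paths integrate dr/ds = ±∇ρ/|∇ρ| (unit speed in arc length) with
classic fixed-step RK4, base step 0.05 bohr, shrunk to
min(step, 0.3·d) as the distance d to the nearest known CP falls —
so approaches are geometric and cannot overshoot the cusp attractors.
Each step's segment is tested for proximity to every CP; passing within
the snap tolerance (1e−4 bohr) terminates the path with its endpoint
snapped exactly onto the CP. Descending paths additionally terminate
when ρ drops below the floor of 1e−4 au; the terminus is then the
reserved "infinity" sentinel (index −1 in memory,
`terminus="infinity"` in the file format). The floor sits below the
0.001 au envelope convention so basin fans extend past the envelopes. A
step cap of 1e5 turns non-termination into an error. Stored polylines
are decimated by Ramer–Douglas–Peucker at 1e−3 bohr with per-point ρ
retained; ρ is strictly monotone along every stored path.

## Interaction lines, rings, cages

**AILs.** Each bond CP is traced ascending along ±λ₃; the two paths
terminate at nuclear attractors and are paired into an atomic
interaction line. A BCP whose paths do not reach two distinct NACPs is
skipped with a warning.

**Ring surfaces and rings.** The ring paths connecting a ring CP to its
bond CPs are separatrices of the ascending flow: a generic ascending
path from the RCP's λ₂–λ₃ eigenplane climbs to a nuclear attractor, and
the BCP-terminated paths lie exactly between fan neighbours that reach
*different* attractors. Moreover a saddle passage amplifies the
seed-angle offset by a power law, so the closest approach to the BCP
shrinks only polynomially as the bracket tightens and saturates near the
float64 angle resolution. The implementation therefore: (a) seeds a fan
of 64 ascending traces at 0.3 bohr from the RCP in the eigenplane (the
larger seed radius spends the available angle resolution on the
separatrix rather than on the slow escape from the near-degenerate RCP
region); (b) bisects every bracket of distinct terminations, splitting a
bracket whenever a *new* attractor surfaces inside it (a basin sliver
the fan resolution missed — this occurs for the nitrogen basins of
hexamethylenetetramine's chair rings); (c) terminates a trace at a BCP
with a dedicated capture radius of 0.02 bohr, far below interatomic
distances but above the amplification floor; and (d) after a bracket
saturates, accepts the best near-miss within 0.1 bohr of a single BCP,
truncated at closest approach and snapped onto it. A ring is accepted
only if the AILs of the reached BCPs close into a single cycle over the
nuclear attractors — this check is what rejects rings around the
spurious shallow RCPs discussed below.

**Cages.** A cage CP is a local minimum of ρ, so no descending path
leaves it (and in highly symmetric cages its Hessian is nearly
isotropic, leaving no preferred eigendirections). Cage membership is
instead established from the ring side: each ring CP is traced
descending along ±λ₁ (its single negative eigendirection); the CCP such
a trace reaches owns that ring. A cage must collect at least two rings.

**Basins, interatomic surfaces, envelopes.** Basin fans trace 162
icosahedral descending directions per attractor, truncated at the
density floor. An interatomic surface seeds 36 angular × 8 radial
(ε·2^k, ε = 1e−3 bohr) descending traces in the bond CP's λ₁–λ₂
eigenplane, and builds a triangle-strip mesh over matched arc-length
samples of the innermost-seeded path per angle around a central BCP
vertex. Envelopes bisect, per direction of a level-3 icosphere (642
vertices), the outermost radius where ρ equals the isovalue (default
0.001 au, relative tolerance 1e−8); the mesh inherits the icosphere
connectivity and is watertight with Euler characteristic 2.

The molecular graph, rings and cages are generated by default; basin
fans, interatomic surfaces and envelopes are opt-in, since they
dominate run time and most molecular-graph figures do not use them.

## What the fixtures show — and what they do not

The bundled geometries are idealized symmetric constructions (benzene
D6h with C–C 1.3915 Å / C–H 1.08 Å; a planar C5h (HF)₅ ring with F–H
0.93 Å and H…F 1.80 Å; a D4d S₈ crown with S–S 2.05 Å and 108° angles;
an adamantane-like Td hexamethylenetetramine with C–N 1.47 Å; linear
HCN and HFH⁻; a centrosymmetric acetic-acid dimer; H₂ at 0.74 Å). On
the promolecular field these reproduce the structure counts a DFT
density gives for the same systems: 12 benzene basins, one aromatic
ring of 6 C–C interaction lines, 10 (HF)₅ interaction lines splitting
5/5 under the van der Waals bonded/non-bonded criterion (bonded iff the
internuclear distance is below 0.6×(vdW_A + vdW_B)), and 4 rings + 1
cage for hexamethylenetetramine.

Promolecular superposition also produces genuine *extra* shallow
features that a relaxed molecular density need not share: four
RCP+CCP pairs along hexamethylenetetramine's anti-nitrogen C3 axes
(ρ ≈ 5e−3 au) and one extra BCP+RCP pair in the acetic dimer. These
keep the Poincaré–Hopf residual at 1 and are correctly rejected from
ring/cage assembly by cycle closure and the two-ring cage minimum — but
they are a real difference between the stand-in field and an ab initio
density, and census counts beyond the attractors should not be read as
predictions for real molecules. Passing tests demonstrate the
correctness of the topology machinery on an analytic field, not the
chemistry of any particular density functional.

## Scene construction

Nuclear-attractor spheres are scaled to 0.25× the element's Bondi van
der Waals radius; all other CP spheres are 0.25 bohr. Interaction-line
tubes (0.1 bohr; non-bonded thinned to 0.25×) are Catmull–Rom-smoothed
cubic Bézier chains sampled at 8 points per segment with exact
endpoints. Materials are Lambert diffuse (intensity 1.0) with a white
Cook–Torrance specular layer (intensity 0.5); element colors follow the
PyMOL palette, bond/ring/cage CPs are red/blue/green (MORPHY- and
AimStudio-style palettes are available as presets), interaction lines
black in uniform mode, degenerate CPs magenta, and surfaces inherit the
element color at transparency 0.6.

The scene frame is the mean CP position with the bounding-sphere radius
r (floored at 1 bohr); the camera sits at center + (0, 0, −4r) looking
at the center (field of view 49.1°); key and fill spotlights are the
camera position rotated ±45° about the vertical axis through the center
and raised by r, with energies 1.0 and 0.5; a rim lamp (energy 0.8)
sits at center + (0, 0, +4r). Rotations are taken about the axis
through the *center*, making the whole setup translation-equivariant.
Render defaults: 1000×1000 px, 8 antialias samples, 6 ray-trace
samples, 16-bit png without compression, sky-blue background. Stereo
pairs rotate the camera ±2° (configurable in (0, 10]) about the
vertical axis, ordered for cross-eyed viewing.

Exports convert bohr to ångström (0.529177210903 Å/bohr) in a
right-handed +y-up frame. Spheres tessellate as 32×16 UV-spheres (482
vertices), curves as open 12-sided tubes with parallel-transport
frames. OBJ ships an MTL with diffuse color and dissolve; PLY is binary
little-endian with per-vertex colors; glTF 2.0 embeds its buffer and
maps the specular intensity to PBR roughness 1 − 0.5·intensity. The
canonical scene JSON serializes every number at 12 significant digits
with sorted keys, so identical scenes are byte-identical — the basis of
all determinism tests. A generated Blender-Python script can rebuild
the scene in that tool; it is emitted as text and never executed here.

## File format

`.top` files are UTF-8 XML validated against the shipped
`Topology.dtd`. Coordinates are bohr (the mandatory `unit` attribute is
rejected for any other value rather than silently converted), indices
are 0-based, and numeric fields carry 12 significant digits, giving
round-trip identity within 1e−9 bohr. The scalar map per point is an
open vocabulary ("rho" is the density); unknown names pass through. A
`simple` read populates only critical points and the molecular graph.
Adapters for external QCT analysis programs are expected to construct a
`Topology` in memory and call `write_topology`; no parsers for their
native outputs are included.

## Known limitations

- The promolecular field is not a self-consistent density: no charge
  transfer, no relaxation, cusped nuclei. Bond-CP ρ values are
  indicative only.
- Ring-path capture is approximate by necessity (see above); captured
  ring paths may end up to 0.02 bohr (worst case 0.1 bohr) off the true
  separatrix before snapping onto the BCP.
- Interatomic-surface meshes are built from the innermost seed ring per
  angle; for strongly curved surfaces the triangle strips are a coarse
  (gap-free but not adaptive) approximation, and the surfaces are open
  disks truncated at the density floor.
- Degenerate CPs are retained and rendered but never used in assembly;
  systems whose chemistry hinges on genuinely degenerate CPs (conical
  density features) are out of scope.
- Scene setup fixes light cone angles and falloff to renderer-typical
  defaults; no claim of pixel-level agreement with any particular
  renderer is made.
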