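# qctviz

A quantum-chemical-topology (QTAIM) toolkit: generate, store and render
the topology of molecular electron-density fields.

Chemists who work with Bader's *Atoms in Molecules* analysis deal with a
zoo of geometric objects derived from the density ρ(r): critical points
where ∇ρ = 0, gradient paths that connect them, the molecular graph of
bond paths, atomic basins, interatomic surfaces and constant-density
envelopes. Standard molecular viewers draw balls and sticks; they have no
vocabulary for these objects. `qctviz` provides that vocabulary as a
typed data model, a validated XML interchange format, and a deterministic
mapping to renderer-agnostic 3D scenes that export to OBJ, PLY and glTF —
so the output of a QCT analysis can be rendered by any modern 3D tool.

Because wavefunction-based densities require external quantum-chemistry
software, the package also ships a **promolecular density engine**: an
analytic field

    ρ(r) = Σ_A Σ_i c_i exp(−ζ_i |r − R_A|)

(one exponential term per occupied shell of each atom A, normalized to
the atomic electron count) with closed-form gradient and Hessian. Its
topology carries the same object zoo as a molecular ab initio density, so
complete, classified topologies can be synthesized from nothing but a
nuclear geometry — and every downstream stage is testable at desk scale.

## The objects

A critical point is classified by the eigenvalues λ₁ ≤ λ₂ ≤ λ₃ of the
Hessian ∇∇ρ at the point: its rank ω (number of non-zero eigenvalues)
and signature σ (sum of their signs). The rank-3 types are the nuclear
attractor (3,−3), bond CP (3,−1), ring CP (3,+1) and cage CP (3,+3);
anything with ω < 3 is degenerate. For an isolated connected system the
census obeys the Poincaré–Hopf relation n − b + r − c = 1, which the
toolkit uses as a completeness audit. An atomic interaction line is the
pair of gradient paths that run from a bond CP to its two nuclear
attractors; the set of all of them is the molecular graph, a
first-principles connectivity of the molecule.

## Worked example

Generate the topology of an idealized D6h benzene
(C–C 1.3915 Å, C–H 1.08 Å) and inspect it:

```
$ qctviz synth benzene -o benzene.top
INFO qctviz: census: 12 NACP, 12 BCP, 1 RCP, 0 CCP, 0 degenerate
INFO qctviz: Poincare-Hopf residual: 1
INFO qctviz: molecular graph: 12 AILs; 1 rings; 0 cages
benzene.top

$ qctviz info benzene.top
NACP: 12
BCP: 12
RCP: 1
CCP: 0
degenerate: 0
poincare_hopf_residual: 1
ails: 12
rings: 1
cages: 0
```

Reading the numbers: every one of the 12 atoms contributes a nuclear
attractor (12 atomic basins); the 6 C–C and 6 C–H bonds each carry a
bond CP whose interaction line is traced into the molecular graph; the
aromatic ring closes into a single ring of 6 C–C interaction lines
around the central ring CP; and 12 − 12 + 1 − 0 = 1 confirms the census
is complete.

From the same file a scene can be produced and exported:

```
$ qctviz scene benzene.top --simple -o benzene_scene.json
$ qctviz export benzene.top -f gltf -o benzene.gltf
```

The scene maps the 25 CPs to spheres (nuclei scaled by van der Waals
radius, bond/ring/cage CPs in red/blue/green), the 24 bond-path branches
to smoothed tubes colored by element, frames the system by the mean CP
position, places the camera at −4r on the view axis with a 45°-offset
three-point lighting rig, and writes 1000×1000, 16-bit render settings —
all deterministic, so identical topologies give byte-identical exports.

The same pipeline runs for any of the bundled fixture geometries
(`h2`, `hcn`, `hfh_anion`, `benzene`, `s8`, `hf_pentamer`,
`acetic_dimer`, `hexamethylenetetramine`) or any XYZ file. The
hydrogen-fluoride pentamer yields 10 interaction lines that the
`--differentiate` flag splits into 5 covalent bonds and 5 hydrogen
bonds; hexamethylenetetramine yields 24 bond paths, 4 six-membered
rings and the single cage they enclose.

## Layout

- `src/qctviz/model.py` — typed topology model and assembly rules
- `src/qctviz/density.py`, `search.py`, `generate.py`, `fixtures.py` —
  promolecular engine: field, CP search, path tracing, pipeline
- `src/qctviz/top_io.py` + `data/Topology.dtd` — the `.top` XML format
- `src/qctviz/scene.py`, `staging.py`, `export.py` — scene mapping,
  camera/lighting, exporters
- `src/qctviz/cli.py` — `qctviz synth | validate | scene | export | info`
- `docs/methods.md` — models, algorithms, tolerances and limitations
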