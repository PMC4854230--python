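# Methods

`flexfit` refines atomic protein models into cryo-EM density maps in the
2.5–4.5 Å regime and assesses the local quality of the fit. This note
documents the models, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Model-derived density

A model map ρ^P is simulated by placing an isotropic Gaussian on every atom,
weighted by its atomic number, with real-space width

    sigma = 0.356 × resolution  (Å).

With this convention the Fourier transform of the kernel falls to half its
peak at spatial frequency 1/resolution, a common operational definition of
"a map at resolution d" for simulated densities. Contributions are
evaluated over a cube of half-width 3 sigma around each atom (≈ 99.2 % of
the Gaussian mass), so a single atom's integrated density matches its
weight times the Gaussian normalization to better than 1 %. Electron
scattering-factor tables are deliberately not used: for correlation-based
scoring at these resolutions only the relative weighting of elements
matters, and atomic numbers are an adequate proxy. When a map is simulated
for scoring or refinement it is sampled on exactly the target map's grid,
so voxel-wise products need no interpolation.

## Scores

**Global CCC** is the mean-subtracted Pearson correlation between two maps
on a shared grid (optionally over a voxel mask). It is invariant to any
positive affine transform of either map.

**SMOC** (segment-based Manders' overlap coefficient) scores a residue
segment over the voxels its atoms occupy:

    SMOC = Σ_i ρ_i^EM ρ_i^P / sqrt(Σ_i (ρ_i^EM)² · Σ_i (ρ_i^P)²),

with i running over all voxels within a cutoff radius of any segment atom.
Because the sums are not mean-subtracted, SMOC is invariant to rescaling of
either map but *not* to additive offsets — the property that makes it
robust when the target map contains density belonging to other components.
"Occupied" is defined by an atom-distance cutoff of
max(2.5 Å, 1.5 × voxel spacing); SMOC values shift with this radius, so it
is exposed as a parameter.

**Profiles.** Every residue inside a helix/strand segment receives that
segment's SMOC. Loop residues are scored over overlapping nine-residue
windows; the window score is assigned to the center residue. Windows are
kept inside the loop run when it is at least nine residues long (shifted
inward at SSE boundaries), otherwise they extend over flanking residues and
shrink only at chain termini, so the profile is total. Window scoring uses
all heavy atoms.

**Z-scores** standardize the per-residue profile with the population
standard deviation (deterministic, and immaterial versus the sample SD at
chain lengths of interest). Maximal runs of at least three consecutive
residues with Z below −1 are flagged as poorly fitting; both the threshold
and the minimum run length are parameters. When stage means are compared
for monotonicity, differences below 1e-4 are treated as ties: once a fit
has converged the stage-to-stage jitter is of order 1e-5 and carries no
information.

## Rigid-body identification

Helices and strands are the clustering units. Two SSEs are in contact when
at least 10 % of their inter-SSE residue pairs have a Cα–Cα distance within
6.5 Å; connected components of this contact graph become rigid bodies. A
loop is absorbed into a body only when both its flanking SSEs belong to the
same cluster; isolated SSEs become singleton bodies; all other residues
stay free. The (6.5 Å, 10 %) operating point is a declared default — both
knobs are exposed, and no cutoff sweep is performed. Strands are treated
individually: strands of one sheet cluster naturally under any reasonable
cutoff. A geometric fallback assigner derives SSEs from backbone dihedral
windows (minimum length 4 for helices, 3 for strands); HELIX/SHEET records
or a TSV annotation override it.

## Restraints

All harmonic terms use the convention **E = k·Δ²** (no ½), so every quoted
force constant has a single unambiguous meaning.

- **Bonds, angles, impropers** are anchored at the values measured in the
  input conformation, with force constants from a small packaged table of
  typical covalent magnitudes (`data/covalent_params.json`, editable):
  bonds ≈ 250–450 kcal/mol/Å² by element pair, angles and impropers
  50 kcal/mol/rad². Impropers comprise the peptide ω dihedral, carbonyl
  planarity and Cα chirality quadruples. Covalent topology is detected by
  distance within residues plus the inter-residue peptide C–N bond; an
  atom in a multi-atom residue with no covalent neighbor is an error.
- **Ramachandran** term: a flat-bottom basin penalty on (φ, ψ) — zero
  inside three generous rectangles (α_R including 3₁₀, β/PPII with the ψ
  interval wrapped through 180°, α_L), harmonic (2 kcal/mol/rad²) in the
  angular distance outside the nearest basin. This approximates a
  statistical torsion potential without shipping one.
- **Non-bonded** term: one-sided lower bound per heavy-atom pair,
  E = 400 kcal/mol/Å² × max(0, bound − d)², with bound = 0.9 × (r_vdW(i) +
  r_vdW(j)). The 0.9 scale accommodates backbone hydrogen-bond contacts
  (helix O(i)–N(i+4) ≈ 2.9–3.0 Å, below the raw radius sum), which are
  genuine geometry and must not be penalized. Pairs within four covalent
  bonds are excluded: 1-5 pairs across the peptide unit (O(i)–C(i+1))
  sit below any reasonable vdW bound in ideal trans geometry.

Analytic gradients of every term are implemented and verified against
central differences in the test suite.

## Objective and optimizer

    total = w_em · (1 − CCC(ρ^EM, ρ^P)) + E_stereo.

The density gradient with respect to atom positions is analytic through the
Gaussian model density:
∂CCC/∂ρ_v = e'_v/√(S_ee S_pp) − CCC·p'_v/S_pp, chained with
∂ρ_v/∂x_a = w_a g(r_v − x_a)(r_v − x_a)/σ².

**Density weight.** `w_em` defaults to 1e4. The density term is
dimensionless and of order one, while covalent force constants are hundreds
of kcal/mol/Å²; with a unit weight, density forces are three to four orders
of magnitude below stereochemical gradients, and rigid-body motion stalls
against the restraints that anchor the linkers. The default puts typical
density forces on the scale of moderate covalent gradients. On the hinge
benchmark this weight recovers the ground truth to ~0.02 Å while the final
stereochemical energy stays below ~1 kcal/mol (geometry is not distorted).
The weight scales with grid size through the CCC normalization, so very
large maps may warrant retuning; it is exposed in `AnnealConfig`.

**Optimizer.** The schedule and the per-step displacement caps are the
specified constraints; the integrator is a design choice. `flexfit` uses
per-degree-of-freedom sign-adaptive capped descent (iRprop−-style step
adaptation: grow ×1.2 on consistent gradient sign up to the cap, halve on a
sign flip, floor at 1e-4 × cap), plus Gaussian exploration noise whose
amplitude is proportional to T/T_max along a piecewise-linear
0 K → 1000 K → 0 K ramp per cycle. Sign-based steps were chosen because the
objective mixes very stiff (covalent) and very soft (density) directions;
magnitude-based steps either stall or oscillate across that conditioning
gap, while sign adaptation traverses it robustly.

Rigid bodies carry six degrees of freedom (translation + rotation about the
body centroid); the rotation gradient is the torque Σ (r−c)×g. After the
Rprop update, body increments are rescaled (iteratively, since rotation
displacement is nonlinear) until no atom moves more than the stage cap
along any axis; free atoms are clipped per axis directly. The per-step
maximum displacement is logged, so cap compliance is auditable from the
trace. Runs are bit-reproducible for a fixed seed.

**Stages.** The hierarchical protocol anneals at cluster level (cap
0.39 Å/step/axis), then per-SSE (0.15 Å), then all-atom (0.1 Å). When the
model yields fewer than two cluster bodies the first stage is skipped and
refinement starts by constraining SSEs. Restraints are re-anchored on each
stage's input (each stage is an independent run, as in the multi-run
protocol the stages mirror). A stage runs up to 5 annealing cycles
(default) and stops early once the cycle-to-cycle CCC gain falls below
1e-4 — the observed plateau criterion. Frozen interface segments, when
given, are carried as extra rigid bodies through every stage including
all-atom, which conserves their internal distances to machine precision.

**Steps per leg.** 200 heating + 200 cooling steps per cycle by default.
The test suite and the acceptance script use 40 + 40 steps and 2 cycles:
on the fixture problems (≤ 70 residues, ≤ 50³ voxel maps) the optimizer
converges well within that budget, and the smaller setting keeps the whole
benchmark battery at desk scale. These problem sizes are the package's
declared study conditions, not a claim about experimental maps.

## Loop-ensemble refinement

Candidate loop conformations are generated by perturbing the loop's φ/ψ
torsions with seeded Gaussian noise (default σ = 30°), rebuilding the
backbone by natural-extension (NeRF) placement with the input's bond
lengths and angles, and restoring the downstream anchor by cyclic
coordinate descent (closure tolerance 0.5 Å on the next residue's N/CA/C;
carbonyl O and Cβ rebuilt from the final backbone). Candidates that bring
any loop atom within 1.8 Å of the non-adjacent remainder are rejected.
Every candidate — plus the input conformation — is scored by SMOC over the
loop's own voxel mask, and the top-scoring conformation is substituted. The
sampler is plumbing; the contribution is the SMOC-ranked selection. With
zero amplitude the input is returned unchanged.

## Synthetic fixtures

The generators build poly-alanine backbones (N, CA, C, O, Cβ) from ideal
internal coordinates via NeRF chain extension. The helix-loop-helix hairpin
uses a fixed six-residue loop torsion set chosen once (by construction
search) so that the two helices pack with ≥ 10 % of Cα pairs within 6.5 Å,
all loop torsions lie inside the Ramachandran basins, and no heavy-atom
pair violates the scaled vdW bound — the ground truth therefore has zero
restraint energy. The two-domain hinge joins two such hairpins with an
extended six-residue linker; the four-helix bundle places ideal helices on
a 7.5 Å square lattice with geometrically approximate connecting arcs
(adequate for contact and scoring tests, not for torsion analysis).
Perturbations (hinge rotation about the linker axis, rigid translation,
tapered loop displacement with endpoint repair) are deterministic per seed
and reject steric collapse (< 1.5 Å non-bonded contact).

RMSDs are reported in the shared map frame by default — fitted models live
in the same coordinate system as the map, so superposition would hide
exactly the error being measured; least-squares superposition is available
explicitly. Per-domain RMSDs are obtained by passing residue-segment
selections.

What passing these benchmarks shows: the scores, the clustering, the
optimizer, the caps, the protocol logic and the selection machinery behave
as specified, with exact oracles wherever one exists. What they do not
show: performance on experimental maps — the fixtures have no noise, no
B-factor heterogeneity, no solvent, no neighboring-component density, and
their perturbations span a far smaller conformational space than homology
models do. Optional additive Gaussian noise is the only experimental
artifact emulated.

## Map I/O conventions

MRC/CCP4 2014 maps are read through gemmi with the header parsed raw: axis
order is normalized to x-fastest, modes 2 (float32) and 1 (int16) are
accepted, and the origin is taken from the ORIGIN record when any component
is nonzero, else NxSTART × spacing. Maps are written in mode 2 with the
origin in the ORIGIN record. B-factor sharpening scales Fourier amplitudes
by exp(−B·s²/4) (crystallographic temperature-factor convention); the s = 0
term is untouched, so the mean is preserved, and B = 0 is the identity.

## Known limitations

- Single-conformer models only; alternate locations are collapsed at parse
  time to the highest-occupancy conformer.
- No nucleic-acid topology, no symmetry restraints, no multi-component
  assembly fitting, no B-factor refinement, no half-map cross-validation.
- Clustering operates within one chain (no quaternary-level bodies).
- The density weight is calibrated for fixture-scale grids (see above).
- The loop sampler's closure can fail for long loops at small n; the error
  suggests raising n or the perturbation amplitude.
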