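# Methods

## Problem setting

Structure predictors cap the number of residues per run (2500 for the
deployments this package targets), so a megaprotein such as the
4018-residue, 452 kDa bridge-like lipid transfer protein LPD-3/BLTP1 must
be predicted piecewise and reassembled. The scientific claims downstream
of such an assembly — an ~30 nm rod, a continuous internal hydrophobic
tunnel wide enough for lipid monomers, a disease/screen mutation that
narrows the tunnel entry, and membrane-anchoring termini — are geometric
and sequence-level statements. megastitch makes each of them a
deterministic, testable computation.

## Fragment planning

Given length L, window length t (default 1500), minimum overlap v
(default 500) and predictor limit (default 2500), the fragment count is
the smallest n with n·t − (n−1)·v ≥ L, i.e. n = ⌈(L−v)/(t−v)⌉. Window
starts are spaced evenly, start_i = 1 + round((i−1)(L−t)/(n−1)) with
round-half-up, so realized overlaps can exceed v (for L = 4018 they are
660/660/661) but never fall below it: consecutive rounded starts differ by
at most ⌈(L−t)/(n−1)⌉ ≤ t−v. Even spacing is a declared convention — the
fragment boundaries actually used for any particular published model are
generally unreported — chosen so the plan is a pure function of
(L, t, v).

## Stitching

Alignment uses Cα atoms only, paired by residue number within the planned
overlap; residue identities must agree letter-for-letter (a mismatch
aborts with the first offending residue named), which guards against
numbering drift between fragment files. The superposition is the
closed-form Kabsch solution via SVD of the 3×3 covariance, with the
determinant correction that excludes reflections; near-collinear point
sets trigger a warning because the rotation about the point axis is then
unidentifiable. The test suite cross-checks this core against an
independently implemented Horn quaternion eigenvalue method (max deviation
< 1e−8 Å RMSD over 1000 random instances).

Fragment 1 anchors the global frame (any other choice differs by one
global rigid motion); fragments are placed left-to-right, each fitted
against the already-assembled model. Each overlap is spliced at one
crossover residue c — `midpoint` (default, c = ⌊(a+b)/2⌋) or
`max_confidence`, which maximizes the weaker of the two fragments' mean
confidences on their contributed sides. A deterministic splice rule
replaces what is, in practice, a manual merge in a graphics program;
manual loop adjustment is deliberately not reproduced. Junctions with
overlap RMSD above 5 Å warn but do not abort. Quality control counts atom
pairs closer than 2 Å that are ≥ 3 residues apart in sequence, using a
k-d tree (near-linear in atom count).

## Axis and tunnel profile

The central axis is the smoothed trace of 50-residue sliding-window Cα
centroids (moving average width 5), resampled at uniform 2 Å arclength.
Sliding centroids cancel helical winding and follow curvature, which a
straight PCA axis would not; a tortuosity (path/end-to-end) above 2
triggers a warning that the chain is not rod-like. Rod length is
deliberately the *straight* extent — max minus min projection of Cα onto
the first principal axis — because "~30 nm long" is an end-to-end
statement; the curved axis arclength is reported alongside.

The radius profile is HOLE-style with fixed centres: at each station the
radius of the largest sphere centred on the axis touching no atom's vdW
surface (C 1.70, N 1.55, O 1.52, S 1.80 Å, others 1.70). No Monte-Carlo
centre optimization is attempted; the profile is therefore a deterministic
lower bound on the true pore radius — adequate for a wide lipid conduit,
conservative for narrow channels. Stations whose raw radius is negative
(axis inside an atom) are clamped to 0 and flagged. Lining residues are
those owning an atom within radius + 3 Å of the station; their mean
Kyte–Doolittle hydropathy quantifies "hydrophobic tunnel".

"Continuous hydrophobic tunnel" is operationalized as: radius ≥ probe
(1.4 Å, water-sized; configurable) at every interior station, with the
first and last 5% of arclength excluded because tunnel mouths have no
enclosing wall, plus mean lining hydropathy > 0. This is the package's own
quantitative definition of an otherwise visual claim.

## Mutation blockage

A substitution X→Y at residue k is modelled by replacing the side chain
with a single sphere 2.4 Å from Cα along the Cα→Cβ direction (for
glycine, a Cβ direction is constructed from N, Cα, C with ideal
tetrahedral geometry). Sphere radii are volume-equivalent radii of the
side chain from Chothia packing volumes plus a 0.45 Å contact envelope
(Glu 3.10 Å; Gly fixed at 1.00 Å, a lone hydrogen). Both the before state
(X sphere) and after state (Y sphere) use the same construction, so the
identity substitution is exactly Δradius ≡ 0, and Δradius isolates the
side-chain volume change from any placement convention. Radii are
recomputed at stations within 15 Å arclength of the residue. Single-sphere
side chains ignore rotamers; the numbers are screening-level, not
energetic.

## Sequence features

Hydropathy: Kyte–Doolittle scale, window 19, no end padding; 'X' counts 0
and is flagged. TM segments: maximal runs ≥ 1.6 of length ≥ 15 — the
classical Kyte–Doolittle operating point, used here because "putatively
hydrophobic transmembrane helix" comes with no stated criterion.
Amphiphilic patches: Eisenberg hydrophobic moment
μ = |Σ_i h_i (cos iδ, sin iδ)|/n at δ = 100°/residue over 18-residue
windows, reported as the top-moment windows of the scanned region.
Polybasic: all overlapping K-x-K-K matches (x = any residue), 1-based.
Molecular weight: average residue masses + one water (via Biopython's
standard table). The bundled LPD-3 preset confines the TM scan to
a.a. 1–72 and the moment scan to a.a. 3945–4018, the experimentally
delimited terminal reporter regions, and pins the G200E scan; the
sequence and model files themselves are user-supplied.

## Synthetic benchmark generator

`make_tube` places n Cα atoms on a helix about a straight z-axis of the
requested length, with the winding auto-chosen as the minimal integer turn
count keeping consecutive Cα spacing ≥ 3.8 Å (the physical virtual-bond
length); each residue carries one pseudo-Cβ carbon sphere, alternating
lumen-facing (centre at `inner_wall_radius`, identity from Ile/Leu/Val)
and outward-facing (Asp/Glu/Lys/Arg). The true lumen radius is
inner_wall_radius − 1.70 Å by construction, and the true axis is recorded.
Defaults (900 residues, 300 Å, 6 Å lumen → wall atoms at 7.7 Å) make a
1:10-scale analogue of the 30 nm rod with a lipid-acyl-scale conduit.

`fragment_and_perturb` cuts a model by a fragment plan, applies an
independent uniform random rotation and ±100 Å translation per fragment,
adds iid Gaussian coordinate noise σ, and ramps confidence linearly from
90 to 50 over each fragment's terminal 50 residues — mimicking the pLDDT
decay at artificial termini that motivates overlapping fragments (the
linear shape is an invention). One master seed streams all randomness, and
the standard-normal draws are consumed identically at every σ, so noise
levels are *paired*: junction RMSD is monotone in σ per seed, not just in
expectation.

What the generator does **not** emulate: real β-sheet wall geometry,
sequence-dependent predictor error, correlated (domain-level) deviations
between fragments, missing residues. Passing tests therefore demonstrate
correctness of the assembly/profiling machinery under rigid-plus-iid-noise
perturbations, not predictor-grade realism.

Closed-form check used in tests: two copies of the same atoms carrying
independent N(0, σ²) noise per coordinate differ by variance 2σ² per
coordinate, so their pairwise 3-D RMSD is σ√6 (≈ 1.22 Å at σ = 0.5),
slightly reduced by the 6 degrees of freedom a superposition absorbs.

## Numerical and degenerate-input choices

- 1-based inclusive residue intervals everywhere, matching mutation and
  reporter notation (G200E, a.a. 1–72).
- Confidence clamped to [0, 100] on read with a warning; altloc resolved
  to highest occupancy; insertion codes rejected (predictor outputs never
  carry them); first model of multi-model files taken with a warning.
- PDB chain ids longer than one character are an explicit error on PDB
  write (mmCIF accepts them); coordinates round-trip at the 3-decimal
  precision both formats carry.
- Superposition requires ≥ 3 paired atoms; axis estimation requires ≥ 2
  windows of residues; empty models and empty sequences are errors, not
  silent no-ops.
- Problem sizes in the test and acceptance runs (900-residue tubes, 3
  fragments, 10–30 seeds, 1000 oracle instances) were chosen as the
  smallest sizes at which the geometry is unambiguous; the whole suite
  runs in seconds.

## Known limitations

Rigid-body stitching cannot fix incompatible fragment conformations (it
only reports the junction RMSD); the fixed-centre radius profile
underestimates off-axis pockets and branched channels; TM/amphiphilic
calling is scale- and threshold-based, not an HMM topology predictor; the
mutation model is steric only (no electrostatics, no relaxation).
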