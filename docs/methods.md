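# Methods

`rbldesign` implements a geometry engine for designing tandem helical
repeat proteins whose long inter-helix loops are rigidified
("buttressed") by backbone and sidechain hydrogen bonds and by packing
against the underlying helices. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
test structures do and do not demonstrate.

## Parametric repeat backbones

A repeat unit is two ideal α-helices (φ = −57°, ψ = −47°, ω = 180°,
Engh–Huber bond lengths and angles: N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å). Helix H1 is built with its axis on z
(N-terminus at z = 0), displaced by a radius along x and rotated about
z by an orientation angle; H2 is a second ideal helix placed by a
six-degree-of-freedom rigid transform (translation in Å plus intrinsic
z–y–x Euler angles in degrees). The unit is propagated by a second
six-DOF transform applied k−1 times, so unit k is *exactly* the
(k−1)-th power of the repeat transform applied to unit 1 (verified to
1e-9 Å). Helix lengths are restricted to 12–28 residues when sampling
repeat architectures.

Two scaffold-level filters gate everything downstream:

- **Termini distance ≤ 18 Å** — the gap a long buttressed loop must
  bridge, measured from the C atom of helix 2's C-terminal residue of
  unit k to the N atom of helix 1's N-terminal residue of unit k+1.
- **Buried-core fraction ≥ 28%** — a residue is "core" when at least
  18 other residues' CB atoms lie within 10 Å of its CB *and* within
  100° of its CA→CB direction (angle at CA). The wide angular limit
  mirrors sidechain-neighbor burial measures, whose soft angular
  falloff extends far past the sidechain hemisphere; a literal narrow
  cone (50° half-angle) can hold at most ~5–6 neighbors even in a
  dense protein core and would make a count threshold of 18
  unsatisfiable. All thresholds are exposed in `PipelineConfig`.

Short (3–6 residue) loops connecting H1→H2 within a unit are closed
with the same pivot-torsion engine used for long loops. The loop is
built once on the first unit and propagated by the repeat transform so
the backbone stays exactly repeat-symmetric; among clash-free
closures, the conformation that hydrogen-bond-satisfies the most
flanking polar atoms (helix C-terminal carbonyls, loop backbone, next
helix's amide groups) is kept — a backbone-level stand-in for helix
capping.

## Long-loop construction

Extended loop fragments are assembled from three parts, all with
ω fixed at 180° and ideal bond geometry:

- a **helix-capping motif** (4 residues) at the loop's N-terminal end,
- a **β-turn motif** (4 residues) at a uniformly sampled interior slot,
- **free residues** (5–10) whose φ/ψ are drawn by inverse-CDF sampling
  from a 10°×10° binned Ramachandran density (a Gaussian mixture over
  the α, β, polyproline-II and left-handed-α basins with a 5% flat
  floor, generated at import — no external data file).

The fragment's first two residues coincide with the helix C-terminal
two residues and its last two with the next helix's N-terminal two
(the closure anchor region), so the net inserted loop has
n_free + 4 = 9–14 residues. Shorter loops carry too little structural
diversity; longer ones are too hard to buttress.

**Closure.** The chain is grown from the upstream anchor by NeRF
(natural-extension reference frame, numba-compiled) and the six pivot
torsions — φ/ψ of the first, middle and last loop residues — are
solved by damped least squares (Levenberg–Marquardt) so the implied
next-residue N and CA coincide with the downstream anchor. Multiple
deterministic restarts (perturbed pivot starts, σ = 40°) recover
multiple closure branches. A solution is accepted when the seam C–N
bond is within 0.08 Å of 1.329 Å and the flanking bond angles within
2° of ideal. On excision/reclosure tests the engine recovers the
original loop exactly when started from its own torsions and closes
≥95% of trials from randomized pivots.

**Loop filters** (applied after propagating the loop to every unit):

| filter | default | meaning |
|---|---|---|
| intraloop H-bonds | ≥ 2 per loop | backbone–backbone, Kabsch–Sander |
| interloop H-bonds | ≥ 1 per neighbor pair | sequence-independent buttressing |
| consecutive helical residues | ≤ 5 | avoid helical loops |
| direction score | 45–135° | loop arches over the scaffold |
| proximity | ≥ 5 residues within 8 Å of a helix Cα | loop–helix contact |
| motif score | < 0 | hydrophobic-contact propensity |
| steric clash | none | heavy-atom pairs ≥3 bonds apart, 0.6 × Bondi radii |

The direction score is the angle between **a** (from the center of
mass of the two loop terminal residues to the farthest loop Cα) and
**b** (from the same origin to the repeat unit's center of mass).
"Farthest" is measured from the vector origin, and **b** uses the
loop's own unit by default (a `frame="protein"` switch uses the whole
model) — both conventions the definition leaves open.

The motif score sums a CB–CB distance-bin log-odds value over
loop–helix residue pairs within 8 Å. The shipped table is a
**synthetic** surrogate profile encoding the canonical hydrophobic
contact-distance preference (favorable 3.5–8 Å, peak 4.5–5.5 Å,
penalty below van der Waals approach); an attempt to derive the table
from the package's own bundle fixtures produced no signal because an
idealized bundle's core and non-core pair-distance distributions
coincide. The sign convention and the "total < 0" selection rule are
unchanged, but absolute values are not comparable to database-mined
scores.

## Hydrogen bonds

- **Backbone–backbone:** Kabsch–Sander electrostatic energy
  E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond
  reported at E < −0.5 kcal/mol. Amide hydrogens are always rebuilt
  (1.01 Å from N, in the peptide plane, anti to the bisector of the
  N→C(prev) and N→CA directions); prolines, chain starts and
  post-break residues get none.
- **Sidechain–backbone:** geometric rule — donor–acceptor < 3.5 Å and
  D–H⋯A angle > 120°, with donors/acceptors enumerated per residue
  type (Asn ND2/OD1, Asp OD1/OD2, Gln NE2/OE1, His ND1/NE2 as either,
  tautomers not modeled). An orientation-dependent energy model is
  deliberately out of scope.
- **Pseudo-hydrogen bond** (used only as the rescue precondition):
  donor–acceptor < 3.0 Å and angle > 120°, the angle read as D–H⋯A.
  Note that under the geometric sidechain rule every pseudo-bond is
  already a detected bond; the rescue stage therefore acts as a
  geometry polisher rather than a qualitative converter, a direct
  consequence of substituting a geometric criterion for an energy one.
- **Secondary structure:** a residue is H when it lies in an i→i+4
  turn (positions i+1..i+4 of any such bond), E when it partners in an
  antiparallel or parallel bridge pattern, else L. This minimal
  assigner agrees with a full Kabsch–Sander re-implementation on every
  labeled position of ideal helices and the hairpin fixture; bridges,
  π-helices and bends are not modeled.

A **bidentate** interaction is ≥2 sidechain–backbone bonds from one
sidechain functional group onto the backbone of a single neighboring
repeat unit (units k±1), or — in loop–helix mode — onto a single
helix, the residue's own unit included.

## Buttressing scans

Each long-loop position is scanned with Asn/Asp/Gln/His (never
Arg/Lys, whose entropic cost defeats the purpose) over a compact
backbone-independent chi table (packaged YAML); sidechains are built
on ideal internal geometry. A placement is kept only if it forms a
bidentate pair; otherwise the position reverts to Ala. Because a
coarse rotamer table almost never lands two simultaneous hydrogen
bonds on a rigid backbone, the scan falls back to chi refinement: the
most promising rotamer (nearest feasible donor/acceptor pair, with an
option to aim only at specified target atoms) is optimized by
Nelder–Mead over its chi angles against the two bond distances
(target 2.9 Å heavy-atom, hinge-loss angle term below 155°) under a
soft quadratic steric penalty. Short-loop positions are scanned the
same way in loop–helix mode (helix capping). Among accepted rotamers
the one whose bonds leave the fewest functional-group atoms
unsatisfied wins.

Near-miss placements (≥2 pseudo-bonds to one neighbor unit) are
refined by coordinate-wise chi grids (±30° in 2° steps, two sweeps)
plus a simplex polish minimizing the harmonic restraint
Σ((d − 2.0 Å)/0.5 Å)² over the pseudo-pair donor–acceptor distances,
never accepting an objective increase; the result is kept only if the
bidentate check passes. Hydrophobic positions are scanned with
Val/Leu/Ile/Met/Phe and accepted at ≥4 sidechain heavy atoms within
4.5 Å of helix heavy atoms without clash.

Accepted placements are copied to the equivalent position of every
unit (same amino acid and chis; the exact repeat symmetry makes the
local frames congruent) and re-verified per unit; a clash in any unit
drops the placement everywhere. Full symmetric backbone minimization
is replaced by this rigid-backbone re-verification — a declared scope
reduction.

**Buried unsatisfied polar atoms** are core-layer N/O atoms in no
detected hydrogen bond. The ≤3 threshold and the per-loop-residue
hydrogen-bond energy threshold (mean Kabsch–Sander energy ≤ −1
kcal/mol) are computed and logged per model *at report level*: they
gate nothing, because they are calibrated for fully sequence-designed
proteins. On backbone-stage models (poly-alanine plus scanned
buttressing sidechains) the buried-unsat count is dominated by polar
atoms that a full sequence-design stage — out of scope here — would
satisfy, plus terminal-unit edge copies that capping helices (also out
of scope) would cover; measured values on demo models are ~8–30, and
treating ≤3 as a hard gate would reject every backbone-stage model
for reasons unrelated to loop quality. Rosetta-internal metrics
(packstat, hole score, total score per residue) appear as null report
columns so report schemas stay stable.

## Motif libraries

β-turn motifs are 4-residue windows whose first residue's carbonyl
accepts a backbone hydrogen bond from the fourth residue's amide
(CO(i)→NH(i+3)); helix-capping motifs are 4-residue windows starting
at a helix's last helical residue with at least one backbone hydrogen
bond from a window residue into the helix's final turn (an
operationalization — the capping requirement admits several readings).
Motifs are stored as torsions plus canonical-frame coordinates
(residue 1's N/CA/C define the frame) and clustered by greedy
farthest-point K-centers under the 16-atom backbone RMSD (N/CA/C/O ×
4, after optimal superposition) at a 0.63 Å radius. The first
fragment seeds the clustering and ties break toward the lowest index,
so results are reproducible for a fixed input order. The packaged
default libraries are mined from the synthetic fixtures: four β-turn
clusters (types I, I′, II, II′ — type VIII lacks the defining hydrogen
bond and cannot appear under this definition) and one Schellman-like
capping cluster. Users can mine real structure sets via
`rbl mine`.

## Synthetic fixtures: what they show and what they don't

The generator (`rbldesign.fixtures`) produces ideal helices, a
12-residue β-hairpin whose type-I′ turn and cross-strand ladder bonds
are genuine (torsions refined once against the target bond geometry
with Cα repulsion, then frozen), a canonical turn gallery, a
helix-with-capping-loop model, two-cluster fragment sets, and a
planted Asn bidentate arrangement solved by inverse geometry (the
partner segment's rigid placement and the Asn chi angles are fit to
the two bond criteria with steric repulsion — the classic Asx-bridge
arrangement in which one partner residue's C=O and N–H both face the
sidechain amide). Identical spec + seed give bit-identical output.

These fixtures exercise the detectors, the closure engine and the
filters under ideal covalent geometry and clean secondary structure.
They do not contain the conformational heterogeneity, non-ideal bond
geometry, missing atoms or sidechain diversity of experimental
structures, so green tests certify the algorithms' correctness on
well-posed inputs, not performance on crystallographic data. The
experimental-comparison path (`compare_structures`, `rbl compare`) is
exercised on synthetic models; comparing against deposited crystal
structures requires the user to supply those files (they are not
redistributable with the package).

## Problem sizes and determinism

The packaged demo uses one repeat architecture (two 20-residue
helices, staggered by (8.6, 4.8, 30) Å with a 180° flip; units
translated 9.6 Å with a −6° twist; 5 repeats, ~200 residues), 600
long-loop attempts and up to 6 buttressed models — sizes chosen so a
full run completes in minutes on one core while the filters still see
O(100) closed candidates. One root seed drives per-stage child
generators (`SeedSequence.spawn`), and reruns of a config are
bit-identical, file for file. Test-suite runs use the same geometry
at reduced sampling.

## Known limitations

- No full-atom energy model anywhere: clash checking is hard-sphere,
  hydrogen bonds are geometric/Kabsch–Sander, scores are surrogate
  log-odds. Rankings are not comparable to molecular-mechanics scores.
- Sequence design is out of scope; emitted models are poly-alanine
  plus scanned buttressing sidechains, and report-level filters
  calibrated for designed sequences (buried-unsat ≤3) are informative
  rather than gating.
- The closure engine returns the branches its restarts find, not the
  complete analytic solution set of the tripeptide polynomial.
- His tautomers/protonation and sidechain acceptor lone-pair
  directionality are not modeled.
- The burial measure is a cone-count approximation; absolute core
  fractions depend on its parameters and should be compared only
  within this package.
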