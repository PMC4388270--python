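# Methods

`deerdock` determines the relative arrangement of two rigid protein
domains joined by a flexible linker from two kinds of solution data:
mean inter-spin-label distances measured by DEER (double electron-electron
resonance) and a 1-D SAXS curve.  This note documents the model behind
each stage, the tunable parameters, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Problem and overall procedure

One domain ("fixed") is held in place; the pose of the other ("moving")
is described by six coordinates: three ZYZ Euler angles (the (α, β)
spherical direction of the rotated z-axis plus a spin angle γ) and a
translation vector **t**.  The procedure is

1. model the mean nitroxide position of every spin-label site;
2. sweep the moving domain over an exhaustive six-dimensional grid and
   score each pose by σ_DEER, the RMS deviation between experimental and
   model mean inter-label distances over the N interdomain restraints:

       σ_DEER = sqrt( (1/N) Σ_i (δ_i,EXP − δ_i,MODEL)² )

3. keep poses with σ_DEER ≤ 3 Å and cluster them by the backbone RMSD
   they induce on the moving domain (complete linkage, 4 Å ceiling), one
   representative (lowest σ) per cluster;
4. build clash-free linker backbones between the domains for each
   representative by constrained Monte Carlo;
5. score each composite model by σ_DEER over *all* restraints (adding
   the two involving the mid-linker label) and by χ_SAXS of its Debye
   curve against the experimental curve (q ≤ 0.3 Å⁻¹), and select models
   with σ_DEER ≤ 3 Å and χ_SAXS ≤ 1.5.

The threshold boundaries are treated inclusively by default (a strict
`<` mode for χ is available); selection is monotone under tightening.

## Spin-label model

DEER restraints refer to the midpoint of the nitroxide N-O bond of an
MTSL label on a cysteine.  Only the *mean* position per site enters the
rigid-body score, so the label is modelled as 18 discrete conformers of
the Cys-S-S-CH₂-pyrroline tether built with idealized bond geometry
(χ₁ ∈ {−75°, −60°, −45°} — the dominant gauche⁻ branch — χ₂ ∈ {−80°,
−60°, 180°}, χ₃ ∈ {±90°}), uniform prior weights, and a hard-sphere
clash filter (2.5 Å against host heavy atoms, attachment residue ±1
exempt); surviving weights are renormalized.  The attachment frame is
built from N, CA and CB (virtual tetrahedral CB for glycine).  The mean
offset sits ~5 Å from CA, inside the 4-10 Å physical tether range.  This
is deliberately not a published rotamer library: absolute label-geometry
accuracy is a few Å, matching the precision at which DEER means
constrain a rigid-body pose; alternative conformer sets can be supplied
as a plain-text file (offset x y z, weight per line).  Sites whose
conformers all clash raise a buried-site error and are excluded.

## Grid search

* Orientations: a deterministic generalized-spiral (Fibonacci) lattice
  of axis directions, one per 0.0385 sr by default → 326 points, times a
  γ sweep every 10° → 11,736 rotations.  The lattice's nearest-neighbour
  spacing has a coefficient of variation below 0.25.
* Translations: a 2 Å lattice over a box; the default box is a cube on
  the fixed-label centroid with half-side max(δ_EXP) + 10 Å (tether
  allowance), which provably contains the feasible region of the
  moving-label centroid.  The moving body is expressed in a frame
  centred on its mean label positions, so the translation *is* the
  global position of that centroid — this keeps the box compact.
* Scoring is vectorized over the translation grid per rotation; ties in
  σ break by grid order, making the search fully deterministic.
* Tests and the packaged analysis use a reduced grid (0.3 sr, γ every
  30°, box half-side 10-12 Å) so each search takes about a second; the
  statistical properties checked do not depend on grid density because
  the ground-truth poses are grid-commensurate.

## Linker construction

Backbones are grown residue by residue with standard internal geometry
(N-CA 1.458, CA-C 1.525, C-N 1.329, C=O 1.231 Å; trans peptide, ω =
180°; carbonyl O in the peptide plane) by the classical recursive
internal-coordinate propagation.  (φ, ψ) pairs are drawn from 10°-binned
Ramachandran densities per residue class.  A geometric subtlety: the
position of residue *i* is fixed by residue *i−1*'s ψ, so each Monte
Carlo move redraws that ψ from its conditional distribution given the
committed φ together with a fresh (φ, ψ) for the new residue; this
preserves the joint dihedral statistics while making the move actually
reposition the residue.  Dead ends back off three residues before the
model restarts.

The first 11 residues (up to the labelled mid-linker cysteine) are
unconstrained; each later residue is accepted only if its CA advances at
least 1.325 Å towards the target CA (the moving domain's N-terminal
residue, whose position the selected pose fixes).  A model succeeds when
the final CA lands within 5 Å of the target; the residual is then
removed by a linear ramp over the backbone in bonded order (N → 3j,
CA → 3j+1, C → 3j+2 for residue j, O riding on its C), normalized so the
final CA lands exactly on the target, the anchor stays immobile, and no
bond stretches by more than residual/(3n−1) ≈ 0.07 Å.  A uniform-shift
variant is available behind `BuilderParams.correction`.  Clashes (two
heavy atoms of nonconsecutive residues closer than 2.5 Å, backbone plus
virtual CB; the last linker residue coincides with the moving domain's
first residue on the sequence axis) are rejected during growth *and*
re-checked after the closure correction, since the correction can move
atoms by up to the 5 Å residual.  Builder budgets (100 proposals per
residue, up to 1,000 model restarts) are configuration parameters.

The Ramachandran tables are synthetic stand-ins: Gaussian-mixture
densities over the classical basins (β, polyproline-II, α_R, α_L) per
residue class (general / Gly / Pro / pre-Pro), with the sterically
forbidden band |φ| < 25° zeroed for non-Gly.  Only the statistical shape
matters for sampling validity; they are not a redistribution of any
published coil library.  A separate helix-biased mixture ("compact") is
used only for growing synthetic globular domains, never for linkers.

## SAXS

Model curves use the Debye sum with one dummy scatterer per residue
(heavy-atom centroid, constant effective electron count 52) by default;
per-atom Cromer-Mann form factors are available.  Displaced solvent and
the hydration shell are not modelled — the multiplicative scale fitted
inside χ_SAXS absorbs most of the difference at q ≤ 0.3 Å⁻¹, and that is
the only range used for selection.

* Guinier: iterated linear fit of ln I on q² over 0.13 ≤ qRg ≤ 1.30
  (the window depends on its own Rg, so the fit is iterated to a fixed
  point).  For a homogeneous sphere this window overestimates Rg by
  ~1.9% — a property of the truncated Guinier expansion, documented and
  frozen into the tests, not an implementation artefact.
* P(r) from models: unweighted pair-distance histogram; D_max is the
  largest pair distance; Rg² = Σ P r² / (2 Σ P).  The histogram omits
  the i = j diagonal, so the moment identity matches the direct Rg up to
  √(N/(N−1)).
* P(r) from curves: non-negative least squares on I(q) = ∫ P(r)
  sinc(qr) dr with a second-derivative Tikhonov penalty and P(0) =
  P(D_max) = 0.  D_max is scanned on a 2 Å grid; candidates are compared
  at minimal regularization (pure representability) and the smallest
  D_max within 5% of the best residual wins — comparing at the per-D_max
  L-curve λ is *not* valid because the chosen λ varies across the scan.
  The returned solution's λ is then picked at the L-curve corner.
  Recovered D_max is accurate to one scan step plus one r-bin; the
  boundary condition pushes D_max up when the outermost pair distance
  falls just below a grid point.
* Dimensionless Kratky: (qRg)² I/I(0) against qRg; the ideal compact
  globule (exact Guinier curve) peaks at 3/e ≈ 1.10 at qRg = √3 ≈ 1.73.
* χ_SAXS: sqrt((1/Np) Σ [(I_exp − c·I_model)/σ]²) with the scale c from
  weighted least squares (an additive offset is available behind a
  flag); model curves are interpolated onto the experimental grid, cubic
  in log I; missing experimental σ falls back to a constant 1% relative
  error.

## Synthetic ground-truth systems

The generator emulates the study conditions: two compact globular
domains, a known SE(3) pose, a 23-residue linker with the label on
residue 11, 13 interdomain restraints in the experimental design pattern
(five fixed-domain sites against a shared moving-domain anchor site,
plus four further moving sites pairing with subsets of the fixed sites),
two mid-linker restraints, Gaussian noise on DEER means (default
0.5 Å; the experimental error model for Tikhonov-derived peak positions
is not stated, and 0.5-1 Å is the plausible scale), and multiplicative
Gaussian noise on the Debye curve (default 5% relative, a typical
mid-q level for a dilute protein sample; the σ column matches the
generating noise).

Toy domains are self-avoiding backbones (N, CA, C, O, CB) grown with
helix-biased dihedral sampling inside a confinement sphere sized for
collapsed-globule scaling (Rg ≈ 1.9 n^0.36 Å), with both termini forced
into the outer shell and the C-terminal tail protruding radially so the
interdomain linker can escape the fold — mirroring how real multidomain
chains present their termini.  All true inter-label distances are kept
inside the 10-80 Å DEER window.  Everything regenerates bit-identically
from recorded seeds.

The packaged arrangement (domain seed 3, 40 residues per domain, pose
α=2.8839, β=2.0402, γ=π, t=(22, 26, −6) Å) was chosen so the span from
the fixed C-terminus to the moving N-terminus (~26 Å) is commensurate
with a 23-residue linker under the 1.325 Å advance rule: the rule forces
a total advance of at least 12 × 1.325 ≈ 16 Å through the restricted
phase, so spans far outside ~16-45 Å make closure statistically
unreachable.  Problem sizes in the analysis (40-residue domains, reduced
grids, a few linkers per cluster) keep a full pipeline run at about a
minute while leaving every recovery property intact.

What the synthetic tests show: the search recovers a grid-commensurate
truth pose exactly from noiseless restraints, keeps the truth inside the
acceptance region under 1 Å noise, the linker builder's retained models
are all clash-free and closed, and χ of the true model against its own
noisy curve is ~1.  What they do not show: accuracy of the simplified
label model against real MTSL rotamer ensembles, robustness to
mis-assigned multimodal DEER peaks, or SAXS contrast effects (solvent,
hydration shell) — on real data those enter the ±3 Å label tolerance and
the fitted χ scale.

## Known limitations

* Means only: DEER distance *distributions* are reduced to their mean
  (multimodal entries to the arithmetic mean of peaks), as the
  rigid-body score consumes only means.
* Two bodies only; no gradient refinement of poses off the grid.
* Linker side chains are not built; clash checking for the linker uses
  backbone plus virtual CB.
* A uniform inflation of all distances can be nearly realizable by
  sliding the moving domain outward when the label sites subtend a small
  angle — infeasibility diagnostics should use sign-alternating
  perturbations, and under-determined searches (< 6 restraints) warn.
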