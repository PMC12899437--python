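# Methods

This note documents the models, conventions, parameters, and numerical
choices behind `gagfes`, and what the synthetic test bed does and does not
demonstrate about real simulation data.

## Cremer–Pople puckering

A six-membered ring is reduced to the out-of-plane displacements `z_j` of
its atoms from the Cremer–Pople mean plane (the plane through the
geometric center whose normal is `R' × R''` with
`R' = Σ R_j sin(2πj/6)`, `R'' = Σ R_j cos(2πj/6)`).  The three puckering
degrees of freedom are

    q2 cos φ2 =  sqrt(2/6) Σ z_j cos(4πj/6)
    q2 sin φ2 = −sqrt(2/6) Σ z_j sin(4πj/6)
    q3        =  sqrt(1/6) Σ (−1)^j z_j
    Q = sqrt(q2² + q3²),   cos θ = q3/Q .

**Convention pinning.**  Atoms are ordered O5, C1, C2, C3, C4, C5
(j = 0…5).  With the standard normal this places the ⁴C₁ chair at θ = 0°,
¹C₄ at θ = 180°, ²S_O at (90°, 150°) and B₃,O at (90°, 180°).  Two checks
pin the orientation and handedness: (a) the four anchor states above map to
their names, and (b) rings generated at ¹C₄/⁴C₁/²S_O reproduce the sign
pattern (and, for ²S_O, the values within a few degrees) of published
near-ideal α-iduronate ring dihedrals (e.g. ¹C₄: Φ₁ = −61.4°, Φ₂ = +57.4°,
…, alternating).  Reversing the traversal direction of the ring maps
θ → 180° − θ; this is asserted in the tests.

The inverse transform builds a ring whose projection is a regular hexagon
(radius 1.46 Å, a typical pyranose value — only the out-of-plane harmonic
content matters) and whose `z_j` carry exactly the m = 2, 3 harmonics, so
forward∘inverse is the identity to floating point (tested at 1e-6°, and in
practice exact to ~1e-12).

**Canonical catalogue.**  The 38 IUPAC conformers (2 chairs, 6 boats,
6 twist-boats, 12 envelopes, 12 half-chairs) are generated at import time
from their idealized displacement patterns (e.g. a boat B_{a,b} displaces
atoms a, b down and the rest up; an envelope displaces one atom), which
puts chairs at the poles, boats/twists on the equator every 30°, envelopes
at θ ≈ 54.7° and half-chairs at θ ≈ 50.8° (and mirror positions).  Deriving
the catalogue from patterns rather than hard-coding vertices guarantees the
names and the forward transform share one convention.

**Idealness.**  Closeness to a target pucker is `(θ − θ_ideal)²` for the
chairs and `(θ − θ_ideal)² + (ϕ − ϕ_ideal)²` for the equatorial targets
(²S_O, B₃,O), with a minimal-image difference on ϕ.  The two-term score is
applied to the two equatorial states: a chair has no azimuth, so a
two-term score is only meaningful off the poles.  Naming by contrast uses
great-circle distance on the CP sphere, which is the right metric when the
candidate set spans both poles and the equator.

## Glycosidic torsions

IUPAC heavy-atom definitions, X ∈ {3, 4}:

    φ = O5_i–C1_i–OX_{i−1}–CX_{i−1}
    ψ = C1_i–OX_{i−1}–CX_{i−1}–C(X−1)_{i−1}

Angles are reported in degrees wrapped to (−180°, 180°].  The bridging
oxygen is found by a covalent-distance search (C–O < 1.7 Å) between the
donor C1 and the acceptor CX instead of trusting residue assignment,
because PDB dialects disagree about which residue owns the glycosidic
oxygen.  The NMR convention (H1 and HX replacing the terminal heavy atoms)
is available as an option; on rigid constructed geometry it differs from
the IUPAC values by a constant offset, which is what the tests assert.

For multi-model helical structures the per-linkage values are aggregated
by linkage type (donor residue name → acceptor residue name) with a
circular mean; both the per-linkage table and the consensus are reported.

## Ring restraint

    E(Φ) = ½ k Σ_{i=1..6} ((Φ_i − Φ0_i)/w)²,  k = 1 kcal/mol, w = 5°

referenced to the ring dihedrals of a near-ideal conformer at the target
pucker.  Differences are wrap-aware (minimal image): the formula itself is
silent on wrapping, but dihedrals near ±180° make it mandatory.  At 298 K
the implied per-dihedral fluctuation is σ_Φ = w·sqrt(kT/k) ≈ 3.9°, enough
to keep the pucker state while allowing moderate ring deformation; the
`pucker_retention` diagnostic (fraction of a (θ, ϕ) series within a
great-circle radius of the target, default 30°) confirms this on a
Metropolis sampler of the restraint's stationary density.  The 30° default
separates the four iduronate states, which are at least 41° apart except
²S_O/B₃,O at 30°.

## Synthetic landscapes and Langevin eABF sampling

The toy potential is a periodic sum of von-Mises-type wells,

    U(x, y) = offset − Σ_j depth_j exp(κ_j (cos(x−x_j) + cos(y−y_j) − 2)),

smooth and 360°-periodic.  `design_two_basin` fixes two well centers and
depths and bisects a shared κ until the exact minimax saddle of the densely
gridded potential gives a prescribed escape barrier from the secondary
basin (tolerance 0.02 kcal/mol internally; the acceptance checks use
±0.1).  Barriers of 3–6 kcal/mol at 298 K (kT = 0.5922 kcal/mol) reproduce
the regime where torsional metastability appears in real GAG disaccharide
simulations.

Dynamics are overdamped Langevin (Euler–Maruyama) in degrees:

    z ← z + (dt/γ)·F + sqrt(2 kT dt/γ)·N(0, 1)

with γ = 1 kcal·mol⁻¹·step·deg⁻² and dt = 1 step by default, i.e. a noise
amplitude of ≈1.1°/step.  Overdamped dynamics is the simplest process with
the correct stationary density exp(−U/kT); inertia, solvent, and 3D ring
motion are deliberately absent.  Each torsion couples harmonically (spring
k_ext = 0.01 kcal/mol/deg², fluctuation sqrt(kT/k_ext) ≈ 7.7°, under two
grid bins) to an extended coordinate λ.  In eABF mode λ additionally feels
the running mean of the accumulated spring force in its λ-bin, ramped by
min(1, N/N_full) with N_full = 200 by default.  Fixed seeds give
bit-identical trajectories; samples are accumulated into the eABF state
every step and recorded to the trajectory pre-move, so a stride-1
trajectory reproduces the accumulated statistics exactly.

**What the toy does not emulate:** atomistic force fields, solvent
friction anisotropy, inertial recrossing, coupling between ring puckering
and (φ, ψ), and multi-dimensional metastability beyond two basins.
Passing the recovery tests shows the estimator stack is correct and
well-conditioned at realistic barrier heights and sampling budgets; it
does not certify force-field accuracy or convergence of any particular MD
system.

## CZAR and Poisson integration

The unbiased free-energy gradient is estimated per z-bin as

    ∇A(z) = −kT ∇ln ρ̃(z) + k_ext (⟨λ⟩_z − z)

with ρ̃ the biased histogram of z, ∇ln ρ̃ by central differences on the
periodic 144×144 grid, and ⟨λ⟩_z accumulated as wrap-safe deviations from
the bin center.  Unsampled bins are filled by iterative neighbor averaging
of ln ρ̃ before differencing and flagged in a mask.

Integration solves ∇²A = ∇·G spectrally with the divergence and Laplacian
both built from the same central-difference operator, making the solution
the exact least-squares potential of the gradient field: for G produced by
central differences of a gridded surface the recovery is exact (tested to
1e-9; in practice machine epsilon), and for noisy G the residual can never
exceed the noise norm.  The zero mode and the Nyquist modes (which central
differencing annihilates) are pinned to zero, and the surface is
normalized to min-zero with the argmin recorded.

**Grid convention.**  144 bins of 2.5° per axis with bin centers at
multiples of 2.5° starting at −180°, so reporting lattices like
(−77.5°, 132.5°) fall on bin centers; `value_at` is nearest-bin lookup
with no interpolation, matching that reporting convention.

## Landscape analysis

All operations treat the grid as a torus with 8-connectivity.  Local
minima are bins strictly below all eight neighbors (flat plateaus collapse
to their lexicographically smallest bin; a constant surface has no
minima).  Basins are assigned by processing bins in increasing
(value, index) order and inheriting the label of the lowest
already-labelled neighbor, which realizes steepest descent with a
deterministic tie-break; bins above the segmentation ceiling (default
15 kcal/mol, the plotted contour ceiling) stay unlabelled.  Barriers are
minimax crossing heights computed by a widest-path Dijkstra, verified
against exhaustive path enumeration on small grids; escape barriers
subtract the starting minimum and are therefore directional, and the two
directions differ by exactly the minimum-depth difference.

Replicate convergence reports the RMS deviation over the region where all
surfaces are ≤ 5 kcal/mol and calls the set consistent when all global
minima agree within 15° (periodic Euclidean) or share one basin of the
first surface; both thresholds are package choices for turning qualitative
convergence judgments into a reproducible verdict.

**Metastability experiment.**  The trapping demonstration uses a
6 kcal/mol escape barrier, replicates started at the secondary minimum,
and a budget of 5×10⁵ steps per replicate for both arms.  Transitions are
counted between *basin cores* (bins below 4 kcal/mol) with a 10-frame
dwell filter: full-torus watershed labels register spurious transitions
when a trajectory loiters on the saddle shoulder without descending into
the other well, whereas core-based counting matches the visual notion of a
state change.  The biased arm uses a faster bias ramp (N_full = 100) so
that the adaptive bias fills the 6 kcal/mol well within the shared budget;
the contrast asserted by the tests is that unbiased replicates make at
most one core-to-core transition while every biased replicate reaches both
cores.

## Structures and fixtures

PDB reading uses gemmi (multi-model, HETATM carbohydrates); writing is
fixed-column at 3-decimal precision.  Atom-name synonyms (primed names such
as O5′) are normalized case-insensitively.  Linkage discovery emits a
`LinkageSpec` for every inter-residue C1–O–C3/C4 bridge within covalent
distance and warns on ambiguity instead of dropping it.

Fixture builders use idealized geometry (C–C 1.52 Å, C–O 1.43 Å,
tetrahedral angles) with the iduronate ring generated at any prescribed
pucker and the glycosidic torsions set *exactly* via natural-extension
(NeRF) placement plus a rigid template fit — the fixtures serve torsion
and pucker logic, not energetics.  Two free construction torsions (bridge
oxygen placement, ring spin about the anomeric bond) are fixed at 120° and
−175°; the latter was chosen so that dodecasaccharide helices built at the
encoded torsion pairs come out extended and self-avoiding, keeping the
distance-based linkage discovery unambiguous.

The synthetic heparin dodecasaccharide `[-4 IdoA2S α1–4 GlcNS6S α1-]₆`
encodes the uniform-helix description of the two NMR structure models of
heparin — one model with every IdoA2S ring in ²S_O and linkage consensus
(−55°, 135°)/(108°, 83°), the other in ¹C₄ with (−77°, 133°)/(79°, 88°) —
as constructed geometry.  It is a stand-in, not experimental coordinates:
it exercises the full parse → classify → measure pipeline (12 residues,
11 linkages, 2 models, PDB round trip at format precision) but cannot test
robustness to experimental noise, alternate atom-name dialects beyond the
synonym table, or non-uniform helices.

## Alignment

Conformer comparison aligns the reducing-end anomeric center (default
atoms C1, O1, C2, O5) with a proper-rotation Kabsch fit; near-collinear
atom sets are rejected via the singular-value gap.  Divergence at the
non-reducing end is reported as the angle between the two highlighted
exocyclic C–O bond vectors (C4–O4 in 1→4 contexts, C3–O3 in 1→3) and the
displacement of the bond origin — reported as metrics, with no threshold
attached.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| grid | 144 bins × 2.5° | degrees | reporting lattice on bin centers |
| temperature | 298 | K | simulation temperature; kT = 0.5922 kcal/mol |
| k_ext | 0.01 | kcal/mol/deg² | spring fluctuation ≈ 7.7° ≲ 2 bins |
| N_full | 200 | samples | standard ABF ramp threshold |
| restraint k, w | 1, 5 | kcal/mol, deg | published restraint parameters |
| dt, γ | 1, 1 | step, kcal·mol⁻¹·step·deg⁻² | ≈1.1°/step thermal noise |
| segmentation ceiling | 15 | kcal/mol | plotted contour ceiling |
| retention radius | 30 | deg | separates the four iduronate states |
| replicates | 3 | — | triplicate sampling convention |

## Known limitations

* The toy sampler is 2-D overdamped Langevin; no claim about kinetics or
  pathways of real systems follows from it.
* Free-energy estimates at the default budgets carry histogram noise that
  grows in high-ΔG regions; only the ΔG < 5 kcal/mol region is held to the
  0.5 kcal/mol recovery bound.
* Fixture geometry is idealized; bond lengths/angles are not force-field
  accurate and fixtures should never be used as simulation inputs.
* `basin_extent` reports axis-aligned periodic intervals, not the exact
  contour outline.
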