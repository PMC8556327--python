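# Methods

This note records the models, conventions and numerical choices behind
`phycoring`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate model and superposition

Structures are read through gemmi (mmCIF canonical, PDB for fixtures) into a
flat atom list. Author chain IDs and residue numbers are preserved exactly,
because anchor residues are quoted in author numbering (αArg30, βPro69).
Hydrogens are dropped (deposited models are heavy-atom); of alternate
locations only blank/'A' is kept; occupancies are ignored by all geometry.

Superposition is the Kabsch SVD solution restricted to proper rotations:
the sign of the smallest singular vector is flipped whenever the unrestricted
optimum would be a reflection. Biological assemblies are chiral, so a
reflection is never an admissible fit even when its residual is lower.
Cα pairing is by shared author residue number by default, with a
sequence-alignment mode (global, match +1 / mismatch 0 / gap −1, via
Biopython's PairwiseAligner) for chains with different numbering. Published
per-structure rmsd values do not state which pairing was used; both are
provided and agree on identical numbering.

## Protomer grouping and ring symmetry

Chains pair into (αβ) protomers either by file order or by inter-chain
contact counts within 5 Å (ties within 5% are refused rather than guessed).
Protomer indices run by layer, then azimuth.

Symmetry detection scores candidate orders n against the azimuthal spacing
of protomer centroids about a principal axis. Both covariance-extreme
eigenvectors are tried, because a wide flat ring is oblate (axis = smallest
eigenvector) while a squat double ring can be prolate (axis = largest); the
axis with the lower mean |gap − 360/n| wins. Two layers are declared when
the axial spread of the centroids exceeds half their mean in-plane radius —
a criterion that is insensitive to coordinate jitter on a genuinely flat
ring — and two equal n-fold layers give Dₙ, one layer Cₙ. Ties within
10⁻³° of residual prefer the larger n (the more specific hypothesis).

The "dihedral angle of the monomer" is defined by three anchor residues;
three points carry no torsion, so it is computed as the planar angle at the
middle anchor on Cα positions — the only reading that reproduces the
published 110°/123° values. Angles are averaged over all symmetry-equivalent
copies, with per-copy values retained. For the adjacent-monomer angle the
interface partner of protomer i is the azimuthal neighbour whose β anchor
lies nearest i's α anchor; this makes the measurement independent of the
azimuthal orientation convention (which reverses in the flipped layer of a
Dₙ assembly).

Pore diameter is reported two ways: raw (twice the smallest radial atom
distance from the axis) and van der Waals (subtracting that atom's Bondi
radius). Published inner diameters do not state their metric, so both are
kept; comparisons between two rings use the same metric and are robust to
the choice.

## Chromophore networks

A chromophore site is any hetero residue whose name is in a configurable
set (default CYC/PCB/BLA — deposited phycocyanobilins appear under varying
codes), anchored to the cysteine whose Sγ is within 2.5 Å of a chromophore
carbon (a thioether bond length with slack). Distances are between
unweighted heavy-atom centroids by default; published tables do not define
their metric, so accession-based comparisons carry ±1 Å. Named-pair values
are minima over symmetry-equivalent copies, matching the single
representative numbers quoted for symmetric assemblies.

## Surface areas and assembly energetics

SASA is Shrake–Rupley sampling on a deterministic golden-spiral point set:
Bondi radii, probe 1.4 Å, 960 points per atom by default (all
configurable); unknown elements are an error, never a silent default
radius. The implementation is verified against closed forms: a single
sphere is exact by construction, two overlapping spheres against the
analytic spherical-cap area to <1%, and doubling the point count moves
totals by <0.3% on the synthetic ring.

contact% = 100·BSA/(ASA + BSA), where ASA is the part's remaining
accessible area in the complex, so the denominator equals its isolated
surface area. The solvation estimate Σ ASP(element)·buried-area is an
explicit atomic-solvation-parameter approximation (Eisenberg–McLachlan-type
coefficients, configurable); it is linear in buried area by construction
and is not expected to reproduce any particular interface-analysis
program's energies, whose parameterizations are not public.

Assembly-route thermodynamics treat the per-oligomer dissociation free
energies ΔG⁰_diss (into monomers) as input data — the shipped defaults are
the published table 4.8 / 20.9 / 16.0 / 54.6 / 20.9 kcal/mol for n = 2, 3,
4, 6, 8 — and derive every balanced step by the thermodynamic cycle
ΔG⁰_f = −(ΔG⁰_diss(product) − Σ ΔG⁰_diss(parts)), negative meaning
favourable formation. Route sums telescope exactly to −ΔG⁰_diss of the
final product, which the tests assert to machine precision. The entropy
terms behind the input table are not recoverable from published material,
which is why the model takes ΔG⁰_diss as data rather than recomputing it.

## Sedimentation velocity

The Lamm equation ∂c/∂t = (1/r)∂/∂r[r(D∂c/∂r − sω²rc)] is solved by
conservative finite volumes on a uniform radial grid (default meniscus
6.0 cm, bottom 7.2 cm, 400 cells) with Crank–Nicolson time stepping and
zero total flux at both ends; because face fluxes telescope, total mass
∫c·r·dr is conserved to round-off in a closed cell. The central scheme
requires cell Péclet number v·Δr/D ≤ 2; a grid too coarse for the fastest
species raises an error naming the required cell count rather than
producing an oscillatory solution. Accuracy checks: the boundary midpoint
follows the non-diffusing law r_m·exp(sω²t) to ≪1%, and ω = 0 relaxes to a
uniform profile.

c(s) inversion builds one Lamm kernel per grid point (default 100 points,
1–15 S, linear), with D(s) tied to a single frictional ratio through
D(s) = (√2/18π)·kT·s^(−1/2)·(η·f/f₀)^(−3/2)·((1−v̄ρ)/v̄)^(1/2), and solves a
non-negative least squares problem with second-difference Tikhonov rows
scaled by λ (default 0.02 relative to the kernel-matrix norm — chosen so
the fit residual sits at the noise level of the simulated data). The fit
excludes radii within 0.01 cm of the meniscus and 0.05 cm of the bottom:
the back-diffusion layer is exquisitely sensitive to the assumed cell
geometry and would otherwise dominate the residual, which is also standard
practice in sedimentation analysis. `f_ratio="fit"` minimizes the residual
by golden section over f/f₀ ∈ [1.0, 2.5] (the objective is smooth and
unimodal here; the recovered value on simulated data is within ±0.04 of the
generating 1.195, the remaining bias reflecting the flatness of the
objective once the residual reaches the noise floor). Peaks above 5% of the
distribution maximum become species: s from the weighted centroid of the
contiguous support, loading from its integral, s₂₀,w via the standard
viscosity/buoyancy correction with water constants ρ = 0.998234 g/mL and
η = 0.010020 P, and M from the Svedberg equation.

Simulated experiments and their fits use deliberately different radial
discretizations (generation on 600 cells resampled to an instrument-like
0.003 cm step; kernels on a Péclet-determined grid, ≈740 cells for s up to
15 S), so the inversion is never fed its own forward model exactly. The
residual floor of a noise-free fit is therefore ≈0.005 absorbance rather
than zero; with σ = 0.005 noise the fitted rmsd is ≈0.005, below the <0.01
level the analysis targets.

## Synthetic data

The toy protomer is a minimal Cα trace: two chains of ~20 residues each,
anchor residues at the published author numbers, bridge residues that give
the α/β pair genuine atomic contacts, and one 4-carbon pseudo-chromophore
per chain thioether-linked (1.8 Å C–S) to a cysteine at α84/β82. The three
bend anchors and three adjacent-monomer anchors are placed so the requested
angles hold *exactly* in the jitter-free ring; n copies by rotation about
z, plus an optional second layer through a perpendicular 2-fold, give exact
Cₙ/Dₙ assemblies with 360/n inter-protomer rotations. Anchor lever arms are
16/12 Å so that realistic coordinate noise propagates to ≲1° in the
measured angles. Jitter is one Gaussian offset per residue (not per atom):
coordinate uncertainty displaces residues but does not stretch covalent
geometry such as the thioether link. Two jitter scales are used: 0.3 Å for
robustness checks, 0.15 Å — the coordinate-error scale of a refined
crystallographic model — for stand-ins emulating deposited structures.

What the toy does *not* emulate: side chains, secondary structure, real
inter-protomer packing (adjacent toy protomers share no atomic contacts, so
ring-interface burial is not exercised beyond the α/β interface), the
β153 chromophore, or deviations of real assemblies from ideal symmetry
beyond isotropic jitter. Passing tests therefore demonstrate correctness of
the estimators under the stated model, not performance on experimental
coordinates; the accession-based checks run automatically whenever the
deposited files are placed under `data/accessions/`.

The simulated sedimentation experiment is a four-species mixture at
3.15/5.24/7.97/11.32 S — dominant dimer loading 0.55, minor species
0.08–0.12 absorbance, matching the observed major/minor pattern — with one
shared frictional ratio 1.195, 60,000 rpm, 20 °C, scans every 400 s from
600 to 5800 s, and i.i.d. Gaussian noise σ = 0.005 chosen so the fitted
rmsd lands below the 0.01 residual level reported for the real experiment.
It does not model time-invariant or radial-invariant optical noise,
meniscus artifacts, or concentration-dependent non-ideality.

## Problem sizes and degenerate inputs

Default problem sizes (400–740 radial cells, 600 time substeps, 100-point
s-grid, 960 sphere points) were chosen as the coarsest settings at which
the convergence and oracle checks above hold with margin; all are exposed
as parameters. Degenerate inputs fail loudly: empty atom sets, odd chain
counts, ambiguous contact pairing, missing anchors (named in the error),
coincident angle vertices, unbalanced stoichiometry, all-zero or
single-scan datasets, f/f₀ < 1, and solvents denser than the particle.
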