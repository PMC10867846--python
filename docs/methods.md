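# Methods

## Model

Each atom carries a fixed partial charge `q_j` (e) and an isotropic,
linear point polarizability `α_j` (bohr³). Under the direct polarization
approximation the induced dipole on atom *j* is

    μ_ind,j = α_j · E_j,
    E_j = E_ext + Σ_{k≠j} f_jk q_k (r_j − r_k) / |r_j − r_k|³,

i.e. dipoles respond to permanent charges and external fields only, never
to one another. Two consequences shape everything in this package:

1. There is no self-consistent-field iteration and no polarization
   catastrophe, so the bare Coulomb and point-dipole kernels are used
   without Thole-style damping.
2. Every observable (atom-site field, induced dipole, ESP at a grid
   point, molecular dipole) is an **exactly linear** function of the
   charge vector, so all fitting problems reduce to linear least squares
   and the "induced" contribution can be folded into a design matrix.

The attenuation `f_jk` follows the Applequist-style convention: 0 for
bonded-path lengths 1 and 2, 0.5 for length 3 (1–4 pairs), 1 beyond.
Path length is the *shortest* bonded path; in rings where a pair is both
1–3 and 1–4, the shorter path wins (the minimum-path convention — the
standard choice, flagged here because ring behaviour is genuinely open).
`f_jk` applies only to fields evaluated **at atom sites**; the ESP
observed at a grid point sums all atoms' charges and dipoles unattenuated
(attenuation is defined for charge–polarizability interactions, not for
observer points).

Internal units are Hartree atomic units throughout (bohr, e, hartree/e);
Å, Debye, Å³ and g/mL appear only at I/O, using
1 Å = 1.8897261254578281 bohr and 1 e·bohr = 2.541746473 D. For ions the
molecular dipole is referenced to the center of nuclear charge, which is
fixed by the structure alone.

## ESP sampling grids

Merz–Singh–Kollman-style nested shells: layer *k* (k = 0…9 by default)
places points on each atom's sphere of radius `1.4·r_vdW + k·0.126 Å` at
17 points/Å², removing points that fall inside any other atom's same-layer
sphere. Defaults follow the reference protocol (10 layers, 17 points/Å²,
0.126 Å spacing); the spacing is interpreted as the radial increment
between successive layers, and the inner scale factor of 1.4 on Bondi
radii is the standard MSK choice (the protocol leaves it unstated; it is
exposed as configuration). Sphere sampling uses a deterministic
golden-spiral lattice oriented in a molecule-fixed principal-axes frame,
which makes the grid reproducible and rotation-equivariant for molecules
with non-degenerate principal axes (symmetric tops fall back to lab axes;
their grids are still deterministic, just not equivariant — irrelevant to
any fitted quantity, which is rotation-invariant regardless).

## Typed-polarizability fit

Training data are *difference* ESPs: perturbed-minus-baseline records
under six uniform fields of 0.01 au (±x, ±y, ±z) — the field magnitude
approximates a sodium ion at ~4 Å. Under the direct approximation the
permanent-charge contribution cancels exactly in the difference, so the
model for a difference record is Σ_j α_type(j) E_ext·r_ij/|r_ij|³: linear
in the typed α. Two solvers are provided and must agree: nonnegative
linear least squares (closed form) and Nelder–Mead simplex on the
identical objective (with restarts from a neutral simplex and a quadratic
out-of-orthant penalty). The agreement is a structural cross-check, not
redundancy — a discrepancy indicates a broken design matrix or a
non-quadratic objective.

Typing schemes: `element` (one α per element symbol) and `pattern`
(SMARTS entries applied in order, last match wins, as in SMIRNOFF
hierarchies). A type with no matching atom anywhere in the training data
raises an unidentifiable-parameter error rather than returning an
arbitrary value.

## RESP-dPol

Stage 1 fits all atoms to the baseline ESP, minimizing

    χ² = Σ_i (V_ref,i − V_model,i)² + Σ_j 2 a (√(q_j²+b²) − b) + λ(Σq − q_tot)

with the weak restraint (a = 0.005 au, b = 0.1 au) on non-hydrogen atoms
(classic RESP practice; hydrogens unrestrained). `V_model = (C + G)·q`
where C is the Coulomb kernel and G folds the induced dipoles driven by
the attenuated permanent-charge fields. Stage 2 freezes every atom except
sp³ carbons carrying ≥2 topologically equivalent hydrogens (methyl and
methylene groups) and those hydrogens, forces within-class equality, and
refits under the strong restraint (a = 0.01 au). The stage-2 selection
realizes "fix the polar regions, refit the conformation-dependent
aliphatic region" by the classic RESP rule, since the polar-region set is
not enumerated anywhere authoritative.

Numerics: the hyperbolic restraint is handled by majorize–minimize
diagonal reweighting — each round replaces the hyperbola with its
quadratic majorizer at the current charges (effective diagonal
`a/√(q_j²+b²)`) and solves the resulting equality-constrained least
squares by nullspace elimination + SVD (`lstsq`), not by normal
equations; this keeps the conditioning at κ rather than κ² and is what
lets zero-noise recovery reach ~1e-15 e. Iterates start feasible (total
charge spread uniformly), so the true objective is provably non-increasing
across iterations. Convergence: max |Δq| < 1e-8 e, cap 200 iterations;
with a = 0 the single solve is exact. A rank-deficient design (degenerate
grids) raises a rank-deficiency error. The factor 2 in the penalty above
makes the stationarity condition match the conventional RESP diagonal
`a/√(q²+b²)`; RESP implementations differ by exactly this factor, and it
is absorbed into the meaning of `a`.

Topological symmetry classes come from Weisfeiler–Lehman colour
refinement on the bond graph (element + formal charge node labels, bond
order edge labels). Refinement only splits classes, so automorphic atoms
always stay together; the (theoretical) failure mode is under-splitting
on pathological regular graphs, which cannot occur for the molecular
graphs in scope. The implementation is cross-checked in the test suite
against RDKit's canonical ranking.

Multi-conformer fitting is per-conformer — conformers are treated as
independent molecules, matching the training protocol this package
emulates. (A joint mode stacking design matrices would be a
straightforward extension; it is deliberately not the default.)

## BCC-dPol

Charges are `q = q_pre + T·B` where `T_jβ` counts β-typed bonds with atom
*j* at the donor end minus the acceptor end, so every column of T sums to
zero and any B conserves total charge exactly. Training minimizes the
summed squared ESP error of `(C+G)(q_pre + T·B)` over all conformers —
by default the induced dipoles respond to the *corrected* charges (the
`induced_on` switch also supports precharges-only response; either way
the problem stays linear in B, and the switch is exposed because the
original protocol is ambiguous on this point). The minimum-norm `lstsq`
solution resolves rank-deficient directions; types with zero support
report B = 0 and are excluded from `covered_types`. Bonds whose two ends
match a type in both orientations (homonuclear, same environment)
transfer no charge by antisymmetry.

Bond types match bond order exactly, with aromatic bonds a distinct order
class (order code 4), as in published BCC type tables; the table contents
are configuration (JSON), not code. Precharges are inputs — no
semi-empirical engine is included.

## Liquid estimators

Given per-frame total dipoles μ (e·bohr) and volumes V (bohr³) at
temperature T:

* ρ = M/⟨V⟩ (M the box molar mass; g/mL at output).
* ε_∞ = 1 + 4πΣα/⟨V⟩. Exact, not approximate, under the direct
  approximation: induced dipoles do not feel each other, so the
  electronic susceptibility is strictly additive and no Clausius–Mossotti
  self-field correction appears. A frozen-box helper computes the same
  quantity as a numeric derivative ∂P/∂E of the implemented model; the
  two must agree to machine precision, and this cross-check is a
  mandatory test.
* D = ε_∞ + 4π(⟨μ·μ⟩ − ⟨μ⟩·⟨μ⟩)/(3⟨V⟩k_B T), with both D and 1/D
  reported (screening is proportional to the reciprocal). ⟨V⟩ rather than
  per-frame V is used in the denominator — the difference is O(relative
  volume fluctuation²) and the choice is documented because the source
  convention is not visible. The full vector second moment is used; no
  block averaging by default.
* Lorentz–Lorenz: α_M = (3/4πρ)·(n²−1)/(n²+2), with the exact algebraic
  inverse provided for round-trip checks.

Gaussian units internally (k_B = 3.166811563e-6 hartree/K); CSV input may
declare Debye/nm³ units in its metadata sidecar.

## Synthetic ground truth

The emulator generates everything a fit needs from known parameters:

* **Toy set**: nine frozen, idealized CHON structures (ethane, butane,
  methanol, ethanol, acetamide, methylamine, acetate anion,
  methylammonium cation, benzene) with 2–4 conformers each. Geometries
  are hard-coded literals (embedded once during development, then
  frozen) — no runtime conformer generation, fully deterministic.
  Flexible molecules get torsion-rotated conformers; rigid ones get
  orientation-distinct conformers, which also exercise the rotational
  invariance of the fits. Pairwise conformer RMSD ≥ 0.5 Å computed on
  stored coordinates without realignment. Ground-truth charges are
  Gasteiger-derived (chemically plausible polarity patterns), normalized
  to sum exactly to the formal charge; ground-truth polarizabilities are
  element-typed at C 9.0, H 2.7, O 5.6, N 7.0 bohr³ — the 0.4–1.4 Å³
  per-atom range typical of organic molecules.
* **ESP records**: baseline plus six difference records per conformer at
  0.01 au field magnitude, from the package's own forward model; optional
  i.i.d. Gaussian noise (hartree/e) added after differencing, seeded per
  conformer via a stable CRC hash. Noise is the simplest stand-in for
  QM/grid error; it reproduces none of the systematic structure of real
  QM ESPs (anisotropy, charge penetration), so recovery tests certify the
  estimators, not the physics of real molecules.
* **Dipolar gas**: N rigid dipoles with independent uniform orientations
  per frame in a fixed box, whose dielectric constant has the closed form
  D = 1 + 4πNμ₀²/(3Vk_BT) + 4πΣα/V. Real liquids add orientational
  correlation (Kirkwood g ≠ 1) and volume fluctuations; the gas isolates
  the estimator itself.
* **Frozen box**: toy molecules on a jittered lattice with seeded random
  rotations, for the ε_∞ finite-difference cross-check.

Because the emulator uses the same forward physics as the fits, zero-noise
recovery is an end-to-end identity test of design-matrix assembly,
constraint handling and solver accuracy — the package's primary
correctness surface — while the independent oracles (brute-force scalar
loops, the classic-ESP normal-equations fit, RDKit symmetry ranks, the
rotor closed form) guard against a bug shared between generator and
fitter.

## Problem sizes and tolerances

The test suite runs the recovery studies on a reduced grid (3 layers,
1 point/Å²) — recovery at zero noise is an exact-model property and does
not depend on sampling density — while `scripts/acceptance.py` uses the
full protocol grid (10 layers, 17 points/Å², ~3×10⁶ stacked residuals for
the polarizability fit). Dielectric estimation uses 10⁵ frames of 64
rotors; the estimate is required to sit within three standard errors
(block estimate) of the closed form. Key tolerances: typed-α recovery and
solver agreement 1e-6 relative; charge and BCC recovery 1e-7 e; total
charge 1e-10 e; physics-core oracle agreement 1e-12; rotational
equivariance 1e-10; ε_∞ analytic-vs-numeric 1e-6.

## Known limitations

* Polarizabilities are isotropic and atom-typed; anisotropic response and
  charge flux are out of scope.
* No energies, forces or periodic electrostatics — the liquids module
  post-processes time series; it does not run MD.
* Quantum-chemistry reference data are consumed as files (or emulated),
  never computed.
* WL symmetry detection can theoretically under-split on regular graphs
  outside the molecular scope.
* Grid equivariance requires non-degenerate principal axes; fitted
  quantities are rotation-invariant in all cases.
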