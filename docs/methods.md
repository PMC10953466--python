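# Methods

## Model and scope

A reaction network on species X₁…Xₙ is an ordered list of reactions
∑ aᵢⱼXᵢ → ∑ (aᵢⱼ+cᵢⱼ)Xᵢ, j = 1…m, encoded by the source matrix
Γₗ = [aᵢⱼ] ≥ 0 and the stoichiometric matrix Γ = [cᵢⱼ].  Under
mass-action kinetics with rate constants κ ∈ ℝ₊ᵐ the concentrations obey

    ẋ = Γ (κ ∘ x^{Γₗᵀ}),

which leaves the positive orthant and each stoichiometric class
(x₀ + im Γ) ∩ ℝ₊ⁿ forward invariant.  The package decides oscillation
questions for the class where a complete theory exists: m = 3 reactions,
rank Γ = 2, sources at most bimolecular ("quadratic", so the ODE is a
quadratic polynomial system).  Three reactions are the minimum for
oscillation: positive dependence of the reaction vectors (required for
positive limit sets) forces rank ≤ m − 1, and periodic orbits need rank
≥ 2.

Every verdict the classifier emits is a consequence of exact integer or
rational computations; floating point appears only in equilibrium
coordinates, eigenvalues, focal values and simulations, which serve as
cross-checks and corroboration.

## Structural layer (exact)

**Dynamical nontriviality.**  ker Γ ∩ ℝ₊ᵐ ≠ ∅ is decided with a
certificate by Stiemke's alternative: either a strictly positive rational
kernel vector u (then positive equilibria are possible) or v with
Γᵀv ≥ 0, ≠ 0 (then some linear functional increases strictly along all
positive orbits, excluding positive limit sets).  For m = 3, rank 2 the
kernel is one-dimensional and spanned by the cross product u = c × d of
the first two independent rows of Γ, so both the decision and the witness
are immediate integers; the witness in the trivial case is assembled from
a zero or mixed-sign pattern of u.  For kernel dimension ≥ 2 (only
reachable through the generic enumeration API) an LP proposes a
combination that is then rationalised and re-verified exactly; the
certificate, not the LP, is the proof.

**Collinear sources.**  If all source complexes lie on one affine line,
the rescaled vector field depends on x only through a scalar monomial and
rank-two systems admit no periodic orbit.  The predicate is an exact rank
computation on source differences.

**Canonical forms.**  Isomorphism (species permutation + reaction
reordering) is decided by the lexicographically minimal serialization
over all n! species permutations with reactions sorted; n ≤ 5 throughout,
so brute force is exact and cheap.  Census counts are counts of canonical
forms; networks differing only by trivial species count as distinct
classes (trivial species are stripped only inside classification).

**Trimolecularization.**  A quadratic reaction with target molecularity
≥ 4 is replaced by at most n reactions that each move a single species by
±1 at rate κ|cⱼ|; the induced vector fields are identical (verified
exactly at rational points in the tests).  This maps statements about
high target molecularity to trimolecular networks with more reactions and
tied rate constants.

## Equilibria and stability

**Log-linear equilibria.**  At a positive equilibrium of a nontrivial
(n, 3, 2) system, κ ∘ x̄^{Γₗᵀ} = μu for a scalar μ with sign μ = common
sign of u.  Taking logarithms gives the linear system
aⱼ·log x̄ − log|μ| = log(|uⱼ|/κⱼ).  For n = 2 with affinely independent
sources the 3×3 system is nonsingular: a unique positive equilibrium for
every κ, found without iteration.  For n ≥ 3 the solution set is an
affine family in log coordinates (a ray or a curve such as the
equilibrium hyperbola of the three-species fold example); intersection
with a stoichiometric class is the only numerical step (bracketed
bisection along one-parameter families, damped root finds from a coarse
grid for two-parameter families).

**Reduced Jacobian.**  With Γ = Γ̃ [cᵀ; dᵀ] (Γ̃ exact, identity block at
the privileged rows), the Jacobian restricted to a class is

    J_red = μ [cᵀ; dᵀ] Δ_u Γₗᵀ Δ_{1/x̄} Γ̃ .

Its determinant expands by Cauchy–Binet into a sum over species pairs of
minors of Γ̃ weighted by 1/(x̄ᵢx̄ⱼ) and the orientation integer
1·(aᵢ· × aⱼ·) of the projected sources.  The printed normalisation of the
expansion carries a positive prefactor that is never used by the theory,
so the implementation pins down sign and positive proportionality: the
2×2 determinant, the expansion sign (times sign μ), and the product of
the two nonzero eigenvalues of the full Jacobian must all agree — this
triple agreement is asserted over hundreds of random systems in the test
suite.  A negative determinant makes the equilibrium a saddle on its
class, and a rank-two system all of whose positive equilibria are saddles
has no periodic orbit.

For n = 2 the sign rule specialises to: with positively oriented sources,
sgn det J = sgn μ = common sign of u; and the trace is
tr J = μ(1/x̄ ∑ aᵢcᵢuᵢ + 1/ȳ ∑ bᵢdᵢuᵢ), checked against the analytic
Jacobian to 1e−9.

**First focal value.**  At a planar center candidate (tr J = 0,
det J = ω² > 0) the equilibrium is translated to the origin and the
linear part brought to [[0, −ω], [ω, 0]] via T = [[j₁₂, 0], [−j₁₁, −ω]]
(j₁₂ ≠ 0 is automatic there).  Because sources are bimolecular the
nonlinearity is exactly quadratic, so the standard planar normal-form
coefficient reduces to its second-derivative part:

    L1 = [f_xy(f_xx+f_yy) − g_xy(g_xx+g_yy) − f_xx g_xx + f_yy g_yy] / (16ω).

L1 < 0 ⇒ supercritical Hopf (stable limit cycle); |L1| below 1e−8 (scaled
by the squared nonlinearity size over ω) is reported as a *vertical
candidate* rather than given a sign — this is what distinguishes the
case-8 and center families (L1 ≡ 0) from genuinely weak foci without
claiming false precision.  Symbolic focal values are out of scope; the
sign is corroborated dynamically by `hopf_side_check`, which tracks
return-map radii on the unstable side and requires the limiting
amplitudes to shrink monotonically toward the bifurcation.

Hopf points are located by varying one rate constant with the others at
1 and bisecting tr J(κ) to ~1e−12 after a sign-change scan on a log grid.

## The classification

**Planar (n = 2).**  Up to exchange of X and Y there are exactly 10
non-collinear triples of bimolecular sources (census-verified).  After
normalising to a positively oriented template order, every verdict is an
integer/rational condition on the reaction-vector entries (c, d):

* cases 1–6: no periodic orbit;
* case 7 (X, X+Y, Y): center for all κ iff c₃ = 0, d₁ = 0 and
  sgn c₁ = −sgn c₂ = −sgn d₃ = sgn d₂ ≠ 0 — the two-parameter generalized
  Lotka family X → (1+c)X, X+Y → (1+d)Y, Y → 0, which conserves
  dκ₂x + κ₂y − κ₃ log x − cκ₁ log y; otherwise no periodic orbit.  (The
  sign chain is implemented with d₃ where one printed source has d₁; the
  printed chain is unsatisfiable together with d₁ = 0, and the corrected
  chain is the one realised by the family.)
* case 8 (2X, X+Y, X): a vertical Hopf family (center exactly at
  κ₁c₁ = κ₂); requires a pentamolecular target;
* cases 9 (2X, X+Y, Y) and 10 (2X, X+Y, 0): the only two families with a
  supercritical Andronov–Hopf bifurcation; in case 9 the tetramolecular
  members are exactly 2X → 3X+Y, X+Y → (1+d)Y, Y → 0 for d = 0..3, and in
  case 10 the smallest members are heptamolecular (exhaustively searched).
  Case 9/10 networks with a positive kernel that fail the Hopf
  inequalities are reported *inconclusive* when no divergence argument
  applies: whether they admit limit cycles is an open question, and the
  classifier does not guess.

**Any n (trimolecular).**  After stripping trivial species, if no
reaction of the autocatalytic form 2Xⱼ → (2+cⱼ)Xⱼ + ∑ cᵢXᵢ (cⱼ > 0,
cᵢ ≥ 0) is present, the Dulac function (x₁⋯xₙ)⁻¹ makes the divergence
nonpositive; it vanishes identically only for Lotka–Volterra systems with
no diagonal term, and the three-reaction networks realising those are
exactly the Ivanova cycle, the generalized Lotka family, and a
three-species family with parameters c, d ≥ 1 (reactions
X+Z → (1+c)X, X+Y → 0, Y+Z → (1+cd)Y + (1+d)Z — re-derived from the
stated ODE normal form, since the printed equilibrium/class formulas are
garbled in the source text; the re-derivation reproduces the classes
x − y + cz = D, the integral dκ₃ log x − κ₁ log y + κ₂ log z and all
three regime bullets: centers on D < 0 iff κ₁ > κ₂ + dκ₃, invariant rays
at equality, saddles on D > 0 otherwise).  With 2X → 3X present the
answer depends on the surviving species count: n = 2 gives the
generalized LVA repellors (Dulac 1/xy) or saddles; n = 3 gives the lifted
LVA family 2X → 3X, X+Y → (1+d)Y + dZ, Y+Z → 0 or saddles; n = 4 admits
positive equilibria only for a single network (2X → 3X, X+Y → Z+W,
Z+W → Y), always a saddle; n ≥ 5 is dynamically trivial.  The lifted LVA
reduces on a class z − y = C, via (v, w) = (y/x, 1/x), to a planar
Lotka–Volterra system: equilibria exist iff C and dκ₂² − κ₁κ₃ share
their sign, and are globally stable / global centers / global repellors
as κ₂ ⋚ κ₃ — a vertical Hopf bifurcation, never an isolated cycle.

## Censuses and pruning

All censuses are canonical-form counts, deterministic, and
order-independent (tested).  The main census enumerates three-reaction
quadratic trimolecular networks on n = 2, 3, 4 species.  Candidate
generation is source-triple-first with two provably sound prunings for
oscillatory networks: sources must be affinely independent (a rank-two
system with collinear sources has no periodic orbit, and repeated sources
are a special case), and every species must appear in some source (a
species absent from all sources is only produced, so e_i separates in the
Stiemke sense and the network is dynamically trivial; a trivial species
occurs in a source whenever it occurs at all).  The remaining filter —
rank 2 with strictly positive kernel — is a small integer computation per
candidate (about 4·10⁶ candidates, a few seconds to minutes).  Survivors
are canonicalized, deduplicated and classified.  A soundness test re-runs
the planar part with no source-based pruning and compares the resulting
sets.  The n ≤ 4 bound is not an assumption: n ≥ 5 oscillatory networks
are impossible by the species-count arguments above, and an n = 5 spot
check in the suite confirms dynamical triviality.

The result is 16 classes: the four generalized Lotka networks
(c, d ∈ {1, 2}), eight one-trivial-species and two two-trivial-species
augmentations of these, the Ivanova reactions and the lifted LVA.  Three
of the 16 are literally bimolecular: Lotka, Ivanova, and the augmentation
of Lotka whose decay reaction carries the trivial species
(Z → 2Z, Y+Z → 2Y, X+Y → X).  The conventional statement that the only
bimolecular oscillators are Lotka and Ivanova refers to networks without
trivial species ("up to the inclusion of trivial species"); the census
reports both counts (`meta["bimolecular"] = 2`,
`meta["bimolecular_including_trivial_augmentations"] = 3`) so the
distinction is explicit.

## Numerical choices

* Integration: DOP853, rtol 1e−9 / atol 1e−12 by default.  Center orbits
  are neutrally stable; looser tolerances turn them into spurious
  spirals.  The positive orthant is never clamped — a numerically
  escaping orbit terminates with a flagged status, and unbounded orbits
  terminate at ‖x‖ = 1e8 with status `blow_up`.
* Periodicity: Poincaré section through x₀ normal to the flow, in
  orthonormal coordinates on the stoichiometric class.  Periodic iff the
  first return lands within 1e−4 (relative to the first loop's extent —
  not the whole trajectory's, so diverging spirals cannot self-certify).
  "Not periodic" is only reported with positive evidence (monotone return
  drift, convergence to an equilibrium, or escape to infinity); anything
  else is inconclusive.
* Equilibrium acceptance: log-linear residual below 1e−9 relative;
  reported residual of the assembled point below 1e−10 in the tests.
* Degenerate-input behaviour: collinear sources make the log-linear
  system singular — the solver returns a family or an empty set, never a
  fake isolated point; `first_focal_value` refuses states that are not
  center candidates; `kernel_sign_vector` refuses m ≠ 3 or rank ≠ 2.

## Limitations

* Focal values are numerical; only the first is computed, and signs
  within 1e−8 of zero are reported as vertical candidates, not decided.
* Case 9/10 networks failing the Hopf conditions are genuinely open and
  classified `inconclusive`.
* Bogdanov–Takens/homoclinic continuation is out of scope; only the
  trace/determinant degeneracy data is exposed.
* The generic enumeration API is exact but not tuned beyond m = 4
  reactions or molecularity 8; SBML import/export and deficiency theory
  are out of scope.
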