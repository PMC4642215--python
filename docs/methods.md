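# Methods

## Data model and classicality

The input record is a membership triplet (μ(A), μ(B), μ(AB)) ∈ [0,1]³ for
one exemplar against a concept pair. Out-of-range weights are rejected, not
clamped; exact 0 and 1 are legal degenerate values. A triplet is classical
conjunction data iff μ(AB) ≤ μ(A), μ(AB) ≤ μ(B) and μ(A)+μ(B)−μ(AB) ≤ 1 —
equivalently, iff a 4-atom joint probability mass function
(p₁₁, p₁₂, p₂₁, p₂₂) with marginals μ(A), μ(B) and intersection μ(AB)
exists. All inequality checks use a shared tolerance ε = 1e-9 (the theory
is exact; ε only absorbs float noise in computed inputs), and reports store
the raw signed slacks alongside the boolean flags so callers can re-apply
their own tolerance. The taxonomy is exhaustive and exclusive: classical,
single overextension, double overextension, or Kolmogorov-factor-only
violation (overextension takes precedence in naming when both occur, since
the double/single distinction is defined by which of the first two
inequalities fail).

## First sector: feasibility and the closed-form solver

A triplet is representable in ℂ³ iff μ(AB) lies in
[ave − dev, ave + dev], ave = ½(μ(A)+μ(B)),
dev = min(√(μ(A)μ(B)), √((1−μ(A))(1−μ(B)))). The feasibility boundary is
included (tolerance ε). The defining conditions leave a continuum of
solutions (two free mass-splitting parameters λ, κ and three relative
phases); the solver freezes one deterministic representative:

* λ = κ = ½ throughout.
* **Rank-1 branch** (μ(A)+μ(B) ≤ 1, projector onto e₁): |A⟩ real with
  amplitudes (√μ(A), √((1−μ(A))/2), √((1−μ(A))/2)); |B⟩ has matching
  amplitudes from μ(B) and phases γ₁ = arccos(I/√(μ(A)μ(B))) with
  I = μ(AB) − ave (the interference the membership formula needs), and
  γ₂,₃ = π + γ₁ ± δ, δ = arccos(√(μ(A)μ(B))/√((1−μ(A))(1−μ(B)))), which
  makes the two tail terms cancel the head term exactly (orthogonality).
  δ is well-defined precisely because μ(A)+μ(B) ≤ 1.
* **Rank-2 branch** (μ(A)+μ(B) ≥ 1, projector onto span(e₁,e₂)): the
  mirror construction with cos γ₃ = −I/√((1−μ(A))(1−μ(B))) and
  δ = arccos(√((1−μ(A))(1−μ(B)))/√(μ(A)μ(B))).
* At μ(A)+μ(B) = 1 exactly both branches are valid; rank-1 is used.
* All-zero / all-one triplets short-circuit to rank-0 / rank-3 projectors
  with canonical states (the conditions then hold for any orthonormal pair).
* Degenerate guards: when a phase's defining ratio is 0/0 (e.g.
  μ(A)μ(B) = 0, where feasibility already forces I = 0) the phase is set to
  0 and δ to π/2; arguments to arccos are clipped to [−1, 1] against float
  spill. The positive sine branch is taken everywhere, so the
  representation is a deterministic function of the triplet.

Verification is by direct residual evaluation of the six conditions; the
solver's residuals are at float precision (≈1e-16), asserted < 1e-10.

## Unification

Per exemplar, the private basis {|Aᵢ⟩, |Bᵢ⟩, |Cᵢ⟩} is completed with
|Cᵢ⟩ = conj(|Aᵢ⟩ × |Bᵢ⟩), normalized — the *conjugated* cross product,
because the bare component-wise cross product of complex vectors is
orthogonal to its factors only under the bilinear form, not the Hermitian
inner product. The basis-change unitary is U = Σₖ |targetₖ⟩⟨sourceₖ| and
operators move by conjugation U M U⁻¹, which preserves every matrix
element, hence all membership expectations, exactly up to float error.

In the second sector the private state (the ℂ⁴ image of the coefficient
matrix under row-major relabeling (i,j) → n(i−1)+j) is completed to an
orthonormal basis by deterministic modified Gram–Schmidt: at each step the
canonical basis vector with the largest residual norm after projection is
orthogonalized (ties broken by lowest index), a second projection pass
controls round-off, and every constructed vector is phase-fixed so its
first nonzero component is real nonnegative. Identical input therefore
yields bit-identical bases. The three unified operators per exemplar are
the conjugated M⊗1, 1⊗M and M⊗M; the model flags an exemplar *first-type*
when its unified A- and B-operators happen to factor as X⊗1 and 1⊗Y
(checked by partial-trace reconstruction to 1e-10).

Second-type (product-state) unification requires knowing the triplet has a
product-state representation; independence μ(AB) = μ(A)μ(B) is a
sufficient condition and the only one this package certifies — any other
triplet is reported "unknown" and rejected by the second-type unifier.
Degenerate factor weights 0/1 use the rank-0/rank-2 (zero/identity)
projector on that factor. The ℂ³⊗ℂ³ embedding zero-pads states and
operators on the embedded index set {3i+j : i,j ∈ {0,1}}, leaving all
expectations unchanged.

## Fock fitting

The two-sector formula μ(AB) = n²(ave + I) + (1−n²)μ(A)μ(B) is fitted by a
deterministic preference rule: n = 1 with I = μ(AB) − ave when |I| is
within the interference bound √(μ(A)μ(B)); otherwise n is scanned downward
on a 0.01 grid and the largest feasible weight returned, with n = 0
admissible only when μ(AB) equals the product. The solution set is a
continuum; preferring the largest n (the maximally "emergent" reading) is
a convention, and a shared-n mode fits one weight across a whole dataset
(largest n feasible for every exemplar). The interference bound uses the
square-root form √(μ(A)μ(B)), which is what the rank-1 amplitude algebra
(a₁b₁ = √μ(A)·√μ(B)) yields. A fit is reported infeasible when no grid
point reproduces μ(AB); round-trips of feasible fits are exact to 1e-12.

## Compatibility

Commutator expectations ⟨v|[M₁,M₂]|v⟩ are purely imaginary for Hermitian
operators. First-sector reports evaluate c_A, c_B on the canonical states
and c_AB as ½(⟨A|+⟨B|)[M₁,M₂](|A⟩+|B⟩) — the superposition is deliberately
left unnormalized with the ½ prefactor compensating. The compatibility
threshold is 1e-10 on magnitude; reports carry the raw complex values.
First-sector c-values inherit the solver's phase conventions (the
underlying representations are non-unique), so only their zero/nonzero
structure is meaningful across implementations; the package reports the
magnitudes but the test suite asserts structure only. Under the all-real
tensor construction every second-sector commutator expectation vanishes
identically — real symmetric operators have antisymmetric commutators with
zero diagonal quadratic form — reproducing the expectation that classical
(tensor) models are always compatible.

## Synthetic data

The generator emulates the *regions* of the theory, not any empirical
distribution of human membership judgements:

* `classical` — a 4-atom joint pmf drawn uniformly from the simplex
  (sorted-uniform spacings) and marginalized, so classicality holds by
  construction;
* `overextended_representable` — (μ(A), μ(B)) uniform, μ(AB) uniform
  inside the feasibility interval, rejected until overextended;
* `first_sector_infeasible` — μ(AB) uniform, rejected until outside the
  interval (with a 1e-6 margin so samples are robustly infeasible);
* `independent` — μ(AB) = μ(A)μ(B) exactly.

Rejection caps at 10⁴ attempts per record. Seeding is part of the public
contract: a config is a reproducible fixture. Real membership data cluster
near the interference-free average and carry response noise; the generator
makes no attempt to model either, so passing tests demonstrate the
*mathematical* contracts (region membership, constructibility,
preservation under unification), not fit to human data.

## Verification strategy and problem sizes

The closed-form solvers are cross-checked against independent numerical
oracles: classicality against LP feasibility of the joint pmf; first-sector
feasibility against a randomized least-squares search over raw ℂ³
state/projector parameters (projector canonical of rank 1 or 2 — valid
without loss of generality because the conditions are unitary-invariant —
500 random triplets, 5 restarts); tensor representability against the same
kind of search over ℂ⁴ coefficients and a rank-1 factor projector.
Property suites run at 12–150 triplets per regime, sizes chosen to exercise
the constructions densely while keeping the full suite in the
tens-of-seconds range on one core.

## Known limitations

* No combined two-sector state construction spanning both sectors at once;
  the Fock fit works at the level of the membership formula.
* First-type representations have no standalone constructor (no known
  necessary-and-sufficient condition); they are only detected post hoc.
* Second-type unification certifies only independent triplets.
* Dimensions are fixed at 2, 3, 4, 9; higher-dimensional first-sector
  spaces add no modeling power (the feasibility condition is unchanged) and
  ℂ² is strictly more restrictive (it forces μ(A)+μ(B) = 1).
* First-sector c-values are convention-dependent (see Compatibility);
  consumers should compare magnitudes only within one solver convention.
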