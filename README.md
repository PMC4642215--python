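# qconj

Quantum representations of concept-conjunction membership data.

## The problem

When people judge whether an exemplar (say, *skateboard*) is a member of
two concepts (*Machine*, *Vehicle*) and of their conjunction (*Machine And
Vehicle*), the measured membership weights μ(A), μ(B), μ(AB) routinely
violate classical probability: the conjunction weight exceeds a constituent
weight (**overextension**). A triplet is *classical conjunction data* iff

    μ(AB) ≤ μ(A),   μ(AB) ≤ μ(B),   μ(A) + μ(B) − μ(AB) ≤ 1.

Quantum-cognition models accommodate non-classical triplets in a two-sector
Fock space **F = H ⊕ (H ⊗ H)**:

* **First sector** (H = ℂ³, emergent conjunction): unit states |A⟩ ⊥ |B⟩
  and an orthogonal projector M with ⟨A|M|A⟩ = μ(A), ⟨B|M|B⟩ = μ(B) and
  μ(AB) = ½(μ(A)+μ(B)) + ℜ⟨A|M|B⟩. Such a model exists **iff**
  μ(AB) ∈ [ave − dev, ave + dev], with ave = ½(μ(A)+μ(B)) and
  dev = min(√(μ(A)μ(B)), √((1−μ(A))(1−μ(B)))).
* **Second sector** (H ⊗ H, logical conjunction): a unit state
  |C⟩ ∈ ℂ²⊗ℂ² and a single-factor projector M with
  ⟨C|M⊗1|C⟩ = μ(A), ⟨C|1⊗M|C⟩ = μ(B), ⟨C|M⊗M|C⟩ = μ(AB). This exists
  **iff** the triplet is classical — the tensor model and the
  Kolmogorovian model are equivalent.
* **Fock formula**: μ(AB) = n²(½(μ(A)+μ(B)) + I) + (1−n²) μ(A)μ(B) with
  sector weight n ∈ [0,1] and interference I = ℜ⟨A|M|B⟩, |I| ≤ √(μ(A)μ(B)).

The package's distinctive piece is **unification by unitary transformation**:
many exemplars' private representations are rotated into one shared basis so
that a *single* conceptual state (pair) serves all exemplars and each
exemplar carries its own measurement operator. With all operators in one
basis, measurement **compatibility** becomes computable: commutator
expectation values c_X = ⟨·|[M₁, M₂]|·⟩ that do not vanish predict order
effects in sequential membership judgements.

## What the package does

* `qconj.data` — triplet validation, classicality taxonomy, CSV/JSON I/O.
* `qconj.first_sector` — Theorem-style feasibility interval, deterministic
  closed-form ℂ³ representations, unitary unification.
* `qconj.second_sector` — all-real tensor constructions, zero-type and
  second-type unification, ℂ³⊗ℂ³ embedding.
* `qconj.fock` — two-sector membership formula, interference bounds,
  deterministic (n, I) fitting.
* `qconj.compatibility` — commutator expectations, pairwise matrices.
* `qconj.synth` — seeded synthetic triplet generator by regime.
* `qconj.cli` — `qconj` command with `classify`, `represent-first`,
  `represent-second`, `unify-first`, `unify-second`, `fock-fit`, `compat`,
  `simulate` and `report` subcommands.

## Worked example

```python
>>> import qconj
>>> ds = qconj.datasets.load("machine_vehicle")   # sailboat, skateboard
>>> [qconj.check_classical(t).category for t in ds]
['classical', 'single_overextension']
>>> rep = qconj.construct_representation(ds[1])   # skateboard in C^3
>>> rep.params.branch, round(rep.membership_ab(), 10)
('rank2', 0.34)
>>> model = qconj.unify([qconj.construct_representation(t) for t in ds])
>>> r = qconj.first_sector_compatibility(model, 0, 1)
>>> r.compatible, round(abs(r.c_a), 4), round(abs(r.c_ab), 4)
(False, 0.0934, 0.0248)
```

The skateboard triplet (0.28, 0.84, 0.34) is overextended (0.34 > 0.28) —
no classical model exists — yet the ℂ³ representation reproduces its
conjunction weight exactly, and the unified sailboat/skateboard model shows
nonzero commutator expectations: the two exemplars' membership measurements
are predicted to exhibit order effects. (The c-magnitudes depend on the
solver's phase conventions; only their nonzero structure is
convention-independent.) By contrast, the classical Building/Dwelling pair:

```python
>>> bd = qconj.datasets.load("building_dwelling")  # cave, synagogue
>>> zm = qconj.unify_zero_type(list(bd))
>>> qconj.second_sector_compatibility(zm, 0, 1).max_magnitude
0.0
```

— the tensor (classical) model always yields compatible measurements.

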