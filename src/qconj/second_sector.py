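"""Tensor-product (second-sector) representations of classical conjunction data.

The second sector models the conjunction "A and B" as a *logical* joint
entity: a unit state |C> in C^n (x) C^n together with a projector M on one
factor, such that

    <C| M (x) 1 |C> = mu(A),   <C| 1 (x) M |C> = mu(B),
    <C| M (x) M |C> = mu(AB).

A triplet admits such a representation with n = 2 exactly when it is
classical conjunction data — the tensor model and the Kolmogorovian model
are equivalent.  The constructive recipe is all-real:

    c11 = sqrt(mu(AB)),          c12 = sqrt(mu(A) - mu(AB)),
    c21 = sqrt(mu(B) - mu(AB)),  c22 = sqrt(1 - mu(A) - mu(B) + mu(AB)),

with M the rank-1 projector onto |1>.

A collection of classical triplets can be *unified* into a zero-type model:
a single shared state |1>(x)|1> with per-exemplar operator triples obtained
by rotating each private representation with a C^4 unitary.  A second-type
model additionally demands a product conceptual state and single-factor
projectors; independence (mu(AB) = mu(A) mu(B)) is a sufficient condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import linalg
from .data import EPSILON, MembershipTriplet, check_classical
from .exceptions import RepresentabilityError, ValidationError


@dataclass(frozen=True)
class TensorRepresentation:
    """One triplet's representation in C^2 (x) C^2 (or C^3 (x) C^3).

    ``coefficients`` is the n-by-n matrix c_ij of the state
    |C> = sum_ij c_ij |i>(x)|j>; ``projector`` is the single-factor M.
    """

    coefficients: np.ndarray
    projector: np.ndarray
    triplet: MembershipTriplet

    @property
    def n(self) -> int:
        return self.coefficients.shape[0]

    @property
    def state_vector(self) -> np.ndarray:
        return linalg.tensor_to_vec(self.coefficients)

    def expectations(self) -> tuple[float, float, float]:
        """(mu_a, mu_b, mu_ab) re-evaluated as tensor expectation values."""
        c = self.state_vector
        m = self.projector
        ma = linalg.kron_factor_identity(m, "left")
        mb = linalg.kron_factor_identity(m, "right")
        mab = np.kron(m, m)
        return (
            float(np.vdot(c, ma @ c).real),
            float(np.vdot(c, mb @ c).real),
            float(np.vdot(c, mab @ c).real),
        )


def construct_tensor_representation(
    t: MembershipTriplet, *, eps: float = EPSILON
) -> TensorRepresentation:
    """Build the all-real C^2 (x) C^2 representation of a classical triplet.

    The four coefficients are the square roots of the atoms of the unique
    4-point joint distribution with marginals mu(A), mu(B) and intersection
    mu(AB); all relative phases are set to zero.  Non-classical triplets are
    rejected with the violated inequality named.
    """
    report = check_classical(t, eps=eps)
    if not report.is_classical:
        violated = []
        if report.overextended_a:
            violated.append("mu_ab <= mu_a")
        if report.overextended_b:
            violated.append("mu_ab <= mu_b")
        if report.kolmogorov_violation:
            violated.append("mu_a + mu_b - mu_ab <= 1")
        raise RepresentabilityError(
            f"triplet {t.exemplar!r} is not classical conjunction data; "
            f"violated: {', '.join(violated)}",
            detail={"category": report.category, "violated": violated},
        )
    atoms = [
        t.mu_ab,
        t.mu_a - t.mu_ab,
        t.mu_b - t.mu_ab,
        1.0 - t.mu_a - t.mu_b + t.mu_ab,
    ]
    coeffs = np.array(
        [[math.sqrt(max(0.0, atoms[0])), math.sqrt(max(0.0, atoms[1]))],
         [math.sqrt(max(0.0, atoms[2])), math.sqrt(max(0.0, atoms[3]))]],
        dtype=complex,
    )
    coeffs /= np.linalg.norm(coeffs.reshape(-1))  # exact unit norm under float
    return TensorRepresentation(coeffs, linalg.canonical_projector(2, 1), t)


@dataclass(frozen=True)
class ZeroTypeModel:
    """Unified tensor model: one shared state, per-exemplar operator triples.

    The shared conceptual state is |1>(x)|1> (the first canonical vector of
    C^(n^2)); exemplar i carries operators (op_a, op_b, op_ab) on the full
    tensor space whose expectations on the shared state reproduce the
    triplet.  ``first_type`` flags exemplars whose unified operators happen
    to factor as M (x) 1 and 1 (x) M — i.e. are unentangled.
    """

    n: int
    exemplars: list[str]
    operators: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    unitaries: list[np.ndarray]
    triplets: list[MembershipTriplet]
    first_type: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.exemplars)

    @property
    def state_vector(self) -> np.ndarray:
        c = np.zeros(self.n * self.n, dtype=complex)
        c[0] = 1.0
        return c

    def membership(self, i: int) -> tuple[float, float, float]:
        c = self.state_vector
        return tuple(float(np.vdot(c, op @ c).real) for op in self.operators[i])  # type: ignore[return-value]


def unify_zero_type(
    ts: list[MembershipTriplet], *, eps: float = EPSILON
) -> ZeroTypeModel:
    """Unify classical triplets into a zero-type model on C^2 (x) C^2.

    Per exemplar: build the all-real tensor representation, view its state
    as a C^4 vector, complete it to an orthonormal basis, rotate that basis
    onto the canonical one with a unitary U_i, and conjugate the three
    operators M(x)1, 1(x)M, M(x)M along.  The shared state becomes
    |1>(x)|1> and every expectation value is preserved.
    """
    canonical = [np.eye(4, dtype=complex)[k] for k in range(4)]
    exemplars, operators, unitaries, triplets, first_type = [], [], [], [], []
    for t in ts:
        rep = construct_tensor_representation(t, eps=eps)
        c4 = rep.state_vector
        basis = linalg.complete_orthonormal_basis([c4], 4)
        u = linalg.build_basis_change(basis, canonical)
        m = rep.projector
        ops = (
            linalg.conjugate_operator(linalg.kron_factor_identity(m, "left"), u),
            linalg.conjugate_operator(linalg.kron_factor_identity(m, "right"), u),
            linalg.conjugate_operator(np.kron(m, m), u),
        )
        fa = linalg.split_as_kron_with_identity(ops[0], 2, "left")
        fb = linalg.split_as_kron_with_identity(ops[1], 2, "right")
        exemplars.append(t.exemplar)
        operators.append(ops)
        unitaries.append(u)
        triplets.append(t)
        first_type.append(fa is not None and fb is not None)
    return ZeroTypeModel(
        n=2,
        exemplars=exemplars,
        operators=operators,
        unitaries=unitaries,
        triplets=triplets,
        first_type=first_type,
    )


def product_state_status(t: MembershipTriplet, *, eps: float = EPSILON) -> str:
    """Whether a triplet is known to admit a product-state representation.

    Independence, mu(AB) = mu(A) mu(B), is sufficient; for any other triplet
    the question is left open and the status is ``"unknown"``.
    """
    return "independent" if abs(t.mu_ab - t.mu_a * t.mu_b) <= eps else "unknown"


@dataclass(frozen=True)
class SecondTypeModel:
    """Product-state unified model: |1>(x)|1> with single-factor projectors."""

    exemplars: list[str]
    projectors_a: list[np.ndarray]
    projectors_b: list[np.ndarray]
    unitaries_a: list[np.ndarray]
    unitaries_b: list[np.ndarray]
    triplets: list[MembershipTriplet]

    def __len__(self) -> int:
        return len(self.exemplars)

    def membership(self, i: int) -> tuple[float, float, float]:
        e1 = np.array([1.0, 0.0], dtype=complex)
        ma, mb = self.projectors_a[i], self.projectors_b[i]
        mu_a = float(np.vdot(e1, ma @ e1).real)
        mu_b = float(np.vdot(e1, mb @ e1).real)
        c = np.kron(e1, e1)
        op_ab = linalg.kron_factor_identity(ma, "left") @ linalg.kron_factor_identity(mb, "right")
        mu_ab = float(np.vdot(c, op_ab @ c).real)
        return mu_a, mu_b, mu_ab


def unify_second_type(
    ts: list[MembershipTriplet], *, eps: float = EPSILON
) -> SecondTypeModel:
    """Unify triplets with product-state representations on C^2 (x) C^2.

    For each exemplar the private factor states |A_i> = (sqrt(muA),
    sqrt(1-muA)) and |B_i> (likewise) with M = |1><1| realize an independent
    triplet; single-factor unitaries rotate each private state onto |1> and
    the projectors are conjugated along, so the shared state is |1>(x)|1>.
    Members whose product-state representability is not established
    (non-independent triplets) are rejected.
    """
    e = [np.eye(2, dtype=complex)[k] for k in range(2)]
    m_check = linalg.canonical_projector(2, 1)
    exemplars, ms_a, ms_b, us_a, us_b, triplets = [], [], [], [], [], []
    for t in ts:
        if product_state_status(t, eps=eps) != "independent":
            raise RepresentabilityError(
                f"triplet {t.exemplar!r}: product-state representation unknown "
                f"(mu_ab != mu_a * mu_b)",
                detail={"mu_ab": t.mu_ab, "product": t.mu_a * t.mu_b},
            )
        factors = []
        for mu in (t.mu_a, t.mu_b):
            if mu >= 1.0 - eps:  # degenerate: identity projector on the factor
                factors.append((linalg.canonical_projector(2, 2), np.eye(2, dtype=complex)))
            elif mu <= eps:  # degenerate: zero projector
                factors.append((linalg.canonical_projector(2, 0), np.eye(2, dtype=complex)))
            else:
                state = np.array([math.sqrt(mu), math.sqrt(1.0 - mu)], dtype=complex)
                u = linalg.build_basis_change(linalg.complete_orthonormal_basis([state], 2), e)
                factors.append((linalg.conjugate_operator(m_check, u), u))
        (ma, ua), (mb, ub) = factors
        exemplars.append(t.exemplar)
        ms_a.append(ma)
        ms_b.append(mb)
        us_a.append(ua)
        us_b.append(ub)
        triplets.append(t)
    return SecondTypeModel(exemplars, ms_a, ms_b, us_a, us_b, triplets)


def embed_in_C3(model: ZeroTypeModel) -> ZeroTypeModel:
    """Trivially embed a C^2 (x) C^2 zero-type model into C^3 (x) C^3.

    Coefficients c*_ij = c_ij for i, j in {1, 2} and 0 otherwise; operators
    are zero-padded onto the embedded index positions.  All expectation
    values are unchanged, and projectors remain Hermitian idempotent.
    """
    if model.n != 3 and model.n != 2:
        raise ValidationError(f"unexpected factor dimension {model.n}")
    if model.n == 3:
        return model
    # tensor index (i, j), 0-based, maps to 2i+j in C^4 and 3i+j in C^9
    idx = [3 * i + j for i in range(2) for j in range(2)]
    operators = []
    unitaries = []
    for ops, u in zip(model.operators, model.unitaries):
        padded_ops = []
        for op in ops:
            big = np.zeros((9, 9), dtype=complex)
            big[np.ix_(idx, idx)] = op
            padded_ops.append(big)
        big_u = np.eye(9, dtype=complex)
        big_u[np.ix_(idx, idx)] = u
        operators.append(tuple(padded_ops))
        unitaries.append(big_u)
    return ZeroTypeModel(
        n=3,
        exemplars=list(model.exemplars),
        operators=operators,
        unitaries=unitaries,
        triplets=list(model.triplets),
        first_type=list(model.first_type),
    )
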