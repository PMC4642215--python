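"""Hilbert-space (first-sector) representations of membership triplets in C^3.

A triplet (mu(A), mu(B), mu(AB)) is representable in the first sector when
there exist unit vectors |A>, |B> in C^3 and an orthogonal projector M with

    <A|A> = <B|B> = 1,      <A|B> = 0,
    <A|M|A> = mu(A),        <B|M|B> = mu(B),
    mu(AB) = (mu(A) + mu(B)) / 2 + Re <A|M|B>,

which happens exactly when mu(AB) lies in the feasibility interval
[ave - dev, ave + dev] with ave = (mu(A)+mu(B))/2 and
dev = min(sqrt(mu(A) mu(B)), sqrt((1-mu(A))(1-mu(B)))).  The conjunction
weight is thus the average of the constituents shifted by an interference
term Re <A|M|B> whose reach is |I| <= dev.

The solution family is a continuum; this module implements one
deterministic closed-form representative (see ``construct_representation``)
so that identical input always yields identical output.  A collection of
representations, one per exemplar, can then be *unified*: rotated by
exemplar-specific unitaries into a single canonical basis where the
conceptual states are |A> = (1,0,0), |B> = (0,1,0) for every exemplar and
all exemplar dependence lives in the projectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import linalg
from .data import EPSILON, MembershipTriplet
from .exceptions import RepresentabilityError, ValidationError

_TINY = 1e-15


@dataclass(frozen=True)
class FeasibilityInterval:
    """The exact set of conjunction weights representable in C^3."""

    ave: float
    dev: float

    @property
    def lo(self) -> float:
        return self.ave - self.dev

    @property
    def hi(self) -> float:
        return self.ave + self.dev

    def contains(self, mu_ab: float, *, eps: float = EPSILON) -> bool:
        return self.lo - eps <= mu_ab <= self.hi + eps


def feasibility_interval(mu_a: float, mu_b: float) -> FeasibilityInterval:
    """Midpoint and half-width of the representable conjunction range.

    ave = (mu_a + mu_b)/2;  dev = min(sqrt(mu_a mu_b), sqrt((1-mu_a)(1-mu_b))).
    """
    if not (0.0 <= mu_a <= 1.0 and 0.0 <= mu_b <= 1.0):
        raise ValidationError("membership weights must lie in [0, 1]")
    ave = 0.5 * (mu_a + mu_b)
    dev = min(math.sqrt(mu_a * mu_b), math.sqrt((1.0 - mu_a) * (1.0 - mu_b)))
    return FeasibilityInterval(ave=ave, dev=dev)


def representable(t: MembershipTriplet, *, eps: float = EPSILON) -> bool:
    return feasibility_interval(t.mu_a, t.mu_b).contains(t.mu_ab, eps=eps)


@dataclass(frozen=True)
class SolverParameters:
    """Free parameters of the constructive solver, frozen at one representative.

    branch: projector rank used (rank0/rank1/rank2/rank3); the rank-1 branch
    requires mu(A)+mu(B) <= 1 and the rank-2 branch >= 1.  lambda_ and kappa
    split the off-projector amplitude mass; gamma1..3 are the relative phases
    of |B> against a real |A>, in radians.
    """

    branch: str
    lambda_: float
    kappa: float
    gamma1: float
    gamma2: float
    gamma3: float


@dataclass(frozen=True)
class FirstSectorRepresentation:
    state_a: np.ndarray
    state_b: np.ndarray
    projector: np.ndarray
    params: SolverParameters
    triplet: MembershipTriplet

    def membership_ab(self) -> float:
        """Re-evaluate the conjunction membership from the representation."""
        t = self.triplet
        inter = np.vdot(self.state_a, self.projector @ self.state_b)
        return 0.5 * (t.mu_a + t.mu_b) + float(inter.real)


def _rank1_phases(mu_a: float, mu_b: float, interference: float) -> tuple[float, float, float]:
    s = math.sqrt(mu_a * mu_b)
    if s > _TINY:
        g1 = math.acos(min(1.0, max(-1.0, interference / s)))
    else:
        g1 = 0.0
    full = math.sqrt((1.0 - mu_a) * (1.0 - mu_b))
    if full > _TINY:
        delta = math.acos(min(1.0, s / full))
    else:
        delta = 0.5 * math.pi
    return g1, math.pi + g1 + delta, math.pi + g1 - delta


def _rank2_phases(mu_a: float, mu_b: float, interference: float) -> tuple[float, float, float]:
    u = math.sqrt((1.0 - mu_a) * (1.0 - mu_b))
    if u > _TINY:
        g3 = math.acos(min(1.0, max(-1.0, -interference / u)))
    else:
        g3 = 0.0
    w2 = math.sqrt(mu_a * mu_b)  # = 2 * a1 b1 at lambda = kappa = 1/2
    if w2 > _TINY:
        delta = math.acos(min(1.0, u / w2))
    else:
        delta = 0.5 * math.pi
    return math.pi + g3 + delta, math.pi + g3 - delta, g3


def construct_representation(
    t: MembershipTriplet, *, eps: float = EPSILON
) -> FirstSectorRepresentation:
    """Deterministic closed-form C^3 representation of a feasible triplet.

    The construction fixes the free parameters of the solution family at
    lambda = kappa = 1/2 and resolves phases in closed form:

    * rank-1 branch (mu(A)+mu(B) <= 1; projector onto e1):
      |A> = (sqrt(muA), sqrt((1-muA)/2), sqrt((1-muA)/2)) real;
      |B>'s amplitudes likewise from muB, with relative phases
      gamma1 = arccos(I / sqrt(muA muB)) carrying the interference
      I = mu(AB) - ave, and gamma2/3 = pi + gamma1 +/- delta with
      delta = arccos(sqrt(muA muB) / sqrt((1-muA)(1-muB))) enforcing
      orthogonality.
    * rank-2 branch (mu(A)+mu(B) >= 1; projector onto span(e1, e2)):
      mirror construction with cos gamma3 = -I / sqrt((1-muA)(1-muB)) and
      delta = arccos(sqrt((1-muA)(1-muB)) / sqrt(muA muB)).
    * all-zero / all-one triplets short-circuit to the rank-0 / rank-3
      projector with canonical orthonormal states.

    At mu(A)+mu(B) = 1 both branches apply; the rank-1 branch is used.
    Positive sine branches are taken throughout, fixing the representative
    uniquely.  Raises :class:`RepresentabilityError` when mu(AB) falls
    outside the feasibility interval.
    """
    mu_a, mu_b, mu_ab = t.mu_a, t.mu_b, t.mu_ab
    interval = feasibility_interval(mu_a, mu_b)
    if not interval.contains(mu_ab, eps=eps):
        raise RepresentabilityError(
            f"mu_ab={mu_ab} outside first-sector feasibility interval "
            f"[{interval.lo:.12g}, {interval.hi:.12g}] for exemplar {t.exemplar!r}",
            detail={"lo": interval.lo, "hi": interval.hi, "ave": interval.ave,
                    "dev": interval.dev, "mu_ab": mu_ab},
        )

    e1 = np.array([1.0, 0.0, 0.0], dtype=complex)
    e2 = np.array([0.0, 1.0, 0.0], dtype=complex)
    interference = mu_ab - interval.ave

    if mu_a <= eps and mu_b <= eps:  # mu_ab forced to ~0 by the interval
        params = SolverParameters("rank0", 0.5, 0.5, 0.0, 0.0, 0.0)
        return FirstSectorRepresentation(e1, e2, linalg.canonical_projector(3, 0), params, t)
    if mu_a >= 1.0 - eps and mu_b >= 1.0 - eps:
        params = SolverParameters("rank3", 0.5, 0.5, 0.0, 0.0, 0.0)
        return FirstSectorRepresentation(e1, e2, linalg.canonical_projector(3, 3), params, t)

    lam = kap = 0.5
    if mu_a + mu_b <= 1.0:
        g1, g2, g3 = _rank1_phases(mu_a, mu_b, interference)
        a = np.array(
            [math.sqrt(mu_a), math.sqrt(lam * (1 - mu_a)), math.sqrt((1 - lam) * (1 - mu_a))],
            dtype=complex,
        )
        b_amp = [math.sqrt(mu_b), math.sqrt(kap * (1 - mu_b)), math.sqrt((1 - kap) * (1 - mu_b))]
        branch, rank = "rank1", 1
    else:
        g1, g2, g3 = _rank2_phases(mu_a, mu_b, interference)
        a = np.array(
            [math.sqrt(lam * mu_a), math.sqrt((1 - lam) * mu_a), math.sqrt(1 - mu_a)],
            dtype=complex,
        )
        b_amp = [math.sqrt(kap * mu_b), math.sqrt((1 - kap) * mu_b), math.sqrt(1 - mu_b)]
        branch, rank = "rank2", 2

    b = np.array(
        [
            b_amp[0] * complex(math.cos(g1), math.sin(g1)),
            b_amp[1] * complex(math.cos(g2), math.sin(g2)),
            b_amp[2] * complex(math.cos(g3), math.sin(g3)),
        ],
        dtype=complex,
    )
    params = SolverParameters(branch, lam, kap, g1, g2, g3)
    return FirstSectorRepresentation(a, b, linalg.canonical_projector(3, rank), params, t)


def verify_representation(rep: FirstSectorRepresentation) -> dict[str, float]:
    """Residuals of the five defining conditions plus the membership formula."""
    a, b, m = rep.state_a, rep.state_b, rep.projector
    t = rep.triplet
    lhs16 = 0.5 * (t.mu_a + t.mu_b) + float(np.vdot(a, m @ b).real)
    return {
        "norm_a": abs(float(np.vdot(a, a).real) - 1.0),
        "norm_b": abs(float(np.vdot(b, b).real) - 1.0),
        "orthogonality": abs(np.vdot(a, b)),
        "membership_a": abs(float(np.vdot(a, m @ a).real) - t.mu_a),
        "membership_b": abs(float(np.vdot(b, m @ b).real) - t.mu_b),
        "membership_ab": abs(lhs16 - t.mu_ab),
    }


@dataclass(frozen=True)
class UnifiedFirstSectorModel:
    """Many exemplars under one conceptual state pair in a shared basis.

    ``state_a`` and ``state_b`` are the canonical (1,0,0) and (0,1,0); each
    exemplar i carries its own projector M_i = U_i Mhat_i U_i^-1, where U_i
    rotates that exemplar's private basis {|A_i>, |B_i>, |C_i>} onto the
    canonical one.  All membership expectations are preserved exactly.
    """

    state_a: np.ndarray
    state_b: np.ndarray
    exemplars: list[str]
    projectors: list[np.ndarray]
    unitaries: list[np.ndarray]
    triplets: list[MembershipTriplet]

    def __len__(self) -> int:
        return len(self.exemplars)

    def membership(self, i: int) -> tuple[float, float, float]:
        """(mu_a, mu_b, mu_ab) re-evaluated from the unified model."""
        m = self.projectors[i]
        mu_a = float(np.vdot(self.state_a, m @ self.state_a).real)
        mu_b = float(np.vdot(self.state_b, m @ self.state_b).real)
        mu_ab = 0.5 * (mu_a + mu_b) + float(np.vdot(self.state_a, m @ self.state_b).real)
        return mu_a, mu_b, mu_ab


def unify(reps: list[FirstSectorRepresentation], *, tol: float = 1e-8) -> UnifiedFirstSectorModel:
    """Rotate per-exemplar representations into one canonical basis.

    For each representation, the private orthonormal basis is completed with
    |C_i> orthogonal to |A_i> and |B_i>; the basis-change unitary U_i maps it
    onto the canonical basis of C^3, and the projector is conjugated along.
    """
    canonical = [np.eye(3, dtype=complex)[k] for k in range(3)]
    exemplars, projectors, unitaries, triplets = [], [], [], []
    for rep in reps:
        res = verify_representation(rep)
        if max(res.values()) > tol:
            raise ValidationError(
                f"invalid member representation for {rep.triplet.exemplar!r}: {res}"
            )
        c = linalg.hermitian_orthogonal_complement_3d(rep.state_a, rep.state_b)
        u = linalg.build_basis_change([rep.state_a, rep.state_b, c], canonical)
        projectors.append(linalg.conjugate_operator(rep.projector, u))
        unitaries.append(u)
        exemplars.append(rep.triplet.exemplar)
        triplets.append(rep.triplet)
    return UnifiedFirstSectorModel(
        state_a=canonical[0],
        state_b=canonical[1],
        exemplars=exemplars,
        projectors=projectors,
        unitaries=unitaries,
        triplets=triplets,
    )
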