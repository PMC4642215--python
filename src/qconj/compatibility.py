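"""Commutator-based compatibility analysis of exemplar measurements.

Two measurement operators expressed in the same basis represent compatible
observables iff their commutator [M1, M2] = M1 M2 - M2 M1 vanishes.  In a
unified representation every exemplar's membership operators share one
basis, so pairwise compatibility becomes a computable property: nonzero
commutator expectation values on the conceptual state(s) predict order
effects in sequential membership judgements.

First-sector reports evaluate, for exemplars i and j with projectors M_i,
M_j and canonical states |A> = (1,0,0), |B> = (0,1,0):

    c_A  = <A|[M_i, M_j]|A>,   c_B = <B|[M_i, M_j]|B>,
    c_AB = (1/2) (<A| + <B|) [M_i, M_j] (|A> + |B>)

(the superposition state is left unnormalized; the 1/2 prefactor
compensates).  Second-sector reports evaluate the three commutators of the
operator triples on the shared state |C> = |1>(x)|1>.  For Hermitian
operators every such expectation is purely imaginary; with the package's
all-real tensor constructions the second-sector values vanish identically —
the tensor (classical) model always yields compatible measurements.

Note the first-sector c-values depend on the solver's phase conventions
(representations are far from unique), so only their zero/nonzero structure
is convention-independent; magnitudes are reported for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionError, QconjError
from .first_sector import UnifiedFirstSectorModel
from .second_sector import ZeroTypeModel

#: magnitude below which a commutator expectation counts as compatible
COMPAT_TOL = 1e-10


def commutator_expectation(m1: np.ndarray, m2: np.ndarray, state: np.ndarray) -> complex:
    """<v|(M1 M2 - M2 M1)|v> — purely imaginary for Hermitian M1, M2."""
    m1 = np.asarray(m1, dtype=complex)
    m2 = np.asarray(m2, dtype=complex)
    v = np.asarray(state, dtype=complex).ravel()
    if m1.shape != m2.shape or m1.shape[0] != v.shape[0]:
        raise DimensionError(
            f"shape mismatch: {m1.shape}, {m2.shape}, state {v.shape}"
        )
    comm = m1 @ m2 - m2 @ m1
    return complex(np.vdot(v, comm @ v))


@dataclass(frozen=True)
class CompatibilityReport:
    """Commutator expectation values for one exemplar pair.

    ``c_a``, ``c_b``, ``c_ab`` are the raw complex values (first-sector
    c or second-sector c' variants, depending on ``sector``); the boolean
    flags apply :data:`COMPAT_TOL` to their magnitudes.
    """

    exemplar_pair: tuple[str, str]
    sector: str
    c_a: complex
    c_b: complex
    c_ab: complex
    tol: float = COMPAT_TOL

    @property
    def compatible_a(self) -> bool:
        return abs(self.c_a) < self.tol

    @property
    def compatible_b(self) -> bool:
        return abs(self.c_b) < self.tol

    @property
    def compatible_ab(self) -> bool:
        return abs(self.c_ab) < self.tol

    @property
    def compatible(self) -> bool:
        return self.compatible_a and self.compatible_b and self.compatible_ab

    @property
    def max_magnitude(self) -> float:
        return max(abs(self.c_a), abs(self.c_b), abs(self.c_ab))

    def to_dict(self) -> dict:
        return {
            "exemplar_pair": list(self.exemplar_pair),
            "sector": self.sector,
            "c_a": [self.c_a.real, self.c_a.imag],
            "c_b": [self.c_b.real, self.c_b.imag],
            "c_ab": [self.c_ab.real, self.c_ab.imag],
            "magnitude_a": abs(self.c_a),
            "magnitude_b": abs(self.c_b),
            "magnitude_ab": abs(self.c_ab),
            "compatible_a": self.compatible_a,
            "compatible_b": self.compatible_b,
            "compatible_ab": self.compatible_ab,
            "compatible": self.compatible,
        }


def first_sector_compatibility(
    model: UnifiedFirstSectorModel, i: int, j: int, *, tol: float = COMPAT_TOL
) -> CompatibilityReport:
    """Compatibility of exemplars i and j in a unified C^3 model."""
    if not (0 <= i < len(model) and 0 <= j < len(model)):
        raise IndexError(f"exemplar index out of range: {i}, {j}")
    m1, m2 = model.projectors[i], model.projectors[j]
    a, b = model.state_a, model.state_b
    superpos = a + b  # unnormalized; 1/2 prefactor below compensates
    comm = m1 @ m2 - m2 @ m1
    return CompatibilityReport(
        exemplar_pair=(model.exemplars[i], model.exemplars[j]),
        sector="first",
        c_a=complex(np.vdot(a, comm @ a)),
        c_b=complex(np.vdot(b, comm @ b)),
        c_ab=0.5 * complex(np.vdot(superpos, comm @ superpos)),
        tol=tol,
    )


def second_sector_compatibility(
    model: ZeroTypeModel, i: int, j: int, *, tol: float = COMPAT_TOL
) -> CompatibilityReport:
    """Compatibility of exemplars i and j in a unified zero-type tensor model."""
    if not (0 <= i < len(model) and 0 <= j < len(model)):
        raise IndexError(f"exemplar index out of range: {i}, {j}")
    c = model.state_vector
    ops_i, ops_j = model.operators[i], model.operators[j]
    return CompatibilityReport(
        exemplar_pair=(model.exemplars[i], model.exemplars[j]),
        sector="second",
        c_a=commutator_expectation(ops_i[0], ops_j[0], c),
        c_b=commutator_expectation(ops_i[1], ops_j[1], c),
        c_ab=commutator_expectation(ops_i[2], ops_j[2], c),
        tol=tol,
    )


def pairwise_matrix(
    model: UnifiedFirstSectorModel | ZeroTypeModel, *, tol: float = COMPAT_TOL
) -> list[list[CompatibilityReport]]:
    """All-pairs compatibility reports (diagonal included, trivially zero)."""
    k = len(model)
    if k < 2:
        raise QconjError("pairwise compatibility needs at least 2 exemplars")
    if isinstance(model, UnifiedFirstSectorModel):
        f = lambda i, j: first_sector_compatibility(model, i, j, tol=tol)  # noqa: E731
    else:
        f = lambda i, j: second_sector_compatibility(model, i, j, tol=tol)  # noqa: E731
    return [[f(i, j) for j in range(k)] for i in range(k)]
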