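"""Complex linear-algebra primitives shared by both sectors.

Conventions used throughout the package:

* Inner product conjugate-linear in the *left* argument:
  ``<u|v> = sum_k conj(u_k) v_k`` (``numpy.vdot`` order).
* Constructed basis vectors are phase-fixed so their first nonzero
  component is real nonnegative, making every construction reproducible
  bit-for-bit.
* Basis-change unitaries are built as ``U = sum_k |target_k><source_k|``,
  so ``U`` maps the k-th source basis vector to the k-th target basis
  vector; operators move between bases by conjugation ``U M U^-1``, which
  preserves every expectation value ``<v|M|w>`` along with rank,
  Hermiticity and idempotence.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DimensionError, ValidationError

UNIT_TOL = 1e-12
OP_TOL = 1e-10


# ---------------------------------------------------------------------------
# vectors


def as_unit_vector(v: np.ndarray, *, tol: float = UNIT_TOL) -> np.ndarray:
    """Validate and return a complex unit vector (squared norm 1 within tol)."""
    v = np.asarray(v, dtype=complex).ravel()
    nrm2 = float(np.vdot(v, v).real)
    if abs(nrm2 - 1.0) > tol:
        raise ValidationError(f"not a unit vector: |v|^2 = {nrm2!r}")
    return v


def normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=complex).ravel()
    nrm = float(np.linalg.norm(v))
    if nrm == 0.0:
        raise ValidationError("cannot normalize the zero vector")
    return v / nrm


def fix_phase(v: np.ndarray, *, tol: float = 1e-12) -> np.ndarray:
    """Rotate a global phase so the first nonzero component is real >= 0."""
    v = np.asarray(v, dtype=complex).ravel()
    for x in v:
        if abs(x) > tol:
            return v * (abs(x) / x)
    return v


def hermitian_orthogonal_complement_3d(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Third basis vector orthogonal to two orthonormal vectors in C^3.

    The component-wise cross product of complex vectors is orthogonal to the
    inputs only under the *bilinear* form; under the Hermitian inner product
    the correct completion is the complex conjugate of the cross product,
    normalized and phase-fixed.
    """
    a = as_unit_vector(a)
    b = as_unit_vector(b)
    if a.shape != (3,) or b.shape != (3,):
        raise DimensionError("inputs must live in C^3")
    c = np.conj(np.cross(a, b))
    return fix_phase(normalize(c))


def complete_orthonormal_basis(
    vectors: list[np.ndarray] | tuple[np.ndarray, ...], dim: int, *, tol: float = 1e-8
) -> list[np.ndarray]:
    """Extend an orthonormal set to a full orthonormal basis of C^dim.

    Deterministic completion: modified Gram-Schmidt seeded by canonical
    basis vectors, at each step orthogonalizing the canonical vector whose
    residual has the largest norm (ties broken by lowest index), then
    phase-fixing.  Identical input therefore yields identical output.
    """
    vs = [as_unit_vector(v) for v in vectors]
    for v in vs:
        if v.shape != (dim,):
            raise DimensionError(f"vector of dim {v.shape[0]} in C^{dim} completion")
    if len(vs) > dim:
        raise DimensionError(f"{len(vs)} vectors cannot be orthonormal in C^{dim}")
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            if abs(np.vdot(vs[i], vs[j])) > tol:
                raise ValidationError("input vectors are not orthonormal")

    basis = list(vs)
    while len(basis) < dim:
        residuals = []
        for k in range(dim):
            e = np.zeros(dim, dtype=complex)
            e[k] = 1.0
            r = e.copy()
            for u in basis:
                r = r - np.vdot(u, r) * u
            residuals.append(r)
        norms = np.array([np.linalg.norm(r) for r in residuals])
        k_best = int(np.argmax(norms))  # argmax takes the lowest index on ties
        if norms[k_best] < 1e-12:
            raise ValidationError("cannot complete basis: residuals all vanish")
        # second MGS pass for numerical orthogonality
        r = residuals[k_best]
        for u in basis:
            r = r - np.vdot(u, r) * u
        basis.append(fix_phase(normalize(r)))
    return basis


# ---------------------------------------------------------------------------
# projectors


def as_projector(m: np.ndarray, *, tol: float = OP_TOL) -> np.ndarray:
    """Validate an orthogonal projector: Hermitian, idempotent, integer trace."""
    m = np.asarray(m, dtype=complex)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DimensionError(f"projector must be square, got {m.shape}")
    if np.max(np.abs(m - m.conj().T)) > tol:
        raise ValidationError("projector is not Hermitian")
    if np.max(np.abs(m @ m - m)) > tol:
        raise ValidationError("projector is not idempotent")
    rank = float(np.trace(m).real)
    if abs(rank - round(rank)) > tol:
        raise ValidationError(f"projector trace {rank} is not an integer")
    return m


def projector_rank(m: np.ndarray) -> int:
    return int(round(float(np.trace(m).real)))


def projector_onto(vectors: list[np.ndarray]) -> np.ndarray:
    """Orthogonal projector onto the span of an orthonormal set."""
    dim = np.asarray(vectors[0]).shape[0]
    p = np.zeros((dim, dim), dtype=complex)
    for v in vectors:
        v = as_unit_vector(v)
        p += np.outer(v, v.conj())
    return p


def canonical_projector(dim: int, rank: int) -> np.ndarray:
    """diag(1,...,1,0,...,0) with ``rank`` ones."""
    if not 0 <= rank <= dim:
        raise DimensionError(f"rank {rank} out of range for dim {dim}")
    return np.diag([1.0 + 0j] * rank + [0.0 + 0j] * (dim - rank))


# ---------------------------------------------------------------------------
# unitaries


def build_basis_change(
    source: list[np.ndarray], target: list[np.ndarray], *, tol: float = 1e-8
) -> np.ndarray:
    """Unitary ``U = sum_k |target_k><source_k|`` mapping source_k to target_k."""
    if len(source) != len(target):
        raise DimensionError("source and target bases differ in length")
    dim = np.asarray(source[0]).shape[0]
    if len(source) != dim:
        raise DimensionError("bases must be complete (length == dim)")
    for basis in (source, target):
        vs = [as_unit_vector(v) for v in basis]
        for i in range(dim):
            if vs[i].shape != (dim,):
                raise DimensionError("basis vector of wrong dimension")
            for j in range(i + 1, dim):
                if abs(np.vdot(vs[i], vs[j])) > tol:
                    raise ValidationError("basis is not orthonormal")
    u = np.zeros((dim, dim), dtype=complex)
    for s, t in zip(source, target):
        u += np.outer(np.asarray(t, dtype=complex), np.asarray(s, dtype=complex).conj())
    return u


def is_unitary(u: np.ndarray, *, tol: float = OP_TOL) -> bool:
    u = np.asarray(u, dtype=complex)
    eye = np.eye(u.shape[0])
    return (
        np.max(np.abs(u.conj().T @ u - eye)) <= tol
        and np.max(np.abs(u @ u.conj().T - eye)) <= tol
    )


def conjugate_operator(op: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Return ``U op U^-1`` (with ``U^-1 = U^dagger`` for unitary ``U``)."""
    op = np.asarray(op, dtype=complex)
    u = np.asarray(u, dtype=complex)
    if op.shape != u.shape:
        raise DimensionError(f"operator {op.shape} vs unitary {u.shape}")
    return u @ op @ u.conj().T


# ---------------------------------------------------------------------------
# C^n (x) C^n  <->  C^(n^2) isomorphism


def tensor_to_vec(coeffs: np.ndarray) -> np.ndarray:
    """Map a coefficient matrix c_ij on C^n (x) C^n to a vector in C^(n^2).

    The relabeling is (i, j) -> n(i-1)+j in 1-based terms, i.e. row-major
    flattening; it sends |1>(x)|1> to e1 and |n>(x)|n> to the last canonical
    vector, and is the inverse of :func:`vec_to_tensor`.
    """
    coeffs = np.asarray(coeffs, dtype=complex)
    if coeffs.ndim != 2 or coeffs.shape[0] != coeffs.shape[1]:
        raise DimensionError(f"coefficient matrix must be square, got {coeffs.shape}")
    return coeffs.reshape(-1)


def vec_to_tensor(v: np.ndarray, n: int) -> np.ndarray:
    v = np.asarray(v, dtype=complex).ravel()
    if v.shape[0] != n * n:
        raise DimensionError(f"vector of length {v.shape[0]} is not C^{n}^2")
    return v.reshape(n, n)


def kron_factor_identity(m: np.ndarray, side: str) -> np.ndarray:
    """``M (x) 1`` (side='left') or ``1 (x) M`` (side='right') as a C^(n^2) matrix."""
    m = np.asarray(m, dtype=complex)
    eye = np.eye(m.shape[0], dtype=complex)
    if side == "left":
        return np.kron(m, eye)
    if side == "right":
        return np.kron(eye, m)
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def split_as_kron_with_identity(op: np.ndarray, n: int, side: str, *, tol: float = 1e-10):
    """If ``op`` on C^(n^2) equals ``X (x) 1`` (side='left') or ``1 (x) X``
    (side='right'), return the n-by-n factor ``X``; else return None.

    Used to detect when a unified tensor-space operator is unentangled,
    i.e. acts on only one factor of the product space.
    """
    op = np.asarray(op, dtype=complex)
    if op.shape != (n * n, n * n):
        raise DimensionError(f"operator {op.shape} is not on C^{n}^2")
    t = op.reshape(n, n, n, n)  # t[i, j, k, l] = <ij| op |kl>
    if side == "left":
        # X (x) 1: t[i,j,k,l] = X[i,k] delta_{jl}
        x = np.trace(t, axis1=1, axis2=3) / n
        rebuilt = np.kron(x, np.eye(n))
    else:
        x = np.trace(t, axis1=0, axis2=2) / n
        rebuilt = np.kron(np.eye(n), x)
    if np.max(np.abs(rebuilt - op)) <= tol:
        return x
    return None


# ---------------------------------------------------------------------------
# JSON serialization helpers


def complex_to_json(arr: np.ndarray) -> list:
    """Nested [re, im] pairs for complex arrays (JSON-safe)."""
    arr = np.asarray(arr, dtype=complex)
    if arr.ndim == 1:
        return [[float(x.real), float(x.imag)] for x in arr]
    return [complex_to_json(row) for row in arr]


def json_to_complex(data: list) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    return arr[..., 0] + 1j * arr[..., 1]
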