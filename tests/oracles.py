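"""Independent numerical oracles used to cross-check the closed-form solvers.

These deliberately avoid the package's constructive formulas: classicality
is decided by linear-programming feasibility of the underlying joint
distribution, and representability in either sector by randomized
least-squares searches over raw state/projector parameters.
"""

import numpy as np
from scipy.optimize import least_squares, linprog


def kolmogorov_polytope_feasible(mu_a, mu_b, mu_ab, tol=1e-9):
    """Does a 4-atom pmf (p11, p12, p21, p22) with the right marginals exist?

    Constraints: p >= 0, sum p = 1, p11 + p12 = mu_a, p11 + p21 = mu_b,
    p11 = mu_ab.  Solved as an LP feasibility problem.
    """
    a_eq = np.array([
        [1.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 0.0],
        [1.0, 0.0, 1.0, 0.0],
        [1.0, 0.0, 0.0, 0.0],
    ])
    b_eq = np.array([1.0, mu_a, mu_b, mu_ab])
    res = linprog(np.zeros(4), A_eq=a_eq, b_eq=b_eq, bounds=[(0, 1)] * 4,
                  method="highs")
    if not res.success:
        return False
    return float(np.max(np.abs(a_eq @ res.x - b_eq))) <= tol


def _first_sector_residuals(params, mu_a, mu_b, mu_ab, rank):
    va = params[0:6:2] + 1j * params[1:6:2]
    vb = params[6:12:2] + 1j * params[7:12:2]
    m = np.zeros((3, 3), dtype=complex)
    for k in range(rank):
        m[k, k] = 1.0
    ip = np.vdot(va, vb)
    return np.array([
        np.vdot(va, va).real - 1.0,
        np.vdot(vb, vb).real - 1.0,
        ip.real,
        ip.imag,
        np.vdot(va, m @ va).real - mu_a,
        np.vdot(vb, m @ vb).real - mu_b,
        0.5 * (mu_a + mu_b) + np.vdot(va, m @ vb).real - mu_ab,
    ])


def first_sector_search(mu_a, mu_b, mu_ab, rng, starts=6, tol=1e-8):
    """Randomized numerical search for states/projector in C^3 satisfying the
    five defining conditions plus the membership formula.

    The projector is taken canonical of rank 1 or 2 without loss of
    generality (the conditions are invariant under a global unitary); the
    twelve complex state components are free.  Returns True if any start of
    scipy's least-squares reaches residual norm below ``tol``.
    """
    if mu_a <= 1e-12 and mu_b <= 1e-12:
        return mu_ab <= 1e-9
    if mu_a >= 1 - 1e-12 and mu_b >= 1 - 1e-12:
        return mu_ab >= 1 - 1e-9
    for rank in (1, 2):
        for _ in range(starts):
            x0 = rng.normal(size=12)
            x0 /= np.linalg.norm(x0) / np.sqrt(2.0)
            sol = least_squares(
                _first_sector_residuals, x0, args=(mu_a, mu_b, mu_ab, rank),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
            if np.linalg.norm(sol.fun) < tol:
                return True
    return False


def _tensor_residuals(params, mu_a, mu_b, mu_ab):
    c = params[0:8:2] + 1j * params[1:8:2]            # state in C^4
    u = params[8:12:2] + 1j * params[9:12:2]          # rank-1 projector axis
    nu = np.vdot(u, u).real
    m = np.outer(u, u.conj()) / (nu if nu > 1e-12 else 1.0)
    eye = np.eye(2)
    ma, mb, mab = np.kron(m, eye), np.kron(eye, m), np.kron(m, m)
    return np.array([
        np.vdot(c, c).real - 1.0,
        nu - 1.0,
        np.vdot(c, ma @ c).real - mu_a,
        np.vdot(c, mb @ c).real - mu_b,
        np.vdot(c, mab @ c).real - mu_ab,
    ])


def tensor_search(mu_a, mu_b, mu_ab, rng, starts=6, tol=1e-8):
    """Randomized search for a C^2 (x) C^2 state and rank-1 factor projector
    reproducing the triplet as tensor expectation values.

    Rank-0 and rank-2 projectors only reach the all-zero / all-one triplets,
    which are checked directly.
    """
    if mu_a <= 1e-9 and mu_b <= 1e-9 and mu_ab <= 1e-9:
        return True
    if mu_a >= 1 - 1e-9 and mu_b >= 1 - 1e-9 and mu_ab >= 1 - 1e-9:
        return True
    for _ in range(starts):
        x0 = rng.normal(size=12)
        sol = least_squares(
            _tensor_residuals, x0, args=(mu_a, mu_b, mu_ab),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        if np.linalg.norm(sol.fun) < tol:
            return True
    return False


def random_projector(dim, rank, rng):
    """Haar-ish random orthogonal projector of given rank via QR."""
    z = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    q, _ = np.linalg.qr(z)
    cols = q[:, :rank]
    return cols @ cols.conj().T


def random_unitary(dim, rng):
    z = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    q, r = np.linalg.qr(z)
    return q * (np.diag(r) / np.abs(np.diag(r)))


def random_unit_vector(dim, rng):
    v = rng.normal(size=dim) + 1j * rng.normal(size=dim)
    return v / np.linalg.norm(v)
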