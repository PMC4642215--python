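"""Two-sector Fock-space membership formula and parameter fitting.

The two modes of conjunction — emergent (first sector, Hilbert space H) and
logical (second sector, H (x) H) — combine in the two-sector Fock space
F = H (+) (H (x) H).  With sector weight n in [0, 1] the membership weight
of an exemplar for the conjunction is

    mu(AB) = n^2 * ((mu(A) + mu(B)) / 2 + I) + (1 - n^2) * mu(A) mu(B),

where I = Re <A|M|B> is the first-sector interference term, bounded by
|I| <= sqrt(mu(A) mu(B)).  At n = 1 the formula is the interference-shifted
average; at n = 0 it is the classical independent product.  The membership
operator is the direct sum M_F = M (+) (M (x) M), whose two sector
expectations are exactly the two additive terms above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import EPSILON, MembershipTriplet
from .exceptions import ValidationError

#: grid step for the sector-weight scan in :func:`fit_fock`
N_GRID_STEP = 0.01


def interference_bound(mu_a: float, mu_b: float) -> float:
    """Largest attainable |Re <A|M|B>| in the first sector: sqrt(mu_a mu_b)."""
    if not (0.0 <= mu_a <= 1.0 and 0.0 <= mu_b <= 1.0):
        raise ValidationError("membership weights must lie in [0, 1]")
    return math.sqrt(mu_a * mu_b)


@dataclass(frozen=True)
class FockParameters:
    """Sector weight n in [0, 1] and interference term I = Re <A|M|B>."""

    n: float
    interference: float
    feasible: bool = True


def fock_membership(
    mu_a: float, mu_b: float, params: FockParameters, *, eps: float = EPSILON
) -> float:
    """Evaluate the two-sector membership formula.

    Raises if the interference term exceeds its first-sector bound.
    """
    bound = interference_bound(mu_a, mu_b)
    if abs(params.interference) > bound + eps:
        raise ValidationError(
            f"interference {params.interference} exceeds bound {bound}"
        )
    if not 0.0 <= params.n <= 1.0:
        raise ValidationError(f"sector weight n={params.n} outside [0, 1]")
    n2 = params.n**2
    ave = 0.5 * (mu_a + mu_b)
    return n2 * (ave + params.interference) + (1.0 - n2) * mu_a * mu_b


def _required_interference(t: MembershipTriplet, n: float) -> float | None:
    """Interference that reproduces mu(AB) at sector weight n, or None at n=0."""
    n2 = n * n
    if n2 == 0.0:
        return None
    ave = 0.5 * (t.mu_a + t.mu_b)
    return (t.mu_ab - (1.0 - n2) * t.mu_a * t.mu_b) / n2 - ave


def fit_fock(t: MembershipTriplet, *, eps: float = EPSILON) -> FockParameters:
    """Deterministic representative (n, I) reproducing a triplet's mu(AB).

    The solution set is a continuum; the representative prefers the largest
    sector weight: n = 1 with I = mu(AB) - ave when that I is within the
    interference bound, otherwise a downward scan of n on a 0.01 grid for
    the largest feasible weight.  If no (n, I) on the grid reproduces
    mu(AB), an infeasible result is returned (feasible=False).
    """
    bound = interference_bound(t.mu_a, t.mu_b)
    steps = int(round(1.0 / N_GRID_STEP))
    for k in range(steps + 1):
        n = 1.0 - k * N_GRID_STEP
        if n > 0.0:
            req = _required_interference(t, n)
            assert req is not None
            if abs(req) <= bound + eps:
                return FockParameters(n=n, interference=req, feasible=True)
        else:
            if abs(t.mu_ab - t.mu_a * t.mu_b) <= eps:
                return FockParameters(n=0.0, interference=0.0, feasible=True)
    return FockParameters(n=float("nan"), interference=float("nan"), feasible=False)


def fit_fock_dataset(
    ts: list[MembershipTriplet], *, shared_n: bool = False, eps: float = EPSILON
) -> list[FockParameters]:
    """Fit Fock parameters for a whole dataset.

    By default each exemplar is fitted independently.  With ``shared_n``
    a single sector weight is used for all exemplars: the largest n on the
    grid at which every exemplar's required interference is within bound
    (infeasible for all if no such n exists).
    """
    if not shared_n:
        return [fit_fock(t, eps=eps) for t in ts]
    steps = int(round(1.0 / N_GRID_STEP))
    for k in range(steps + 1):
        n = 1.0 - k * N_GRID_STEP
        params: list[FockParameters] = []
        ok = True
        for t in ts:
            if n > 0.0:
                req = _required_interference(t, n)
                assert req is not None
                if abs(req) <= interference_bound(t.mu_a, t.mu_b) + eps:
                    params.append(FockParameters(n=n, interference=req))
                else:
                    ok = False
                    break
            else:
                if abs(t.mu_ab - t.mu_a * t.mu_b) <= eps:
                    params.append(FockParameters(n=0.0, interference=0.0))
                else:
                    ok = False
                    break
        if ok:
            return params
    return [
        FockParameters(n=float("nan"), interference=float("nan"), feasible=False)
        for _ in ts
    ]


def fock_operator(m_first: np.ndarray, m_second_factor: np.ndarray) -> np.ndarray:
    """Membership operator M_F = M (+) (M (x) M) as a block-diagonal matrix.

    ``m_first`` acts on the first sector (C^3); ``m_second_factor`` is the
    single-factor projector whose tensor square acts on the second sector.
    The two diagonal blocks' expectations are the two additive terms of the
    membership formula.
    """
    m1 = np.asarray(m_first, dtype=complex)
    m2 = np.kron(m_second_factor, m_second_factor)
    d1, d2 = m1.shape[0], m2.shape[0]
    out = np.zeros((d1 + d2, d1 + d2), dtype=complex)
    out[:d1, :d1] = m1
    out[d1:, d1:] = m2
    return out
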