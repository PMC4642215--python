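"""Deterministic synthetic membership-triplet generator, by regime.

Regimes correspond to the acceptance regions of the theory:

* ``classical`` — triplets admitting a Kolmogorovian model, drawn by
  sampling a 4-atom joint probability vector uniformly from the simplex
  and marginalizing (classicality holds by construction).
* ``overextended_representable`` — non-classical (overextended) triplets
  that nevertheless lie inside the first-sector feasibility interval.
* ``first_sector_infeasible`` — conjunction weight outside the interval.
* ``independent`` — mu(AB) = mu(A) mu(B) exactly (classical, and with a
  product-state tensor representation).

Sampling is seeded and fully reproducible: identical config yields an
identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, MembershipTriplet, check_classical
from .exceptions import QconjError
from .first_sector import feasibility_interval

REGIMES = (
    "classical",
    "overextended_representable",
    "first_sector_infeasible",
    "independent",
)

#: rejection-sampling attempt cap per record
MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class GeneratorConfig:
    regime: str
    count: int
    seed: int
    concept_a: str = "A"
    concept_b: str = "B"

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise QconjError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.count <= 0:
            raise QconjError(f"count must be positive, got {self.count}")


def _simplex4(rng: np.random.Generator) -> np.ndarray:
    """Uniform draw from the 4-atom probability simplex (sorted spacings)."""
    cuts = np.sort(rng.uniform(0.0, 1.0, size=3))
    return np.diff(np.concatenate([[0.0], cuts, [1.0]]))


def _sample_one(regime: str, rng: np.random.Generator) -> tuple[float, float, float]:
    for _ in range(MAX_ATTEMPTS):
        if regime == "classical":
            p11, p12, p21, _ = _simplex4(rng)
            return p11 + p12, p11 + p21, p11
        if regime == "independent":
            mu_a, mu_b = rng.uniform(0.0, 1.0, size=2)
            return mu_a, mu_b, mu_a * mu_b
        mu_a, mu_b = rng.uniform(0.0, 1.0, size=2)
        interval = feasibility_interval(mu_a, mu_b)
        if regime == "overextended_representable":
            if interval.dev <= 1e-12:
                continue
            mu_ab = rng.uniform(interval.lo, interval.hi)
            mu_ab = min(1.0, max(0.0, mu_ab))
            if mu_ab > min(mu_a, mu_b) and interval.contains(mu_ab):
                return mu_a, mu_b, mu_ab
        elif regime == "first_sector_infeasible":
            mu_ab = rng.uniform(0.0, 1.0)
            if not interval.contains(mu_ab, eps=1e-6):
                return mu_a, mu_b, mu_ab
    raise QconjError(f"regime {regime!r}: no sample found in {MAX_ATTEMPTS} attempts")


def sample_dataset(cfg: GeneratorConfig) -> Dataset:
    """Generate ``cfg.count`` triplets from the configured regime."""
    rng = np.random.default_rng(cfg.seed)
    triplets = []
    for i in range(cfg.count):
        mu_a, mu_b, mu_ab = _sample_one(cfg.regime, rng)
        triplets.append(
            MembershipTriplet(
                exemplar=f"{cfg.regime}_{i:04d}",
                concept_a=cfg.concept_a,
                concept_b=cfg.concept_b,
                mu_a=float(mu_a),
                mu_b=float(mu_b),
                mu_ab=float(mu_ab),
            )
        )
    ds = Dataset(triplets)
    # post-condition: every sample verifiably lies in its regime's region
    for t in ds:
        if cfg.regime == "classical" and not check_classical(t).is_classical:
            raise QconjError(f"generator bug: non-classical sample {t}")
    return ds
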