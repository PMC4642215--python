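"""Membership-triplet data model, classicality checks and CSV/JSON I/O.

The universal input record of the package is a *membership triplet*: an
exemplar ``p`` together with the empirical membership weights mu(A), mu(B)
and mu(AB) of that exemplar with respect to two concepts A and B and their
conjunction "A and B".  A triplet is *classical conjunction data* when it
admits a Kolmogorovian probability model, which happens exactly when

    mu(AB) <= mu(A),    mu(AB) <= mu(B),    mu(A) + mu(B) - mu(AB) <= 1.

Violations of the first two inequalities are *overextension* (single or
double); violation of the third is the *Kolmogorovian factor violation*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import SchemaError, ValidationError

#: Tolerance for all classicality / feasibility inequality checks.
EPSILON = 1e-9

CSV_COLUMNS = ("exemplar", "concept_a", "concept_b", "mu_a", "mu_b", "mu_ab")


@dataclass(frozen=True)
class MembershipTriplet:
    """One exemplar's membership weights with respect to A, B and AB.

    Weights are dimensionless reals in [0, 1]; exact 0 and 1 are legal
    (degenerate but representable cases).
    """

    exemplar: str
    concept_a: str
    concept_b: str
    mu_a: float
    mu_b: float
    mu_ab: float

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_b", "mu_ab"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValidationError(f"{name} is not finite: {value!r}")
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"{name} out of range [0, 1]: {value!r} (exemplar {self.exemplar!r})"
                )

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.mu_a, self.mu_b, self.mu_ab)


def validate_triplet(record: Mapping[str, object], *, row: int | None = None) -> MembershipTriplet:
    """Build a :class:`MembershipTriplet` from a raw field map.

    Out-of-range weights are an error — they are never clamped.  The raised
    :class:`ValidationError` names the offending field and (when given) the
    input row.
    """
    where = "" if row is None else f" (row {row})"
    values: dict[str, object] = {}
    for name in ("exemplar", "concept_a", "concept_b"):
        if name not in record:
            raise SchemaError(f"missing field {name!r}{where}")
        values[name] = str(record[name])
    for name in ("mu_a", "mu_b", "mu_ab"):
        if name not in record:
            raise SchemaError(f"missing field {name!r}{where}")
        try:
            values[name] = float(record[name])  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"field {name!r} not parseable as real{where}: "
                                  f"{record[name]!r}") from exc
    try:
        return MembershipTriplet(**values)  # type: ignore[arg-type]
    except ValidationError as exc:
        raise ValidationError(f"{exc}{where}") from None


@dataclass(frozen=True)
class ClassicalityReport:
    """Outcome of the classicality check for one triplet.

    ``slack_*`` store the raw signed slack of each inequality (positive =
    satisfied with margin); the booleans apply the shared tolerance
    :data:`EPSILON`.  ``category`` is exactly one of ``classical``,
    ``single_overextension``, ``double_overextension``, ``kolmogorov_only``.
    """

    triplet: MembershipTriplet
    is_classical: bool
    overextended_a: bool
    overextended_b: bool
    kolmogorov_violation: bool
    category: str
    slack_a: float
    slack_b: float
    slack_k: float

    def to_dict(self) -> dict:
        return {
            "exemplar": self.triplet.exemplar,
            "mu_a": self.triplet.mu_a,
            "mu_b": self.triplet.mu_b,
            "mu_ab": self.triplet.mu_ab,
            "is_classical": self.is_classical,
            "overextended_a": self.overextended_a,
            "overextended_b": self.overextended_b,
            "kolmogorov_violation": self.kolmogorov_violation,
            "category": self.category,
            "slack_a": self.slack_a,
            "slack_b": self.slack_b,
            "slack_k": self.slack_k,
        }


def check_classical(t: MembershipTriplet, *, eps: float = EPSILON) -> ClassicalityReport:
    """Classify a triplet by the three classical-conjunction inequalities.

    The triplet is classical iff mu(AB) <= mu(A), mu(AB) <= mu(B) and
    mu(A)+mu(B)-mu(AB) <= 1, each checked with tolerance ``eps``.
    Equivalently (and this is what the tests cross-check) iff a 4-atom joint
    probability mass function with the right marginals exists.
    """
    slack_a = t.mu_a - t.mu_ab
    slack_b = t.mu_b - t.mu_ab
    slack_k = 1.0 - (t.mu_a + t.mu_b - t.mu_ab)

    over_a = slack_a < -eps
    over_b = slack_b < -eps
    kolm = slack_k < -eps
    classical = not (over_a or over_b or kolm)

    if classical:
        category = "classical"
    elif over_a and over_b:
        category = "double_overextension"
    elif over_a or over_b:
        category = "single_overextension"
    else:
        category = "kolmogorov_only"

    return ClassicalityReport(
        triplet=t,
        is_classical=classical,
        overextended_a=over_a,
        overextended_b=over_b,
        kolmogorov_violation=kolm,
        category=category,
        slack_a=slack_a,
        slack_b=slack_b,
        slack_k=slack_k,
    )


@dataclass
class Dataset:
    """An ordered collection of triplets sharing one (concept_a, concept_b) pair."""

    triplets: list[MembershipTriplet] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        pairs: set[tuple[str, str]] = set()
        for t in self.triplets:
            if t.exemplar in seen:
                raise SchemaError(f"duplicate exemplar id {t.exemplar!r}")
            seen.add(t.exemplar)
            pairs.add((t.concept_a, t.concept_b))
        if len(pairs) > 1:
            raise SchemaError(f"dataset mixes concept pairs: {sorted(pairs)}")

    def __len__(self) -> int:
        return len(self.triplets)

    def __iter__(self) -> Iterator[MembershipTriplet]:
        return iter(self.triplets)

    def __getitem__(self, i: int) -> MembershipTriplet:
        return self.triplets[i]

    @property
    def concept_pair(self) -> tuple[str, str] | None:
        if not self.triplets:
            return None
        return (self.triplets[0].concept_a, self.triplets[0].concept_b)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "exemplar": t.exemplar,
                    "concept_a": t.concept_a,
                    "concept_b": t.concept_b,
                    "mu_a": t.mu_a,
                    "mu_b": t.mu_b,
                    "mu_ab": t.mu_ab,
                }
                for t in self.triplets
            ],
            columns=list(CSV_COLUMNS),
        )


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset from CSV (comma-separated, UTF-8, dot decimal).

    Required header columns: exemplar, concept_a, concept_b, mu_a, mu_b,
    mu_ab.  File order is preserved.  Missing columns and duplicate exemplar
    identifiers raise :class:`SchemaError`.
    """
    try:
        frame = pd.read_csv(path, dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file with no header") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    triplets = [
        validate_triplet({c: rec[c] for c in CSV_COLUMNS}, row=i + 2)  # header is row 1
        for i, rec in enumerate(frame.to_dict(orient="records"))
    ]
    return Dataset(triplets)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    ds.to_frame().to_csv(path, index=False)


def classify_dataset(ds: Dataset, *, eps: float = EPSILON) -> list[ClassicalityReport]:
    return [check_classical(t, eps=eps) for t in ds]


def write_report(reports: Iterable[ClassicalityReport] | dict, path: str | Path) -> None:
    """Serialize classicality reports (or any JSON-ready mapping) to JSON."""
    if isinstance(reports, dict):
        payload = reports
    else:
        payload = {"classicality": [r.to_dict() for r in reports]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
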