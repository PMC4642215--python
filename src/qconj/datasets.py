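"""Bundled example datasets: membership triplets from Hampton's
concept-combination experiments, as used in the worked examples.

Three concept pairs ship with the package:

* ``machine_vehicle`` — "Machine" and "Vehicle": sailboat (classical) and
  skateboard (singly overextended but first-sector representable).
* ``building_dwelling`` — "Building" and "Dwelling": cave and synagogue,
  both classical.
* ``furniture_household_appliances`` — "Furniture" and "Household
  Appliances": filing cabinet (first-sector representable) and heated
  waterbed (outside the first-sector interval; handled by the Fock fit).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .data import Dataset, read_dataset

_NAMES = (
    "machine_vehicle",
    "building_dwelling",
    "furniture_household_appliances",
)


def available() -> tuple[str, ...]:
    return _NAMES


def load(name: str) -> Dataset:
    """Load a bundled dataset by name (see :func:`available`)."""
    if name not in _NAMES:
        raise KeyError(f"unknown dataset {name!r}; available: {_NAMES}")
    ref = resources.files("qconj").joinpath("fixtures", f"{name}.csv")
    with resources.as_file(ref) as path:
        return read_dataset(Path(path))


def load_machine_vehicle() -> Dataset:
    return load("machine_vehicle")


def load_building_dwelling() -> Dataset:
    return load("building_dwelling")


def load_furniture_household_appliances() -> Dataset:
    return load("furniture_household_appliances")
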