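"""Physical units and the packaged reference energy landscape.

Energies are stored in eV, times in fs, rates in fs^-1 throughout the
package; spin-orbit coupling constants are quoted in cm^-1 and converted
to eV only when a Hamiltonian is built.  This module provides the
conversions between the four unit systems the workflow touches (eV,
cm^-1, nm, fs^-1) and loads the packaged table of critical-point
energies of 2-thiocytosine (stationary points, conical intersections and
singlet-triplet minimum-energy crossing points) that the vibronic model
is calibrated against.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Literal

__all__ = [
    "EV_NM",
    "CM1_PER_EV",
    "HBAR_EV_FS",
    "HARTREE_EV",
    "EnergyValue",
    "convert_energy",
    "CriticalPoint",
    "CriticalPointTable",
    "load_critical_points",
    "load_soc_reference",
]

#: Photon-energy / wavelength product, eV * nm.
EV_NM = 1239.84198
#: Wavenumbers per electron-volt.
CM1_PER_EV = 8065.543937
#: Reduced Planck constant, eV * fs.
HBAR_EV_FS = 0.6582119569
#: Hartree in eV (used for the decoherence-constant default).
HARTREE_EV = 27.211386245988

Unit = Literal["eV", "cm^-1", "nm", "fs^-1"]

_RECIPROCAL_UNITS = {"nm"}  # units related to eV by x -> const / x


@dataclass(frozen=True)
class EnergyValue:
    """A scalar energy-like quantity tagged with its unit."""

    value: float
    unit: Unit

    def to(self, target_unit: Unit) -> "EnergyValue":
        return convert_energy(self, target_unit)


def _to_ev(x: EnergyValue) -> float:
    if x.unit == "eV":
        return x.value
    if x.unit == "cm^-1":
        return x.value / CM1_PER_EV
    if x.unit == "nm":
        if x.value <= 0:
            raise ValueError(f"wavelength must be positive, got {x.value} nm")
        return EV_NM / x.value
    if x.unit == "fs^-1":
        # E = hbar * omega with omega = 2*pi*nu?  No: we use E = hbar/tau
        # conventions nowhere; fs^-1 here means an angular rate E/hbar.
        return x.value * HBAR_EV_FS
    raise ValueError(f"unknown unit {x.unit!r}")


def _from_ev(ev: float, unit: Unit) -> float:
    if unit == "eV":
        return ev
    if unit == "cm^-1":
        return ev * CM1_PER_EV
    if unit == "nm":
        if ev <= 0:
            raise ValueError(f"energy must be positive to express in nm, got {ev} eV")
        return EV_NM / ev
    if unit == "fs^-1":
        return ev / HBAR_EV_FS
    raise ValueError(f"unknown unit {unit!r}")


def convert_energy(x: EnergyValue, target_unit: Unit) -> EnergyValue:
    """Convert ``x`` to ``target_unit``.

    nm <-> eV uses E[eV] = 1239.84198 / lambda[nm]; cm^-1 <-> eV uses
    8065.543937 cm^-1 per eV; fs^-1 <-> eV uses E = hbar * omega with
    hbar = 0.6582119569 eV fs.  Conversions round-trip to better than
    1e-12 relative.  Non-positive values are rejected whenever a
    reciprocal (nm) conversion is involved.
    """
    if x.unit in _RECIPROCAL_UNITS or target_unit in _RECIPROCAL_UNITS:
        if x.value <= 0:
            raise ValueError(
                f"non-positive value {x.value} cannot be converted "
                f"between reciprocal units ({x.unit} -> {target_unit})"
            )
    return EnergyValue(_from_ev(_to_ev(x), target_unit), target_unit)


@dataclass(frozen=True)
class CriticalPoint:
    """One entry of the reference landscape.

    ``kind`` is one of ``minimum``, ``CoIn``, ``MECP``, ``FC-point`` or
    ``barrier``; ``states`` holds one state label for a minimum/FC point
    and two labels joined by ``/`` for a crossing.  ``bound`` is ``eq``
    for a value quoted exactly and ``ge`` for a lower bound (the
    ground-state-recovery barrier is only bounded from below).
    """

    label: str
    kind: str
    states: tuple[str, ...]
    energy_eV: float
    bound: str = "eq"


@dataclass(frozen=True)
class CriticalPointTable:
    entries: tuple[CriticalPoint, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, label: str) -> CriticalPoint:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    with resources.files("thiodyn.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        return list(csv.DictReader(fh))


def load_critical_points() -> CriticalPointTable:
    """Load the packaged critical-point energies of 2-thiocytosine.

    All energies are MS-CASPT2 values in eV relative to the ground-state
    minimum: the Franck-Condon point of the bright 1pipi* state, the
    excited-state minima, the singlet and triplet conical intersections
    and the two singlet-triplet MECPs that open the intersystem-crossing
    funnel, plus the lower bound on the barrier towards ground-state
    recovery.
    """
    entries = []
    for row in _read_packaged_csv("critical_points.csv"):
        entries.append(
            CriticalPoint(
                label=row["label"],
                kind=row["kind"],
                states=tuple(row["states"].split("/")),
                energy_eV=float(row["energy_eV"]),
                bound=row["bound"],
            )
        )
    return CriticalPointTable(tuple(entries))


def load_soc_reference() -> dict[str, float]:
    """Packaged spin-orbit coupling magnitudes (cm^-1).

    Three distinct numbers are quoted for 2-thiocytosine and they refer
    to different geometries: the maximum near the singlet-triplet MECPs
    and two trajectory-ensemble averages (S1-T2 and S1-T1).  They are
    stored under distinct keys rather than conflated.
    """
    return {
        row["label"]: float(row["soc_cm1"])
        for row in _read_packaged_csv("soc_reference.csv")
    }
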