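"""Molecular formulas, adduct ions and exact-mass arithmetic.

Monoisotopic ion m/z values are computed from a pinned isotope-mass table
(CIAAW abundances, AME atomic masses) with explicit electron-mass
correction, so that e.g. the deprotonated ion of a tetrabrominated
bisphenol-S derivative reproduces instrument-software values to 1e-4 Da.
Heavy-isotope substitutions (the number of ⁸¹Br atoms, k) are first-class:
halogenated contaminants are routinely quantified on a mid-envelope
isotopologue rather than the monoisotopic peak.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "ELECTRON_MASS_DA",
    "AtomicMassTable",
    "MolecularFormula",
    "IonSpecies",
    "FormulaError",
    "parse_formula",
    "ion_mz",
    "ppm_error",
]

#: CODATA electron mass in Da.
ELECTRON_MASS_DA = 0.000548579909

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or impossible ion definitions."""


@dataclass(frozen=True)
class Isotope:
    element: str
    label: str  # e.g. "81Br"
    mass_da: float
    abundance: float


class AtomicMassTable:
    """Immutable per-isotope exact masses and natural abundances.

    The packaged default pins the constants every mass calculation in the
    package depends on; ``version`` identifies that snapshot.
    """

    def __init__(self, isotopes: list[Isotope], version: str,
                 electron_mass_da: float = ELECTRON_MASS_DA):
        by_element: dict[str, tuple[Isotope, ...]] = {}
        for iso in isotopes:
            if iso.mass_da <= 0:
                raise ValueError(f"non-positive mass for {iso.label}")
            by_element.setdefault(iso.element, ())
            by_element[iso.element] += (iso,)
        for el, isos in by_element.items():
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances for {el} sum to {total}, not 1")
            by_element[el] = tuple(sorted(isos, key=lambda i: i.mass_da))
        self._by_element = by_element
        self._by_label = {i.label: i for i in isotopes}
        self.version = version
        self.electron_mass_da = electron_mass_da

    @classmethod
    def default(cls) -> "AtomicMassTable":
        return _DEFAULT_TABLE

    @classmethod
    def from_csv(cls, path) -> "AtomicMassTable":
        version = "unversioned"
        isotopes = []
        with open(path, newline="") as fh:
            for line in fh:
                if line.startswith("#"):
                    m = re.search(r"version:\s*(\S+)", line)
                    if m:
                        version = m.group(1)
            fh.seek(0)
            rows = (r for r in fh if not r.startswith("#"))
            for rec in csv.DictReader(rows):
                isotopes.append(Isotope(rec["element"], rec["isotope"],
                                        float(rec["mass_da"]),
                                        float(rec["abundance"])))
        return cls(isotopes, version=version)

    def elements(self) -> tuple[str, ...]:
        return tuple(self._by_element)

    def isotopes(self, element: str) -> tuple[Isotope, ...]:
        """Isotopes of *element*, sorted by mass (lightest first)."""
        try:
            return self._by_element[element]
        except KeyError:
            raise FormulaError(f"element {element!r} not in mass table") from None

    def principal(self, element: str) -> Isotope:
        """The most abundant isotope, used as the monoisotopic reference."""
        return max(self.isotopes(element), key=lambda i: i.abundance)

    def isotope(self, label: str) -> Isotope:
        try:
            return self._by_label[label]
        except KeyError:
            raise FormulaError(f"isotope {label!r} not in mass table") from None


def _load_default() -> AtomicMassTable:
    ref = resources.files("bromscreen").joinpath("data/isotope_masses.csv")
    with resources.as_file(ref) as path:
        return AtomicMassTable.from_csv(path)


@dataclass(frozen=True)
class MolecularFormula:
    """An element → count map, e.g. ``{C:15, H:10, Br:4, O:4, S:1}``."""

    element_counts: Mapping[str, int]

    def __post_init__(self):
        counts = {el: int(n) for el, n in self.element_counts.items() if n}
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        if any(n < 0 for n in counts.values()):
            raise FormulaError("element counts must be non-negative")
        object.__setattr__(self, "element_counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def add(self, element: str, n: int) -> "MolecularFormula":
        counts = dict(self.element_counts)
        counts[element] = counts.get(element, 0) + n
        if counts[element] < 0:
            raise FormulaError(
                f"removing {-n} {element} from {self} leaves a negative count")
        return MolecularFormula(counts)

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        counts = dict(self.element_counts)
        parts = []
        order = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
        order += sorted(el for el in counts if el not in order)
        for el in order:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str, table: AtomicMassTable | None = None) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C15H9Br4O4S"``.

    Unknown element symbols (checked against *table*, default the pinned
    table) raise :class:`FormulaError` naming the offending symbol.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    table = table or AtomicMassTable.default()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        el, digits = m.groups()
        if el not in table.elements():
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return MolecularFormula(counts)


#: Supported adduct transforms: (formula delta as element → count, charge).
ADDUCTS: dict[str, tuple[dict[str, int], int]] = {
    "[M-H]-": ({"H": -1}, -1),
    "M-H": ({"H": -1}, -1),
    "[M+H]+": ({"H": +1}, +1),
    "M+H": ({"H": +1}, +1),
    "[M]-": ({}, -1),
    "[M]+": ({}, +1),
}


@dataclass(frozen=True)
class IonSpecies:
    """A charged, adduct-adjusted ion with optional heavy-isotope substitutions.

    ``isotope_substitutions`` maps ``(element, heavy_isotope_label)`` to the
    number of atoms of that element replaced by the heavy isotope, e.g.
    ``{("Br", "81Br"): 2}`` for the two-⁸¹Br isotopologue.
    """

    neutral: MolecularFormula
    adduct: str = "[M-H]-"
    charge: int = -1
    isotope_substitutions: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        if self.charge == 0:
            raise FormulaError("ion charge must be non-zero")
        if self.adduct not in ADDUCTS:
            raise FormulaError(f"unsupported adduct {self.adduct!r}")
        delta, adduct_charge = ADDUCTS[self.adduct]
        if adduct_charge * self.charge < 0:
            raise FormulaError(
                f"adduct {self.adduct!r} implies charge sign {adduct_charge:+d}")
        ion = self.ion_formula
        for (el, _label), k in self.isotope_substitutions.items():
            if k < 0:
                raise FormulaError("substitution counts must be non-negative")
            if k > ion[el]:
                raise FormulaError(
                    f"{k} substitutions of {el} exceed its count {ion[el]} in {ion}")

    @property
    def ion_formula(self) -> MolecularFormula:
        delta, _ = ADDUCTS[self.adduct]
        f = self.neutral
        for el, n in delta.items():
            f = f.add(el, n * abs(self.charge))
        return f

    def substituted(self, element: str, heavy_label: str, k: int) -> "IonSpecies":
        subs = dict(self.isotope_substitutions)
        subs[(element, heavy_label)] = subs.get((element, heavy_label), 0) + k
        return IonSpecies(self.neutral, self.adduct, self.charge, subs)

    def __str__(self) -> str:
        sign = "-" if self.charge < 0 else "+"
        z = abs(self.charge)
        return f"[{self.ion_formula}]{z if z > 1 else ''}{sign}"


def ion_mz(ion: IonSpecies, table: AtomicMassTable | None = None) -> float:
    """Exact m/z of *ion*: principal-isotope masses, stated heavy-isotope
    substitutions, and ± electron masses for the charge state, divided by |z|.
    """
    table = table or AtomicMassTable.default()
    mass = 0.0
    subs_by_element: dict[str, list[tuple[str, int]]] = {}
    for (el, label), k in ion.isotope_substitutions.items():
        subs_by_element.setdefault(el, []).append((label, k))
    for el, n in ion.ion_formula.element_counts.items():
        principal = table.principal(el)
        n_principal = n
        for label, k in subs_by_element.get(el, []):
            iso = table.isotope(label)
            if iso.element != el:
                raise FormulaError(f"isotope {label!r} is not an isotope of {el}")
            mass += k * iso.mass_da
            n_principal -= k
        mass += n_principal * principal.mass_da
    z = abs(ion.charge)
    mass += (z if ion.charge < 0 else -z) * table.electron_mass_da
    return mass / z


def ppm_error(observed: float, calculated: float) -> float:
    """Absolute mass error in ppm, |obs − calc| / calc × 1e6."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return abs(observed - calculated) / calculated * 1e6


_DEFAULT_TABLE = _load_default()
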