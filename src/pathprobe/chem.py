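"""Chemical-formula arithmetic and the modification-reaction registry.

The registry holds neutral-loss modification reactions (glycosylations,
acylations, amine/alcohol/acid conjugations, ...) used to screen untargeted
MS/MS data for modified metabolites and to interpret precursor mass
differences between network neighbours.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "H2_MASS",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "ModificationType",
    "ModificationRegistry",
    "DeltaMatch",
    "load_modification_registry",
    "match_mass_delta",
    "FormulaError",
]

#: Monoisotopic masses of the most abundant isotope (CODATA/NIST), Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

#: Mass of H2, used for ring-opening / dehydrogenation adjustments.
H2_MASS: float = 2.0 * MONOISOTOPIC_MASS["H"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

CATEGORIES = frozenset({"generic", "specific"})
SUBCATEGORIES = frozenset(
    {
        "none",
        "amine-conjugation",
        "hydroxycinnamoyl-conjugation",
        "acid-conjugation",
        "alcohol-conjugation",
        "isoprenylation",
    }
)


class FormulaError(ValueError):
    """Raised for malformed or unknown-element molecular formulas."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula string into element counts.

    Accepts condensed structural spellings (``CH3NH2``, ``CH2CO``); repeated
    element symbols are summed. Element symbols must appear in
    :data:`MONOISOTOPIC_MASS`.

    >>> parse_formula("C6H10O5")
    {'C': 6, 'H': 10, 'O': 5}
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"malformed token at position {pos} in formula {formula!r}"
            )
        pos = match.end()
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
    if pos != len(formula):
        raise FormulaError(f"trailing garbage at position {pos} in {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Write element counts in Hill order (C, H, then alphabetical)."""
    ordered: list[str] = []
    symbols = set(counts)
    for sym in ("C", "H"):
        if sym in symbols:
            ordered.append(sym)
            symbols.discard(sym)
    ordered.extend(sorted(symbols))
    parts = []
    for sym in ordered:
        n = counts[sym]
        if n <= 0:
            raise FormulaError(f"non-positive count for {sym!r}")
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an element-count map; {} -> 0.0."""
    total = 0.0
    for sym, n in counts.items():
        try:
            total += MONOISOTOPIC_MASS[sym] * n
        except KeyError:
            raise FormulaError(f"element {sym!r} absent from isotope table") from None
    return total


@dataclass(frozen=True)
class ModificationType:
    """One modification reaction: a named neutral-loss moiety."""

    name: str
    formula: Mapping[str, int]
    mass: float
    category: str
    subcategory: str = "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subcategory not in SUBCATEGORIES:
            raise ValueError(f"unknown subcategory {self.subcategory!r}")
        if (self.category == "generic") != (self.subcategory == "none"):
            raise ValueError(
                f"{self.name}: generic <=> subcategory none violated "
                f"({self.category}/{self.subcategory})"
            )
        if self.mass <= 0:
            raise ValueError(f"{self.name}: non-positive mass {self.mass}")
        expected = monoisotopic_mass(self.formula)
        if abs(expected - self.mass) > 1e-6:
            raise ValueError(
                f"{self.name}: mass {self.mass} inconsistent with formula "
                f"({expected:.6f})"
            )

    @classmethod
    def from_formula(
        cls, name: str, formula: str, category: str, subcategory: str = "none"
    ) -> "ModificationType":
        counts = parse_formula(formula)
        return cls(
            name=name,
            formula=counts,
            mass=monoisotopic_mass(counts),
            category=category,
            subcategory=subcategory,
        )


class ModificationRegistry:
    """Ordered collection of :class:`ModificationType` with mass lookup."""

    def __init__(self, types: Iterable[ModificationType]):
        self._types: tuple[ModificationType, ...] = tuple(types)
        names = [t.name for t in self._types]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate modification names: {sorted(dupes)}")
        self._by_name = {t.name: t for t in self._types}
        if not self._types:
            warnings.warn("empty modification registry", stacklevel=2)

    def __len__(self) -> int:
        return len(self._types)

    def __iter__(self) -> Iterator[ModificationType]:
        return iter(self._types)

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ModificationType:
        return self._by_name[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self._types)

    def counts_by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self._types:
            out[t.category] = out.get(t.category, 0) + 1
        return out

    def counts_by_subcategory(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self._types:
            if t.category == "specific":
                out[t.subcategory] = out.get(t.subcategory, 0) + 1
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModificationRegistry":
        types: list[ModificationType] = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return cls([])
            required = {"name", "formula", "category", "subcategory"}
            missing = required - set(reader.fieldnames)
            if missing:
                raise ValueError(f"registry file missing columns: {sorted(missing)}")
            for row in reader:
                types.append(
                    ModificationType.from_formula(
                        row["name"].strip(),
                        row["formula"].strip(),
                        row["category"].strip(),
                        row["subcategory"].strip() or "none",
                    )
                )
        return cls(types)


def load_modification_registry(path: str | Path | None = None) -> ModificationRegistry:
    """Load a registry CSV (``name,formula,category,subcategory``).

    Without ``path`` the packaged default registry of 61 phenylpropanoid
    modification reactions is loaded.
    """
    if path is None:
        ref = resources.files("pathprobe").joinpath("data/modifications.csv")
        with resources.as_file(ref) as p:
            return ModificationRegistry.from_csv(p)
    return ModificationRegistry.from_csv(path)


@dataclass(frozen=True)
class DeltaMatch:
    """A registry entry explaining an observed mass difference.

    ``adjustment`` is ``""`` for an exact match, or ``"-2H"``/``"+2H"`` when
    the observed delta equals the registry mass minus/plus one H2 (e.g. a
    ring-opened moiety that lost two hydrogens). ``ppm_error`` is relative to
    the (unadjusted) registry mass.
    """

    modification: ModificationType
    ppm_error: float
    adjustment: str = ""
    observed_delta: float = field(default=0.0, compare=False)

    @property
    def adjusted_mass(self) -> float:
        if self.adjustment == "-2H":
            return self.modification.mass - H2_MASS
        if self.adjustment == "+2H":
            return self.modification.mass + H2_MASS
        return self.modification.mass


def match_mass_delta(
    delta: float,
    registry: ModificationRegistry,
    tol_ppm: float = 15.0,
    allow_h2_adjustment: bool = False,
) -> list[DeltaMatch]:
    """Match an observed mass difference against the registry.

    Returns every registry entry whose mass (optionally shifted by +-H2 when
    ``allow_h2_adjustment``) lies within ``tol_ppm`` of ``delta``, sorted by
    increasing absolute ppm error with exact matches preferred over adjusted
    ones at equal error.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    adjustments = [("", 0.0)]
    if allow_h2_adjustment:
        adjustments += [("-2H", -H2_MASS), ("+2H", +H2_MASS)]
    matches: list[DeltaMatch] = []
    for mod in registry:
        for label, adj in adjustments:
            ref = mod.mass + adj
            if ref <= 0:
                continue
            ppm = 1e6 * (delta - ref) / mod.mass
            if abs(ppm) <= tol_ppm:
                matches.append(
                    DeltaMatch(
                        modification=mod,
                        ppm_error=ppm,
                        adjustment=label,
                        observed_delta=delta,
                    )
                )
    matches.sort(key=lambda m: (abs(m.ppm_error), m.adjustment != "", m.modification.name))
    return matches
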