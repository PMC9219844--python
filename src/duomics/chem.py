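"""Molecular-formula arithmetic and the offline compound/adduct registry.

Everything downstream of the mass spectrometer reduces to arithmetic on
monoisotopic masses: a neutral molecule of known elemental composition has a
single theoretical monoisotopic mass, and each ionized (adduct) form observed
in positive-mode electrospray has m/z = (M + shift) / z, where the shift is
the mass of the attached (or lost) atoms corrected for the electron(s)
carried by the charge.  Compound identity assignment then becomes a
parts-per-million comparison between observed and theoretical m/z.

This module provides the element mass table, a Hill-notation formula parser,
the adduct algebra, and loaders for the tab-separated compound and adduct
registries that stand in for live spectral-database (METLIN-style) lookups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "Adduct",
    "adduct_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "Compound",
    "load_adducts",
    "load_compounds",
    "load_registry",
    "default_adducts",
    "default_compounds",
    "default_observed_features",
    "adduct_priority",
    "normalize_adduct_name",
]

# IUPAC monoisotopic atomic masses (u), most abundant isotope of each element.
# Carbon is exactly 12 by definition of the unified atomic mass unit.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Cu": 62.9295975,
    "Zn": 63.9291422,
    "Se": 79.9165213,
    "Br": 78.9183371,
    "I": 126.904473,
}

PROTON_MASS = 1.007276466
ELECTRON_MASS = 0.000548579909

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
CAS_PATTERN = re.compile(r"^\d{2,7}-\d{2}-\d$")


class FormulaError(ValueError):
    """Raised when a molecular formula string cannot be parsed."""


def parse_formula(text: str, masses: Optional[Mapping[str, float]] = None) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    Counts default to 1 when omitted ("CH4O" == "C1H4O1").  Symbols must be
    present in the element mass table; unknown symbols raise
    :class:`FormulaError` naming the offending token.
    """
    if masses is None:
        masses = MONOISOTOPIC_MASS
    if not text or not text.strip():
        raise FormulaError("empty molecular formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable formula {text!r} at position {pos}: {text[pos:match.start()]!r}"
            )
        symbol, digits = match.groups()
        if symbol not in masses:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in formula {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"trailing garbage in formula {text!r}: {text[pos:]!r}")
    if not counts:
        raise FormulaError(f"formula {text!r} contains no elements")
    return counts


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Serialize element counts back to Hill notation (C, H, then alphabetical)."""
    symbols = sorted(formula, key=lambda s: (s != "C", s != "H", s))
    parts = []
    for s in symbols:
        n = formula[s]
        parts.append(s if n == 1 else f"{s}{n}")
    return "".join(parts)


def monoisotopic_mass(
    formula: Mapping[str, int], masses: Optional[Mapping[str, float]] = None
) -> float:
    """Monoisotopic mass (u) of a formula: sum of element masses times counts."""
    if masses is None:
        masses = MONOISOTOPIC_MASS
    total = 0.0
    for symbol, count in formula.items():
        if symbol not in masses:
            raise FormulaError(f"element {symbol!r} missing from mass table")
        if count < 0:
            raise FormulaError(f"negative count for element {symbol!r}")
        total += masses[symbol] * count
    if total <= 0.0:
        raise FormulaError("formula has non-positive mass")
    return total


@dataclass(frozen=True)
class Adduct:
    """A positive-mode ionized form: m/z = (M + mass_shift) / charge.

    ``mass_shift`` is the signed, electron-corrected total shift in u for the
    whole ion (e.g. M+H = +1.007276, not +1.007825: the added hydrogen lacks
    its electron).
    """

    name: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct {self.name!r}: charge must be >= 1")

    def mz(self, neutral_mass: float) -> float:
        return adduct_mz(neutral_mass, self)

    def neutral_mass(self, mz: float) -> float:
        return neutral_mass_from_mz(mz, self)


def adduct_mz(neutral_mass: float, adduct: Adduct) -> float:
    """m/z (Th) of ``adduct`` formed from a neutral molecule of ``neutral_mass`` u."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be >= 0")
    mz = (neutral_mass + adduct.mass_shift) / adduct.charge
    if mz <= 0:
        raise ValueError(
            f"nonphysical m/z {mz:.6f} for neutral mass {neutral_mass} with {adduct.name}"
        )
    return mz


def neutral_mass_from_mz(mz: float, adduct: Adduct) -> float:
    """Invert :func:`adduct_mz`: the neutral mass implied by an observed m/z."""
    return mz * adduct.charge - adduct.mass_shift


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error, (observed - theoretical)/theoretical x 1e6."""
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


# Observed adduct spellings vary in source tables; canonicalize the known aliases.
ADDUCT_ALIASES = {
    "M+NH3+": "M+NH3[1+]",
    "M+NH4[1+]": "M+NH3[1+]",
    "M+H+Na": "M+H+Na[2+]",
}


def normalize_adduct_name(name: str) -> str:
    name = name.strip()
    return ADDUCT_ALIASES.get(name, name)


@dataclass
class Compound:
    """A registry entry: named metabolite with formula-derived neutral mass.

    ``ec_links`` carries Enzyme Commission codes associated with the compound
    (the metabolite-side bridge into reaction space); ``pathways`` the
    pathway names used for enrichment.  ``verified`` marks compounds with at
    least one mass-consistent observed feature in the packaged table fixture.
    """

    name: str
    formula: dict[str, int]
    neutral_mass: float
    cas: Optional[str] = None
    kegg: Optional[str] = None
    ec_links: frozenset = field(default_factory=frozenset)
    pathways: frozenset = field(default_factory=frozenset)
    verified: bool = True

    def __post_init__(self) -> None:
        expected = monoisotopic_mass(self.formula)
        if abs(expected - self.neutral_mass) > 1e-6:
            raise ValueError(
                f"compound {self.name!r}: neutral_mass {self.neutral_mass} inconsistent "
                f"with formula mass {expected}"
            )
        if self.cas and not CAS_PATTERN.match(self.cas):
            raise ValueError(f"compound {self.name!r}: malformed CAS number {self.cas!r}")

    def __hash__(self) -> int:  # name is unique within a registry
        return hash(self.name)


def _split_multi(cell: str) -> frozenset:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(x.strip() for x in cell.split(";") if x.strip())


def load_adducts(path) -> list[Adduct]:
    """Read a tab-separated adduct table (columns: name, mass_shift, charge).

    File order defines the tie-break priority used during annotation.
    """
    adducts: list[Adduct] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "mass_shift", "charge"]:
            raise ValueError(f"{path}: expected header name/mass_shift/charge, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed adduct row {line!r}")
            name = normalize_adduct_name(parts[0])
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate adduct name {name!r}")
            seen.add(name)
            adducts.append(Adduct(name=name, mass_shift=float(parts[1]), charge=int(parts[2])))
    if not adducts:
        raise ValueError(f"{path}: no adducts found")
    return adducts


def load_compounds(path) -> list[Compound]:
    """Read a tab-separated compound registry.

    Columns: name, formula, cas, kegg, ec_links (semicolon-joined), pathways
    (semicolon-joined), verified.  Malformed rows raise with the line number;
    duplicate names are rejected.
    """
    compounds: list[Compound] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "formula", "cas", "kegg", "ec_links", "pathways", "verified"]
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            name, formula_s, cas, kegg, ecs, pathways, verified = parts
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate compound name {name!r}")
            seen.add(name)
            try:
                formula = parse_formula(formula_s)
                compound = Compound(
                    name=name,
                    formula=formula,
                    neutral_mass=monoisotopic_mass(formula),
                    cas=cas or None,
                    kegg=kegg or None,
                    ec_links=_split_multi(ecs),
                    pathways=_split_multi(pathways),
                    verified=verified.strip().lower() in ("1", "true", "yes"),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            compounds.append(compound)
    if not compounds:
        raise ValueError(f"{path}: no compounds found")
    return compounds


def load_registry(compound_path, adduct_path) -> tuple[list[Compound], list[Adduct]]:
    """Load compound and adduct registries together."""
    return load_compounds(compound_path), load_adducts(adduct_path)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("duomics.data") / name))


def default_adducts() -> list[Adduct]:
    """The packaged positive-mode adduct set."""
    return load_adducts(_data_path("adducts.tsv"))


def default_compounds() -> list[Compound]:
    """The packaged registry of named metabolites from the study's tables."""
    return load_compounds(_data_path("compounds.tsv"))


def default_observed_features():
    """Observed (compound, adduct, m/z, RT, fold, p) rows from the study's tables.

    Returned as a pandas DataFrame.  Rows whose printed m/z deviates > 10 ppm
    from theory under the packaged adduct definitions carry verified=False and
    are excluded from mass-consistency checks.
    """
    import pandas as pd

    df = pd.read_csv(_data_path("observed_features.tsv"), sep="\t")
    df["adduct"] = df["adduct"].map(normalize_adduct_name)
    df["verified"] = df["verified"].astype(bool)
    return df


def write_compounds(compounds: Iterable[Compound], path, header_comment: Optional[str] = None) -> None:
    """Serialize a compound registry to the tab-separated interchange format."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("name\tformula\tcas\tkegg\tec_links\tpathways\tverified\n")
        for c in compounds:
            fh.write(
                "\t".join(
                    [
                        c.name,
                        formula_to_string(c.formula),
                        c.cas or "",
                        c.kegg or "",
                        ";".join(sorted(c.ec_links)),
                        ";".join(sorted(c.pathways)),
                        "true" if c.verified else "false",
                    ]
                )
                + "\n"
            )


def write_adducts(adducts: Iterable[Adduct], path, header_comment: Optional[str] = None) -> None:
    """Serialize an adduct table; row order encodes tie-break priority."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("name\tmass_shift\tcharge\n")
        for a in adducts:
            fh.write(f"{a.name}\t{a.mass_shift!r}\t{a.charge}\n")


_PRIORITY_CACHE: Optional[dict[str, int]] = None


def adduct_priority(name: str, adducts: Optional[Iterable[Adduct]] = None) -> int:
    """Tie-break priority of an adduct (lower = more favored).

    Priority follows typical positive-mode ESI abundance: M+H > M+Na > M+NH4
    > M+K > in-source water loss > ammonia loss > doubly charged species.
    It is encoded as row order of the adduct table.
    """
    global _PRIORITY_CACHE
    if adducts is not None:
        order = {a.name: i for i, a in enumerate(adducts)}
        return order.get(normalize_adduct_name(name), len(order))
    if _PRIORITY_CACHE is None:
        _PRIORITY_CACHE = {a.name: i for i, a in enumerate(default_adducts())}
    return _PRIORITY_CACHE.get(normalize_adduct_name(name), len(_PRIORITY_CACHE))
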