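"""Elemental-mass arithmetic for positive-mode small-molecule MS.

Everything downstream — theoretical fragment m/z, mass-error gates,
formula decomposition of observed masses — reduces to arithmetic on
:class:`Formula` objects against a monoisotopic element mass table.
The chemistry space is deliberately small: C, H and O (Na only as an
adduct), singly charged positive ions, electron-mass corrected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ElementMassTable",
    "Formula",
    "IonSpec",
    "MassError",
    "MASSES",
    "monoisotopic_mass",
    "ion_mz",
    "mass_error",
    "rdbe",
    "decompose",
    "subformula",
    "formula_diff",
    "parse_ion",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Hill convention: carbon, hydrogen, then the rest alphabetically.
_HILL_HEAD = ("C", "H")


class UnknownElementError(KeyError):
    """Element symbol absent from the mass table."""


@dataclass(frozen=True)
class ElementMassTable:
    """Monoisotopic masses (Da) per element symbol, plus the electron mass."""

    masses: Mapping[str, float]
    electron_mass: float

    def __post_init__(self) -> None:
        for required in ("C", "H", "O", "Na"):
            if required not in self.masses:
                raise ValueError(f"mass table missing element {required}")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("element masses must be positive")
        if not 5.0e-4 < self.electron_mass < 6.0e-4:
            raise ValueError("implausible electron mass")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise UnknownElementError(symbol) from None


def _load_mass_table() -> ElementMassTable:
    with resources.files("flavotier.data").joinpath("elements.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    electron = raw.pop("electron")
    return ElementMassTable(masses=raw, electron_mass=electron)


MASSES: ElementMassTable = _load_mass_table()

#: Mass added by each supported +1 adduct (charge carrier, electron-corrected).
PROTON = MASSES["H"] - MASSES.electron_mass


@dataclass(frozen=True, eq=False)
class Formula:
    """Multiset of elements with non-negative counts.

    The all-zero formula is a legal value: it is the identity of addition
    and the result of ``f - f``, which keeps fragmentation-tree roots and
    self-differences unexceptional.  Hashable, so formulas can key sets
    and dicts.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self.counts == other.counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {sym}")
            if not isinstance(n, int):
                raise TypeError(f"count for {sym} must be an integer")
            if n:
                clean[sym] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-order formula string such as ``C16H12O4``."""
        text = text.strip()
        if not text:
            return cls({})
        counts: dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            sym, num = match.groups()
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        parts = []
        for sym in _HILL_HEAD:
            if self.counts.get(sym):
                n = self.counts[sym]
                parts.append(sym if n == 1 else f"{sym}{n}")
        for sym in sorted(self.counts):
            if sym in _HILL_HEAD:
                continue
            n = self.counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        out = dict(self.counts)
        for sym, n in other.counts.items():
            out[sym] = out.get(sym, 0) - n
            if out[sym] < 0:
                raise ValueError(
                    f"subtraction {self} - {other} is negative in {sym}"
                )
        return Formula(out)

    def __mul__(self, k: int) -> "Formula":
        return Formula({s: n * k for s, n in self.counts.items()})


F = Formula.parse  # terse constructor used throughout the package

ADDUCTS = ("[M+H]+", "[M+Na]+", "[2M+H]+", "cation")


@dataclass(frozen=True)
class IonSpec:
    """A singly charged positive ion: neutral formula plus adduct.

    ``adduct="cation"`` means the formula *is already* the cation
    (as printed, e.g. ``[C16H13O4]+``); only the electron mass is removed.
    """

    formula: Formula
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        if self.adduct not in ADDUCTS:
            raise ValueError(
                f"unsupported adduct {self.adduct!r}; expected one of {ADDUCTS}"
            )

    @property
    def cation_formula(self) -> Formula:
        """Elemental composition of the charged species itself."""
        if self.adduct == "cation":
            return self.formula
        if self.adduct == "[M+H]+":
            return self.formula + F("H")
        if self.adduct == "[M+Na]+":
            return self.formula + F("Na")
        return self.formula * 2 + F("H")  # [2M+H]+


@dataclass(frozen=True)
class MassError:
    """Observed minus theoretical, in mDa and ppm (ppm against theoretical)."""

    mda: float
    ppm: float


def monoisotopic_mass(formula: Formula, table: ElementMassTable = MASSES) -> float:
    """Neutral monoisotopic mass in Da; raises on unknown element symbols."""
    return sum(n * table[sym] for sym, n in formula)


def ion_mz(ion: IonSpec, table: ElementMassTable = MASSES) -> float:
    """m/z of a +1 ion, electron-mass corrected.

    A proton therefore adds 1.007276 Da, not 1.007825 — which is what
    makes four-decimal agreement with printed fragment m/z possible.
    """
    if ion.adduct == "cation":
        return monoisotopic_mass(ion.formula, table) - table.electron_mass
    if ion.adduct == "[M+H]+":
        return monoisotopic_mass(ion.formula, table) + table["H"] - table.electron_mass
    if ion.adduct == "[M+Na]+":
        return monoisotopic_mass(ion.formula, table) + table["Na"] - table.electron_mass
    # [2M+H]+
    return 2 * monoisotopic_mass(ion.formula, table) + table["H"] - table.electron_mass


def mass_error(observed: float, theoretical: float) -> MassError:
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    delta = observed - theoretical
    return MassError(mda=1000.0 * delta, ppm=1e6 * delta / theoretical)


def rdbe(formula: Formula) -> float:
    """Rings plus double-bond equivalents: C - H/2 + 1 (Na counted H-like)."""
    return formula["C"] - (formula["H"] + formula["Na"]) / 2.0 + 1.0


def subformula(small: Formula, big: Formula) -> bool:
    """Element-wise ``small <= big`` (every formula contains itself)."""
    return all(big[sym] >= n for sym, n in small)


def formula_diff(big: Formula, small: Formula) -> Formula:
    """``big - small``; hard error if any element count would go negative."""
    return big - small


def parse_ion(text: str) -> IonSpec:
    """Parse ``[M+H]+``-style adduct strings or explicit cations.

    ``[M+H]+`` / ``[M+Na]+`` / ``[2M+H]+`` return an IonSpec with an empty
    neutral formula (caller supplies it); ``[C16H13O4]+`` parses as a
    cation-as-written.
    """
    text = text.strip()
    if text in ("[M+H]+", "[M+Na]+", "[2M+H]+"):
        return IonSpec(Formula({}), text)
    m = re.fullmatch(r"\[([A-Za-z0-9]+)\]\+", text)
    if m is None:
        raise ValueError(f"cannot parse ion string {text!r}")
    return IonSpec(F(m.group(1)), "cation")


# -- formula decomposition ---------------------------------------------------

RDBE_RANGE = (0.0, 25.0)


def decompose(
    target_mz: float,
    adduct: str = "[M+H]+",
    tol_mda: float = 5.0,
    max_c: int = 30,
    max_h: int = 40,
    max_o: int = 10,
    table: ElementMassTable = MASSES,
) -> list[Formula]:
    """Enumerate CHO formulas whose ion m/z falls within ``tol_mda``.

    ``adduct="neutral"`` matches a neutral mass instead of an ion.  The
    search is an exhaustive scan over the element bounds, filtered by
    RDBE in [0, 25] and the H <= 2C + 2 valence ceiling, sorted by
    absolute mass error (ties: fewer oxygens).  An empty list is a valid
    result.
    """
    if tol_mda <= 0:
        raise ValueError("tolerance must be positive")
    tol = tol_mda / 1000.0
    mc, mh, mo = table["C"], table["H"], table["O"]

    if adduct == "neutral":
        shift = 0.0
    elif adduct == "cation":
        shift = -table.electron_mass
    elif adduct == "[M+H]+":
        shift = mh - table.electron_mass
    elif adduct == "[M+Na]+":
        shift = table["Na"] - table.electron_mass
    else:
        raise ValueError(f"unsupported adduct {adduct!r} for decomposition")

    out: list[tuple[float, int, Formula]] = []
    for c in range(max_c + 1):
        base_c = c * mc + shift
        if base_c - target_mz > tol:
            break
        h_cap = min(max_h, 2 * c + 2)
        for o in range(max_o + 1):
            base_co = base_c + o * mo
            if base_co - target_mz > tol:
                break
            for h in range(h_cap + 1):
                mass = base_co + h * mh
                if mass - target_mz > tol:
                    break
                err = mass - target_mz
                if abs(err) > tol:
                    continue
                f = Formula({"C": c, "H": h, "O": o})
                if not f:
                    continue
                r = rdbe(f)
                if not RDBE_RANGE[0] <= r <= RDBE_RANGE[1]:
                    continue
                out.append((abs(err), o, f))
    out.sort(key=lambda t: (t[0], t[1], str(t[2])))
    return [f for _, _, f in out]
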