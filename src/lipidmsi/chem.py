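"""Exact-mass arithmetic for small-molecule ions.

Monoisotopic masses, positive-mode adduct m/z, neutral-loss fragment m/z,
ppm mass error and aggregated isotope envelopes.  Atomic masses and natural
isotope abundances come from the NIST table shipped with :mod:`pyteomics`
(current IUPAC/CODATA values); all ion arithmetic, including the electron-mass
correction that moves a singly charged cation by ~0.55 mTh, is done here.

Conventions
-----------
* Positive ions only, charge magnitude 1 in practice (``adduct_mz`` divides by
  ``|charge|`` so higher charge states are formally supported but untested).
* m/z values are kept at full precision internally; rounding is applied only
  for display via :func:`format_mz` (half-even, 4 decimals).
* Isotope envelopes are aggregated by integer nucleon-number offset
  (M, M+1, M+2, ...), the resolution at which an Orbitrap envelope is
  normally displayed; fine structure within an offset is merged into an
  abundance-weighted centroid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
from pyteomics import mass as _ptmass

__all__ = [
    "ELECTRON_MASS",
    "Formula",
    "AdductSpec",
    "IsotopePattern",
    "ElementTable",
    "DEFAULT_ELEMENT_TABLE",
    "BUILTIN_ADDUCTS",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_loss_mz",
    "ppm_error",
    "isotope_pattern",
    "get_adduct",
    "format_mz",
]

#: CODATA electron mass in Da.
ELECTRON_MASS: float = _ptmass.nist_mass["e*"][0][0]


class FormulaError(ValueError):
    """Raised for malformed formulas or impossible compositions."""


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element -> count map for a neutral molecular composition.

    Zero-count entries are dropped on construction; equality is count-map
    equality.  Supports ``+`` and ``-`` (``-`` raises :class:`FormulaError`
    if any resulting count would be negative).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}: {n}")
            if n:
                clean[str(el)] = int(n)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "Formula") -> "Formula":
        out = dict(self.counts)
        for el, n in other.counts.items():
            out[el] = out.get(el, 0) + n
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        out = dict(self.counts)
        for el, n in other.counts.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"removing {other.hill()} from {self.hill()} leaves "
                    f"negative {el} count"
                )
            out[el] = new
        return Formula(out)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        items = dict(self.counts)
        parts: List[str] = []
        order: List[str] = []
        if "C" in items:
            order = ["C"] + (["H"] if "H" in items else []) + sorted(
                k for k in items if k not in ("C", "H")
            )
        else:
            order = sorted(items)
        for el in order:
            n = items[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula such as ``"C24H47NO7"``.

    Element symbols are one capital letter optionally followed by one lower
    case letter, each with an optional positive integer count.  Unknown
    symbols and empty input raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        el, num = m.group(1), m.group(2)
        if el not in _ptmass.nist_mass:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return Formula(counts)


# --------------------------------------------------------------------------
# element table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementTable:
    """Per-element isotope masses/abundances plus the electron mass.

    ``isotopes[el]`` is a list of ``(mass_da, abundance)`` sorted by mass;
    abundances for each element sum to 1 within 1e-9.
    """

    isotopes: Mapping[str, Tuple[Tuple[float, float], ...]]
    electron_mass: float = ELECTRON_MASS

    def monoisotopic(self, el: str) -> float:
        """Mass of the most abundant isotope of ``el``."""
        iso = self.isotopes.get(el)
        if iso is None:
            raise FormulaError(f"element {el!r} not in element table")
        return max(iso, key=lambda t: t[1])[0]


def _build_default_table() -> ElementTable:
    iso: Dict[str, Tuple[Tuple[float, float], ...]] = {}
    for el, entries in _ptmass.nist_mass.items():
        if el == "e*":
            continue
        pairs = sorted(
            (m, ab) for key, (m, ab) in entries.items() if key != 0 and ab > 0
        )
        if pairs:
            iso[el] = tuple(pairs)
    return ElementTable(iso)


DEFAULT_ELEMENT_TABLE = _build_default_table()


def monoisotopic_mass(f: Formula, table: ElementTable = DEFAULT_ELEMENT_TABLE) -> float:
    """Sum of most-abundant-isotope masses; 0.0 for the empty formula."""
    return sum(table.monoisotopic(el) * n for el, n in f.counts.items())


# --------------------------------------------------------------------------
# adducts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductSpec:
    """A charged species recipe: M + added − removed, with electron loss.

    ``electron_delta`` is the number of electrons removed (one per positive
    charge in positive mode; a protonated ion removes the proton's electron
    implicitly because H is added as a neutral atom here).
    """

    name: str
    added: Formula = field(default_factory=Formula)
    removed: Formula = field(default_factory=Formula)
    charge: int = 1
    electron_delta: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


_H2O = Formula({"H": 2, "O": 1})

BUILTIN_ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", added=Formula({"H": 1})),
    "[M+H-H2O]+": AdductSpec("[M+H-H2O]+", added=Formula({"H": 1}), removed=_H2O),
    "[M+NH4]+": AdductSpec("[M+NH4]+", added=Formula({"N": 1, "H": 4})),
    "[M+Na]+": AdductSpec("[M+Na]+", added=Formula({"Na": 1})),
    "[M]+.": AdductSpec("[M]+.", added=Formula(), removed=Formula()),
}

#: accepted spellings on the command line / in panel files
_ADDUCT_ALIASES = {
    "M+H": "[M+H]+",
    "M+H-H2O": "[M+H-H2O]+",
    "M+NH4": "[M+NH4]+",
    "M+NA": "[M+Na]+",
    "M+Na": "[M+Na]+",
    "M": "[M]+.",
    "[M]+•": "[M]+.",
}


def get_adduct(name: str) -> AdductSpec:
    """Look up a built-in adduct by canonical name or short alias."""
    key = name.strip()
    if key in BUILTIN_ADDUCTS:
        return BUILTIN_ADDUCTS[key]
    alias = _ADDUCT_ALIASES.get(key) or _ADDUCT_ALIASES.get(key.upper())
    if alias:
        return BUILTIN_ADDUCTS[alias]
    raise KeyError(f"unknown adduct {name!r}; known: {sorted(BUILTIN_ADDUCTS)}")


def ion_composition(f: Formula, adduct: AdductSpec) -> Formula:
    """Elemental composition of the ion (errors if a count goes negative)."""
    return (f + adduct.added) - adduct.removed


def adduct_mz(
    f: Formula,
    adduct: AdductSpec,
    table: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> float:
    """Theoretical m/z of ``f`` ionised as ``adduct``.

    ``(mono(M) + mono(added) − mono(removed) − electron_delta·m_e) / |z|``.
    """
    comp = ion_composition(f, adduct)
    m = monoisotopic_mass(comp, table) - adduct.electron_delta * table.electron_mass
    return m / abs(adduct.charge)


def neutral_loss_mz(precursor_mz: float, loss: Formula,
                    table: ElementTable = DEFAULT_ELEMENT_TABLE) -> float:
    """m/z after a neutral loss from a singly charged precursor."""
    out = precursor_mz - monoisotopic_mass(loss, table)
    if out <= 0:
        raise FormulaError(
            f"neutral loss {loss.hill()} exceeds precursor m/z {precursor_mz}"
        )
    return out


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def format_mz(mz: float, decimals: int = 4) -> str:
    """Display rounding, half-even (Python's round) at ``decimals`` places."""
    return f"{round(mz, decimals):.{decimals}f}"


# --------------------------------------------------------------------------
# isotope envelopes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """Envelope aggregated by nucleon-number offset from the monoisotopic peak.

    ``entries`` is an ordered tuple of ``(mz, relative_abundance)``; the first
    entry is the monoisotopic peak, m/z is strictly increasing and abundances
    sum to 1 within 1e-9 (after truncation they are renormalised).
    """

    entries: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        mzs = [m for m, _ in self.entries]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("isotope pattern m/z must be strictly increasing")
        total = sum(a for _, a in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isotope abundances sum to {total}, not 1")

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.entries])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([a for _, a in self.entries])


def _single_atom_dist(el: str, table: ElementTable) -> Dict[int, Tuple[float, float]]:
    """offset -> (probability, mean mass) for one atom of ``el``."""
    iso = table.isotopes.get(el)
    if iso is None:
        raise FormulaError(f"element {el!r} not in element table")
    base_nucleon = round(iso[0][0])  # lightest isotope defines offset 0
    out: Dict[int, Tuple[float, float]] = {}
    for m, ab in iso:
        off = round(m) - base_nucleon
        if off in out:
            p0, m0 = out[off]
            p = p0 + ab
            out[off] = (p, (p0 * m0 + ab * m) / p)
        else:
            out[off] = (ab, m)
    return out


def _convolve(a: Dict[int, Tuple[float, float]],
              b: Dict[int, Tuple[float, float]],
              max_offset: int) -> Dict[int, Tuple[float, float]]:
    out: Dict[int, List[float]] = {}
    for oa, (pa, ma) in a.items():
        for ob, (pb, mb) in b.items():
            off = oa + ob
            if off > max_offset:
                continue
            p = pa * pb
            cell = out.setdefault(off, [0.0, 0.0])
            cell[0] += p
            cell[1] += p * (ma + mb)
    return {k: (p, s / p) for k, (p, s) in out.items() if p > 0}


def _power(dist: Dict[int, Tuple[float, float]], n: int,
           max_offset: int) -> Dict[int, Tuple[float, float]]:
    """n-fold self-convolution by binary exponentiation."""
    result = {0: (1.0, 0.0)}
    base = dist
    while n:
        if n & 1:
            result = _convolve(result, base, max_offset)
        n >>= 1
        if n:
            base = _convolve(base, base, max_offset)
    return result


def isotope_pattern(
    f: Formula,
    n_peaks: int = 4,
    charge: int = 0,
    electron_delta: int | None = None,
    table: ElementTable = DEFAULT_ELEMENT_TABLE,
) -> IsotopePattern:
    """Aggregated isotope envelope of a composition.

    Elementwise isotope distributions are convolved, aggregated by integer
    nucleon offset, truncated to ``n_peaks`` and renormalised.  For an ion
    envelope pass the *ion* composition (e.g. via
    :func:`ion_composition`) together with ``charge`` (the electron-mass
    correction is then applied and masses divided by ``|charge|``).

    Note an adduct's envelope is obtained by applying this to the ion
    composition, not by shifting the neutral envelope.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    max_off = n_peaks - 1
    dist = {0: (1.0, 0.0)}
    for el, n in f.counts.items():
        dist = _convolve(dist, _power(_single_atom_dist(el, table), n, max_off),
                         max_off)
    e_delta = electron_delta if electron_delta is not None else (
        charge if charge > 0 else 0
    )
    z = abs(charge) if charge else 1
    entries = []
    for off in sorted(dist):
        p, m = dist[off]
        entries.append(((m - e_delta * table.electron_mass) / z, p))
    total = sum(p for _, p in entries)
    entries = [(m, p / total) for m, p in entries]
    return IsotopePattern(tuple(entries))
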