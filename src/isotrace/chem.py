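"""Elemental formulas, natural isotope abundances, and theoretical spectra.

The natural abundance values are shipped as a read-only JSON document
(``isotrace/data/isotope_abundances.json``) so they can be audited or
overridden; all probabilities are indexed by integer mass shift above the
monoisotopic peak, which is the natural representation for nominal-resolution
(unit mass) spectra.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import FormulaError, UnknownElementError

__all__ = [
    "IsotopePattern",
    "AbundanceTable",
    "default_table",
    "natural_pattern",
    "parse_formula",
    "formula_to_text",
    "convolve",
    "composition_spectrum",
]


@dataclass(frozen=True)
class IsotopePattern:
    """Natural isotope pattern of one element.

    ``shifts`` are integer mass shifts above the monoisotopic isotope,
    strictly increasing from 0; ``probabilities`` are the matching mole
    fractions and sum to 1.
    """

    element: str
    shifts: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.shifts or self.shifts[0] != 0:
            raise ValueError(f"{self.element}: shifts must start at 0")
        if any(b <= a for a, b in zip(self.shifts, self.shifts[1:])):
            raise ValueError(f"{self.element}: shifts must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValueError(f"{self.element}: probabilities outside [0, 1]")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ValueError(f"{self.element}: probabilities do not sum to 1")

    def dense(self) -> np.ndarray:
        """Probabilities as a dense array indexed by mass shift."""
        out = np.zeros(self.shifts[-1] + 1)
        out[list(self.shifts)] = self.probabilities
        return out

    @property
    def max_shift(self) -> int:
        return self.shifts[-1]


class AbundanceTable:
    """Versioned collection of per-element natural isotope patterns."""

    def __init__(self, patterns: dict[str, IsotopePattern], version: str):
        self._patterns = dict(patterns)
        self.version = version

    @classmethod
    def from_json(cls, path: str | Path) -> "AbundanceTable":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        patterns = {
            el: IsotopePattern(el, tuple(s for s, _ in rows), tuple(p for _, p in rows))
            for el, rows in doc["elements"].items()
        }
        return cls(patterns, doc.get("version", "unversioned"))

    def __contains__(self, element: str) -> bool:
        return element in self._patterns

    def __getitem__(self, element: str) -> IsotopePattern:
        try:
            return self._patterns[element]
        except KeyError:
            raise UnknownElementError(element) from None

    def elements(self) -> tuple[str, ...]:
        return tuple(self._patterns)


@lru_cache(maxsize=1)
def default_table() -> AbundanceTable:
    """The packaged IUPAC/CIAAW representative terrestrial abundances."""
    with resources.as_file(
        resources.files("isotrace.data") / "isotope_abundances.json"
    ) as p:
        return AbundanceTable.from_json(p)


def natural_pattern(element: str, table: AbundanceTable | None = None) -> IsotopePattern:
    """Natural terrestrial isotope pattern of ``element``."""
    return (table or default_table())[element]


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(
    formula_text: str, table: AbundanceTable | None = None
) -> dict[str, int]:
    """Parse plain Hill-notation formula text into element counts.

    Accepts element symbols (one uppercase plus optional lowercase letter)
    each followed by an optional positive integer; repeated symbols
    accumulate.  No parentheses, charges, or isotope prefixes.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    table = table or default_table()
    text = formula_text.strip()
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula_text!r}: unexpected character "
                f"{text[pos]!r} at position {pos}"
            )
        symbol, digits = m.groups()
        if symbol not in table:
            raise UnknownElementError(symbol)
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n <= 0:
                raise FormulaError(
                    f"malformed formula {formula_text!r}: zero count for "
                    f"{symbol} at position {pos}"
                )
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def formula_to_text(comp: dict[str, int]) -> str:
    """Inverse of :func:`parse_formula` (element order as given)."""
    return "".join(f"{el}{n if n != 1 else ''}" for el, n in comp.items() if n > 0)


def convolve(a: np.ndarray, b: np.ndarray, max_shift: int) -> np.ndarray:
    """Distribution of the sum of two independent mass shifts.

    Truncates (never renormalizes) at ``max_shift``; the dropped tail mass is
    recoverable as ``1 - result.sum()``.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    full = np.convolve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    out = np.zeros(max_shift + 1)
    k = min(len(full), max_shift + 1)
    out[:k] = full[:k]
    return out


def composition_spectrum(
    comp: dict[str, int],
    max_shift: int,
    table: AbundanceTable | None = None,
) -> np.ndarray:
    """Theoretical mass-shift distribution of a whole elemental composition.

    Convolves each element's natural pattern raised to its atom count,
    truncated at ``max_shift``.  The empty composition yields ``[1.0]``
    padded with zeros (a massless placeholder).
    """
    table = table or default_table()
    spectrum = np.zeros(max_shift + 1)
    spectrum[0] = 1.0
    for element, count in comp.items():
        if count < 0:
            raise ValueError(f"negative atom count for {element}")
        if count == 0:
            continue
        # square-and-multiply keeps the number of convolutions logarithmic
        base = table[element].dense()
        power = np.zeros(1)
        power[0] = 1.0
        n = count
        while n:
            if n & 1:
                power = convolve(power, base, max_shift)
            n >>= 1
            if n:
                base = convolve(base, base, max_shift)
        spectrum = convolve(spectrum, power, max_shift)
    return spectrum
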