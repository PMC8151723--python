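"""Chemical formulas and per-element isotope mass distributions (IMDs).

An IMD is a dense vector of relative abundances indexed by integer mass shift
above the element's nominal (lightest principal isotope) mass: index 0 is the
monoisotopic form, index ``i`` the form carrying ``i`` extra neutrons. Natural
abundances come from a pinned table shipped with the package; the IMD of a
tracer-derived labeled atom is a purity/enrichment-weighted blend of a pure
m+1 atom and the natural distribution.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "AbundanceTable",
    "FormulaError",
    "ParameterError",
    "UnknownElementError",
    "default_table",
    "labeled_imd",
    "natural_imd",
    "parse_formula",
]


class FormulaError(ValueError):
    """A chemical formula string could not be parsed."""


class UnknownElementError(KeyError):
    """An element symbol is not present in the abundance table."""


class ParameterError(ValueError):
    """A numeric parameter (purity, enrichment) is out of range."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class AbundanceTable:
    """Natural isotope abundances for a set of elements.

    Maps element symbols to dense IMD vectors. Entries are validated to be
    non-negative and to sum to one within 1e-9 at load time.
    """

    def __init__(self, distributions: dict[str, np.ndarray]):
        self._imds: dict[str, np.ndarray] = {}
        for symbol, weights in distributions.items():
            w = np.asarray(weights, dtype=float)
            if w.ndim != 1 or w.size == 0:
                raise ValueError(f"IMD for {symbol!r} must be a non-empty vector")
            if np.any(w < 0):
                raise ValueError(f"IMD for {symbol!r} has negative weights")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"IMD for {symbol!r} sums to {w.sum():.12f}, expected 1"
                )
            w.setflags(write=False)
            self._imds[symbol] = w

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._imds

    def __getitem__(self, symbol: str) -> np.ndarray:
        try:
            return self._imds[symbol]
        except KeyError:
            raise UnknownElementError(
                f"element {symbol!r} is not in the abundance table "
                f"(known: {', '.join(sorted(self._imds))})"
            ) from None

    def elements(self) -> list[str]:
        return sorted(self._imds)

    @classmethod
    def from_text(cls, text: str) -> "AbundanceTable":
        """Parse the shipped ``element<TAB>mass_shift<TAB>abundance`` format."""
        rows: dict[str, dict[int, float]] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"abundance table line {lineno}: expected 3 fields")
            symbol, shift, abundance = parts[0], int(parts[1]), float(parts[2])
            rows.setdefault(symbol, {})[shift] = abundance
        dists = {}
        for symbol, shifts in rows.items():
            vec = np.zeros(max(shifts) + 1)
            for shift, abundance in shifts.items():
                vec[shift] = abundance
            dists[symbol] = vec
        return cls(dists)


@lru_cache(maxsize=1)
def default_table() -> AbundanceTable:
    """The pinned natural-abundance table shipped with the package."""
    text = (
        resources.files("midcorrect")
        .joinpath("data/isotope_abundances.tsv")
        .read_text()
    )
    return AbundanceTable.from_text(text)


def parse_formula(formula: str, table: AbundanceTable | None = None) -> dict[str, int]:
    """Parse a plain element+count formula such as ``"C11H13N2O2"``.

    Counts default to 1; repeated element tokens accumulate. The grammar has
    no parentheses, hydrates, or charges. Every symbol must be present in the
    abundance table.
    """
    if table is None:
        table = default_table()
    if not formula or not formula.strip():
        raise FormulaError("empty chemical formula")
    s = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            raise FormulaError(f"unparseable token at {s[pos:]!r} in formula {s!r}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in table:
            raise FormulaError(f"unknown element {symbol!r} in formula {s!r}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(f"non-positive count in token {m.group(0)!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return counts


def natural_imd(element: str, table: AbundanceTable | None = None) -> np.ndarray:
    """Natural IMD of one atom; length follows the pinned table's support."""
    if table is None:
        table = default_table()
    return table[element]


def labeled_imd(
    element: str,
    purity: float,
    enrichment: float,
    table: AbundanceTable | None = None,
) -> np.ndarray:
    """IMD of a tracer-derived labeled atom under tracer purity and enrichment.

    A labeled atom is fully enriched one mass unit above nominal; impure or
    under-enriched tracers contribute natural atoms instead, so the result is

        P*E * delta(m+1) + (1 - P*E) * natural_imd(element)

    where P is tracer purity and E the atom enrichment at labeled positions.
    Only the product P*E enters, so the two factors are not separately
    identifiable.
    """
    if not 0.0 <= purity <= 1.0:
        raise ParameterError(
            f"tracer purity must be a fraction in [0, 1], got {purity}; "
            "if the value is a percent, divide by 100"
        )
    if not 0.0 <= enrichment <= 1.0:
        raise ParameterError(
            f"label enrichment must be a fraction in [0, 1], got {enrichment}; "
            "if the value is a percent, divide by 100"
        )
    nat = natural_imd(element, table)
    pe = purity * enrichment
    out = np.zeros(max(2, nat.size))
    out[: nat.size] = (1.0 - pe) * nat
    out[1] += pe
    return out
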