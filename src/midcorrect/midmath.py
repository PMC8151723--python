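"""Polynomial arithmetic on isotope distributions.

The MID of a molecule is the product of its atoms' IMDs treated as
polynomials in a formal mass-shift variable: multiplying polynomials and
collecting terms of equal total degree is exactly discrete convolution of the
abundance vectors. No truncation is performed here — full-support vectors are
carried so that downstream correction-matrix columns keep their unit sums.
"""

from __future__ import annotations

from itertools import product
from math import prod

import numpy as np

from .isotope import UnknownElementError

__all__ = ["brute_force_mid", "convolve", "formula_mid", "imd_power"]

# exhaustive enumeration is exponential in atom count; this is a test oracle
_BRUTE_FORCE_MAX_ATOMS = 12


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Product of two distributions: out[k] = sum_i a[i] * b[k-i]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot convolve an empty distribution")
    return np.convolve(a, b)


def imd_power(a: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation; n = 0 gives [1]."""
    if n < 0:
        raise ValueError(f"power must be non-negative, got {n}")
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("cannot convolve an empty distribution")
    result = np.array([1.0])
    base = a
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def formula_mid(
    counts: dict[str, int], imd_map: dict[str, np.ndarray]
) -> np.ndarray:
    """Theoretical MID of a formula given one IMD per element.

    Convolves ``imd_map[e] ** counts[e]`` over the elements; the result sums
    to the product of the input sums, i.e. to one when every IMD is
    normalized. Iteration order of ``counts`` does not affect the result
    beyond floating-point round-off below 1e-12.
    """
    mid = np.array([1.0])
    for element, count in counts.items():
        if element not in imd_map:
            raise UnknownElementError(
                f"element {element!r} has no IMD in the supplied map"
            )
        mid = np.convolve(mid, imd_power(imd_map[element], count))
    return mid


def brute_force_mid(
    counts: dict[str, int], imd_map: dict[str, np.ndarray]
) -> np.ndarray:
    """Exhaustive-enumeration oracle for :func:`formula_mid`.

    Iterates every per-atom isotope assignment, accumulating the product of
    the per-atom abundances into the bin of the summed mass shift. Guarded to
    small molecules; intended for testing only.
    """
    atoms: list[np.ndarray] = []
    for element, count in counts.items():
        if element not in imd_map:
            raise UnknownElementError(
                f"element {element!r} has no IMD in the supplied map"
            )
        atoms.extend([np.asarray(imd_map[element], dtype=float)] * count)
    if len(atoms) > _BRUTE_FORCE_MAX_ATOMS:
        raise ValueError(
            f"brute-force enumeration limited to {_BRUTE_FORCE_MAX_ATOMS} atoms, "
            f"got {len(atoms)}"
        )
    support = sum(imd.size - 1 for imd in atoms) + 1
    mid = np.zeros(support)
    for shifts in product(*(range(imd.size) for imd in atoms)):
        mid[sum(shifts)] += prod(imd[i] for imd, i in zip(atoms, shifts))
    return mid
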