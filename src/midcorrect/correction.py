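"""Correction-matrix assembly and least-squares deconvolution.

Column k of the correction matrix is the theoretical MID of the measured
fragment guaranteed to carry k tracer-derived labeled atoms; the measured MID
is the matrix applied to the corrected MID, so the corrected MID is recovered
as the minimum-norm least-squares (Moore-Penrose) solution. High-resolution
acquisition is modeled per element by collapsing the IMD of every resolved
non-tracer element to pure nominal mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .isotope import (
    AbundanceTable,
    ParameterError,
    default_table,
    labeled_imd,
    natural_imd,
)
from .midmath import convolve, formula_mid, imd_power

__all__ = [
    "HIGH_RES_ALL",
    "HIGH_RES_NONE",
    "CorrectionMatrix",
    "CorrectionResult",
    "FragmentSpec",
    "build_correction_matrix",
    "component_mid",
    "correct",
    "effective_imd_map",
]

#: Sentinel: heavy isotopes of every non-tracer element are resolved.
HIGH_RES_ALL = "all"
#: Sentinel: no element is resolved (low-resolution data).
HIGH_RES_NONE = "none"


def _normalize_high_res(high_res) -> frozenset | str:
    if isinstance(high_res, str):
        token = high_res.strip().lower()
        if token in (HIGH_RES_ALL, HIGH_RES_NONE):
            return token
        return frozenset(high_res.split())
    return frozenset(high_res)


@dataclass(frozen=True)
class FragmentSpec:
    """Full description of one correction task.

    Parameters
    ----------
    name : str
        Fragment label used in reports.
    fragment_formula : dict
        Element -> atom count of the measured ion species (for electrospray
        LC-MS usually the whole, possibly protonated, metabolite; for EI
        GC-MS a fragment of the derivatized metabolite).
    can_acquire_label : dict
        Element -> count of atoms that can possibly acquire label from the
        tracer. Only the tracer element's entry matters; atoms contributed by
        a derivatization reagent are excluded here and always carry the
        natural IMD.
    labeled_element : str
        Chemical symbol of the heavy-isotope-labeled element on the tracer.
    tracer_enrichment, label_enrichment : float
        Tracer purity P and labeled-position atom enrichment E, both
        fractions in [0, 1]. Only the product P*E enters the model.
    high_res : set of str, or "all"/"none"
        Elements whose heavy-isotope mass shifts the instrument resolves from
        those of the tracer element.
    measured_mid : sequence of float, optional
        Measured mass isotopologue distribution (relative abundances from
        m+0 upward). May be None for a forward-simulation skeleton.
    """

    name: str
    fragment_formula: dict
    can_acquire_label: dict
    labeled_element: str
    tracer_enrichment: float = 1.0
    label_enrichment: float = 1.0
    high_res: frozenset | str = HIGH_RES_NONE
    measured_mid: tuple | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "high_res", _normalize_high_res(self.high_res)
        )
        object.__setattr__(
            self, "fragment_formula", dict(self.fragment_formula)
        )
        object.__setattr__(
            self, "can_acquire_label", dict(self.can_acquire_label)
        )
        for element, count in self.can_acquire_label.items():
            if count > self.fragment_formula.get(element, 0):
                raise ValueError(
                    f"CanAcquireLabel has {count} {element} atoms but the "
                    f"fragment formula has only "
                    f"{self.fragment_formula.get(element, 0)}"
                )
        if self.labeled_element not in self.fragment_formula:
            raise ValueError(
                f"labeled element {self.labeled_element!r} does not occur in "
                "the fragment formula"
            )
        for value, what in (
            (self.tracer_enrichment, "TracerEnrichment"),
            (self.label_enrichment, "LabelEnrichment"),
        ):
            if not 0.0 <= value <= 1.0:
                raise ParameterError(
                    f"{what} must be a fraction in [0, 1], got {value}; "
                    "if the value is a percent, divide by 100"
                )
        if (
            isinstance(self.high_res, frozenset)
            and self.labeled_element in self.high_res
        ):
            raise ValueError(
                f"the labeled element {self.labeled_element!r} cannot be "
                "listed in HighRes: its own mass shifts are the signal"
            )
        if self.measured_mid is not None:
            mid = np.asarray(self.measured_mid, dtype=float)
            if mid.ndim != 1 or mid.size == 0:
                raise ValueError("measured MID must be a non-empty vector")
            if np.any(mid < 0):
                raise ValueError("measured MID entries must be non-negative")
            if mid.sum() == 0:
                raise ValueError("measured MID is all zero")
            object.__setattr__(self, "measured_mid", tuple(float(v) for v in mid))

    @property
    def n_label(self) -> int:
        """Number of fragment atoms that can carry tracer label."""
        return int(self.can_acquire_label.get(self.labeled_element, 0))

    def is_resolved(self, element: str) -> bool:
        """Whether this element's heavy isotopes are resolved from the tracer's."""
        if element == self.labeled_element:
            return False
        if self.high_res == HIGH_RES_ALL:
            return True
        if self.high_res == HIGH_RES_NONE:
            return False
        return element in self.high_res

    def with_measured(self, measured_mid) -> "FragmentSpec":
        return replace(self, measured_mid=tuple(np.asarray(measured_mid, float)))


@dataclass(frozen=True)
class CorrectionMatrix:
    """R x K matrix whose column k is the k-labeled-atoms theoretical MID."""

    values: np.ndarray
    n_label: int

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrectionResult:
    """Corrected MID with residual diagnostics.

    ``corrected_mid`` has n_label + 1 entries (label counts 0..n_label) and
    may contain negative values: they have no physical meaning but are
    reported as computed, since zeroing them would break the unit sum.
    """

    name: str
    corrected_mid: np.ndarray
    residuals: np.ndarray
    sse: float
    matrix: CorrectionMatrix
    warnings: list = field(default_factory=list)

    @property
    def mid_c(self) -> np.ndarray:
        """Alias for the corrected MID."""
        return self.corrected_mid


def effective_imd_map(
    spec: FragmentSpec, table: AbundanceTable | None = None
) -> dict[str, np.ndarray]:
    """Per-element IMDs after applying the high-resolution semantics.

    Resolved elements contribute no mass shift to the tracer-element
    isotopologue axis, so their IMD collapses to pure nominal mass ``[1]``;
    every other element keeps its natural IMD. The labeled-atom IMD is not
    part of this map — it is applied per matrix column.
    """
    if table is None:
        table = default_table()
    return {
        element: np.array([1.0]) if spec.is_resolved(element)
        else natural_imd(element, table)
        for element in spec.fragment_formula
    }


def component_mid(
    spec: FragmentSpec, k: int, table: AbundanceTable | None = None
) -> np.ndarray:
    """Theoretical MID of the fragment with exactly k tracer-derived labels.

    k atoms of the tracer element carry the purity/enrichment-adjusted
    labeled-atom IMD; the remaining tracer-element atoms — including any that
    cannot acquire label, e.g. derivatization-reagent atoms — and all other
    elements carry their effective (natural or resolution-collapsed) IMDs.
    Full support, no truncation.
    """
    if not 0 <= k <= spec.n_label:
        raise ValueError(f"label count {k} outside 0..{spec.n_label}")
    if table is None:
        table = default_table()
    eff = effective_imd_map(spec, table)
    lab = labeled_imd(
        spec.labeled_element,
        spec.tracer_enrichment,
        spec.label_enrichment,
        table,
    )
    counts = dict(spec.fragment_formula)
    counts[spec.labeled_element] -= k
    if counts[spec.labeled_element] == 0:
        del counts[spec.labeled_element]
    return convolve(imd_power(lab, k), formula_mid(counts, eff))


def build_correction_matrix(
    spec: FragmentSpec, table: AbundanceTable | None = None
) -> CorrectionMatrix:
    """Assemble the correction matrix for a fragment.

    The row count covers both the measured MID and the longest component
    support; shorter columns are zero-padded so every column keeps its full
    (unit, when P = E = 1) mass.
    """
    if table is None:
        table = default_table()
    columns = [component_mid(spec, k, table) for k in range(spec.n_label + 1)]
    measured_len = 0 if spec.measured_mid is None else len(spec.measured_mid)
    n_rows = max(measured_len, max(col.size for col in columns))
    values = np.zeros((n_rows, spec.n_label + 1))
    for k, col in enumerate(columns):
        values[: col.size, k] = col
    return CorrectionMatrix(values=values, n_label=spec.n_label)


def correct(
    spec: FragmentSpec, table: AbundanceTable | None = None
) -> CorrectionResult:
    """Correct a measured MID for natural abundance, purity and enrichment.

    Thin functional wrapper over :class:`midcorrect.MIDCorrector`; see that
    class for the solver contract.
    """
    from .estimator import MIDCorrector

    if spec.measured_mid is None:
        raise ValueError("FragmentSpec has no measured MID to correct")
    est = MIDCorrector.from_spec(spec, table=table)
    return est.fit().correct(spec.measured_mid, name=spec.name)
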