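"""Scikit-learn style estimator for natural-abundance MID correction."""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .correction import (
    HIGH_RES_NONE,
    CorrectionMatrix,
    CorrectionResult,
    FragmentSpec,
    build_correction_matrix,
)
from .isotope import AbundanceTable, default_table, parse_formula

__all__ = ["MIDCorrector"]

logger = logging.getLogger("midcorrect")

# measured MIDs are relative peak areas; user rounding can leave the sum
# slightly off one — beyond this we renormalize (with a warning) before solving
_SUM_TOLERANCE = 1e-3


class MIDCorrector(TransformerMixin, BaseEstimator):
    """Remove natural heavy-isotope contributions from measured MIDs.

    The transformer maps rows of measured mass isotopologue distributions to
    corrected distributions over tracer-label counts 0..n. Fitting builds the
    correction matrix whose column k is the theoretical MID of the fragment
    with exactly k tracer-derived labeled atoms; transforming solves the
    resulting linear system by minimum-norm least squares (the Moore-Penrose
    pseudo-inverse solution), which covers square, over- and under-determined
    cases with one contract.

    Parameters
    ----------
    formula : str
        Fragment chemical formula, e.g. ``"C3H7NO3"`` for serine.
    can_acquire_label : str or None
        Formula of the atoms that can acquire label from the tracer; None
        means the whole fragment formula (no derivatization-reagent atoms).
    labeled_element : str, default "C"
        Tracer element symbol.
    tracer_enrichment, label_enrichment : float, default 1.0
        Tracer purity P and labeled-position atom enrichment E (fractions).
    high_res : str or iterable of str, default "none"
        Elements resolved from the tracer element, or ``"all"``/``"none"``.

    Attributes
    ----------
    spec_ : FragmentSpec
        The validated fragment description.
    n_labelable_ : int
        Number of atoms that can carry label; corrected MIDs have
        ``n_labelable_ + 1`` components.
    correction_matrix_ : ndarray of shape (n_rows_, n_labelable_ + 1)
        Full-support correction matrix.

    Examples
    --------
    >>> corr = MIDCorrector("C3H7NO3", labeled_element="C").fit()
    >>> corr.transform([[0.917, 0.073, 0.009, 0.001]]).shape
    (1, 4)
    """

    def __init__(
        self,
        formula: str,
        can_acquire_label: str | None = None,
        labeled_element: str = "C",
        tracer_enrichment: float = 1.0,
        label_enrichment: float = 1.0,
        high_res="none",
    ):
        self.formula = formula
        self.can_acquire_label = can_acquire_label
        self.labeled_element = labeled_element
        self.tracer_enrichment = tracer_enrichment
        self.label_enrichment = label_enrichment
        self.high_res = high_res

    @classmethod
    def from_spec(
        cls, spec: FragmentSpec, table: AbundanceTable | None = None
    ) -> "MIDCorrector":
        """Build an (unfitted) estimator from a :class:`FragmentSpec`."""
        est = cls(formula="")
        est._prebuilt_spec = spec
        est._table = table
        return est

    def _build_spec(self) -> FragmentSpec:
        if getattr(self, "_prebuilt_spec", None) is not None:
            return self._prebuilt_spec
        table = self._get_table()
        formula = parse_formula(self.formula, table)
        if self.can_acquire_label is None:
            labelable = dict(formula)
        else:
            labelable = parse_formula(self.can_acquire_label, table)
        return FragmentSpec(
            name=self.formula,
            fragment_formula=formula,
            can_acquire_label=labelable,
            labeled_element=self.labeled_element,
            tracer_enrichment=self.tracer_enrichment,
            label_enrichment=self.label_enrichment,
            high_res=self.high_res if self.high_res is not None else HIGH_RES_NONE,
        )

    def _get_table(self) -> AbundanceTable:
        table = getattr(self, "_table", None)
        return table if table is not None else default_table()

    def fit(self, X=None, y=None) -> "MIDCorrector":
        """Assemble the correction matrix; X and y are ignored."""
        spec = self._build_spec()
        matrix = build_correction_matrix(spec, self._get_table())
        self.spec_ = spec
        self.n_labelable_ = spec.n_label
        self.correction_matrix_ = matrix.values
        self.n_rows_ = matrix.values.shape[0]
        return self

    def _padded_matrix(self, n_bins: int) -> np.ndarray:
        check_is_fitted(self, "correction_matrix_")
        if n_bins <= self.n_rows_:
            return self.correction_matrix_
        padded = np.zeros((n_bins, self.n_labelable_ + 1))
        padded[: self.n_rows_] = self.correction_matrix_
        return padded

    def correct(self, measured_mid, name: str = "") -> CorrectionResult:
        """Correct one measured MID, returning full diagnostics.

        The measured vector is renormalized (with a warning) if its sum
        deviates from one by more than 1e-3, zero-padded to the matrix row
        count, and deconvolved by minimum-norm least squares. Negative
        corrected components are retained and flagged, never clipped.
        """
        check_is_fitted(self, "correction_matrix_")
        measured = np.asarray(measured_mid, dtype=float)
        if measured.ndim != 1 or measured.size == 0:
            raise ValueError("measured MID must be a non-empty vector")
        if np.any(measured < 0):
            raise ValueError("measured MID entries must be non-negative")
        total = measured.sum()
        if total == 0:
            raise ValueError("measured MID is all zero")
        warnings: list[str] = []
        if abs(total - 1.0) > _SUM_TOLERANCE:
            warnings.append(
                f"measured MID sums to {total:.6f}; renormalized to 1 before solving"
            )
            measured = measured / total
        cm = self._padded_matrix(measured.size)
        n_rows = cm.shape[0]
        if n_rows > measured.size:
            padded_mass = cm[measured.size :, :].sum(axis=0)
            warnings.append(
                f"measured MID has {measured.size} bins but the theoretical "
                f"support spans {n_rows}; missing bins assumed zero "
                f"(up to {padded_mass.max():.3%} of a column's mass lies in "
                "the padded rows)"
            )
        y = np.zeros(n_rows)
        y[: measured.size] = measured
        x, _, rank, _ = np.linalg.lstsq(cm, y, rcond=None)
        if rank < self.n_labelable_ + 1:
            warnings.append(
                f"correction matrix is rank deficient (rank {rank} < "
                f"{self.n_labelable_ + 1}); minimum-norm solution returned"
            )
        residuals = y - cm @ x
        sse = float(residuals @ residuals)
        negative = np.flatnonzero(x < 0)
        if negative.size:
            listed = ", ".join(
                f"m+{i}: {x[i]:.3e}" for i in negative
            )
            warnings.append(
                "corrected MID has negative components (reported as computed, "
                f"not clipped): {listed}"
            )
        for message in warnings:
            logger.warning("%s: %s", name or "fragment", message)
        return CorrectionResult(
            name=name,
            corrected_mid=x,
            residuals=residuals,
            sse=sse,
            matrix=CorrectionMatrix(values=cm, n_label=self.n_labelable_),
            warnings=warnings,
        )

    def transform(self, X) -> np.ndarray:
        """Correct each row of X; returns (n_samples, n_labelable_ + 1)."""
        check_is_fitted(self, "correction_matrix_")
        X = check_array(X, dtype=float, ensure_min_samples=1)
        return np.vstack([self.correct(row).corrected_mid for row in X])

    def inverse_transform(self, X) -> np.ndarray:
        """Forward model: map label-count weights back to measured-space MIDs."""
        check_is_fitted(self, "correction_matrix_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_labelable_ + 1:
            raise ValueError(
                f"expected {self.n_labelable_ + 1} label-count columns, "
                f"got {X.shape[1]}"
            )
        return X @ self.correction_matrix_.T
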