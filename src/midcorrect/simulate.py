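"""Forward simulation of measured MIDs with known ground truth.

Generates random fragments and synthesizes their measured MIDs from a known
true label-count distribution by running the correction model forward
(weighting the correction-matrix columns), optionally perturbed by
multiplicative lognormal noise — MID components are relative peak areas, so
noise that scales with the signal is the natural choice. All randomness is
behind explicit integer seeds.
"""

from __future__ import annotations

import numpy as np

from .correction import FragmentSpec, build_correction_matrix
from .isotope import AbundanceTable

__all__ = ["forward_measure", "random_fragment", "random_weights"]

_ELEMENT_POOL = ("C", "H", "N", "O", "S", "Si")


def random_fragment(
    seed: int,
    max_atoms: int = 20,
    labeled_element: str = "C",
    tracer_enrichment: float = 1.0,
    label_enrichment: float = 1.0,
    high_res="none",
) -> FragmentSpec:
    """Deterministic-in-seed random fragment skeleton (no measured MID).

    The fragment always contains at least one tracer-element atom, and the
    number of labelable atoms is a random value between 1 and the tracer-atom
    count — atoms beyond it model e.g. derivatization-reagent carbon.
    """
    if max_atoms < 2:
        raise ValueError("max_atoms must be at least 2")
    rng = np.random.default_rng(seed)
    n_atoms = int(rng.integers(2, max_atoms + 1))
    counts: dict[str, int] = {labeled_element: 1}
    for _ in range(n_atoms - 1):
        element = _ELEMENT_POOL[rng.integers(0, len(_ELEMENT_POOL))]
        counts[element] = counts.get(element, 0) + 1
    n_tracer = counts[labeled_element]
    n_labelable = int(rng.integers(1, n_tracer + 1))
    return FragmentSpec(
        name=f"synthetic-seed{seed}",
        fragment_formula=counts,
        can_acquire_label={labeled_element: n_labelable},
        labeled_element=labeled_element,
        tracer_enrichment=tracer_enrichment,
        label_enrichment=label_enrichment,
        high_res=high_res,
    )


def random_weights(spec: FragmentSpec, seed: int) -> np.ndarray:
    """Random convex label-count weight vector of length n_label + 1."""
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(spec.n_label + 1))
    return w


def forward_measure(
    spec: FragmentSpec,
    true_weights,
    noise_cv: float = 0.0,
    seed: int = 0,
    table: AbundanceTable | None = None,
) -> np.ndarray:
    """Synthesize a measured MID from known label-count weights.

    Computes the forward model ``CM @ w``, multiplies each isotopologue by an
    independent lognormal factor with the requested coefficient of variation,
    and renormalizes to unit sum. ``noise_cv = 0`` gives the exact forward
    model.
    """
    w = np.asarray(true_weights, dtype=float)
    if w.size != spec.n_label + 1:
        raise ValueError(
            f"expected {spec.n_label + 1} weights (label counts 0..{spec.n_label}), "
            f"got {w.size}"
        )
    if np.any(w < 0):
        raise ValueError("true weights must be non-negative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    cm = build_correction_matrix(spec, table)
    measured = cm.values @ w
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=measured.size)
        measured = measured * factors
        measured = measured / measured.sum()
    return measured
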