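"""Correction-matrix assembly and least-squares deconvolution."""

import numpy as np
import pytest

from midcorrect import (
    FragmentSpec,
    brute_force_mid,
    build_correction_matrix,
    component_mid,
    correct,
    effective_imd_map,
    labeled_imd,
    natural_imd,
    parse_formula,
)
from midcorrect.midmath import convolve, formula_mid, imd_power
from midcorrect.simulate import forward_measure, random_fragment, random_weights


class TestFragmentSpec:
    def test_rejects_label_count_exceeding_formula(self):
        with pytest.raises(ValueError, match="CanAcquireLabel"):
            FragmentSpec("x", {"C": 2}, {"C": 3}, "C")

    def test_rejects_tracer_element_in_high_res(self):
        with pytest.raises(ValueError, match="HighRes"):
            FragmentSpec("x", {"C": 2, "H": 2}, {"C": 2}, "C", high_res={"C", "H"})

    def test_rejects_percent_style_enrichment(self):
        with pytest.raises(ValueError, match="divide by 100"):
            FragmentSpec("x", {"C": 2}, {"C": 2}, "C", tracer_enrichment=99.0)

    def test_rejects_all_zero_measured_mid(self):
        with pytest.raises(ValueError, match="zero"):
            FragmentSpec("x", {"C": 2}, {"C": 2}, "C", measured_mid=[0.0, 0.0])

    def test_label_count_uses_tracer_element_entry_only(self, tryptophan_spec):
        assert tryptophan_spec.n_label == 11


class TestEffectiveImdMap:
    def test_resolved_elements_collapse_to_nominal_mass(self, tryptophan_spec, table):
        eff = effective_imd_map(tryptophan_spec, table)
        for element in ("N", "O", "H"):
            np.testing.assert_array_equal(eff[element], [1.0])
        np.testing.assert_array_equal(eff["C"], natural_imd("C", table))

    def test_low_resolution_keeps_all_natural(self, serine_spec, table):
        eff = effective_imd_map(serine_spec, table)
        for element in ("C", "H", "N", "O"):
            np.testing.assert_array_equal(eff[element], natural_imd(element, table))

    def test_all_sentinel_spares_only_the_tracer(self, table):
        spec = FragmentSpec("x", parse_formula("C2H3NO"), {"C": 2}, "C", high_res="all")
        eff = effective_imd_map(spec, table)
        assert eff["C"].size > 1
        for element in ("H", "N", "O"):
            np.testing.assert_array_equal(eff[element], [1.0])


class TestComponentMid:
    def test_zero_labels_is_the_natural_mid(self, serine_spec, table):
        expected = formula_mid(
            serine_spec.fragment_formula,
            {e: natural_imd(e, table) for e in "CHNO"},
        )
        np.testing.assert_allclose(component_mid(serine_spec, 0, table), expected,
                                   atol=1e-15)

    def test_one_label_replaces_one_carbon(self, serine_spec, table):
        # MID of C_L C2 H7 N O3 with IMD(C_L) = [0, 1]
        rest = formula_mid(
            {"C": 2, "H": 7, "N": 1, "O": 3},
            {e: natural_imd(e, table) for e in "CHNO"},
        )
        expected = convolve(labeled_imd("C", 1, 1, table), rest)
        np.testing.assert_allclose(component_mid(serine_spec, 1, table), expected,
                                   atol=1e-15)

    def test_fully_labeled_high_res_fragment_is_delta(self, table):
        spec = FragmentSpec("x", parse_formula("C3H4O2"), {"C": 3}, "C",
                            high_res="all")
        out = component_mid(spec, 3, table)
        delta = np.zeros(out.size)
        delta[3] = 1.0
        np.testing.assert_allclose(out, delta, atol=1e-15)

    def test_non_labelable_tracer_atoms_stay_natural(self, table):
        # 1 of 2 carbons is derivatization-derived: column 1 still carries one
        # natural carbon, so its support extends past the labeled shift
        spec = FragmentSpec("x", {"C": 2}, {"C": 1}, "C")
        out = component_mid(spec, 1, table)
        expected = convolve(labeled_imd("C", 1, 1, table), natural_imd("C", table))
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_out_of_range_label_count(self, serine_spec, table):
        with pytest.raises(ValueError):
            component_mid(serine_spec, 4, table)


class TestBuildCorrectionMatrix:
    def test_serine_has_four_columns(self, serine_spec, table):
        cm = build_correction_matrix(serine_spec, table)
        assert cm.n_columns == 4

    def test_rows_cover_measured_and_support(self, tryptophan_spec, table):
        cm = build_correction_matrix(tryptophan_spec, table)
        assert cm.n_columns == 12
        assert cm.n_rows == 12  # C11 support (11 shifts) exceeds the 3 measured bins

    def test_columns_sum_to_one_at_full_support(self, table, rng):
        for _ in range(20):
            spec = random_fragment(int(rng.integers(2**31)), max_atoms=40)
            cm = build_correction_matrix(spec, table)
            np.testing.assert_allclose(
                cm.values.sum(axis=0), np.ones(cm.n_columns), atol=1e-9
            )
            assert np.all(cm.values >= 0)

    def test_single_label_monoisotopic_tracer_all_high_res_is_identity(self, table):
        # phosphorus is naturally monoisotopic, so with every other element
        # resolved both columns collapse to deltas
        spec = FragmentSpec(
            "x", {"P": 1, "O": 3}, {"P": 1}, "P", high_res="all",
            measured_mid=[0.7, 0.3],
        )
        cm = build_correction_matrix(spec, table)
        np.testing.assert_allclose(cm.values, np.eye(2), atol=1e-15)

    def test_low_res_c2_columns_match_oracle(self, table):
        spec = FragmentSpec("x", {"C": 2}, {"C": 2}, "C")
        cm = build_correction_matrix(spec, table)
        natural = {"C": natural_imd("C", table)}
        labeled = {"C": labeled_imd("C", 1, 1, table)}
        col0 = brute_force_mid({"C": 2}, natural)
        col2 = brute_force_mid({"C": 2}, labeled)
        np.testing.assert_allclose(cm.values[: col0.size, 0], col0, atol=1e-12)
        np.testing.assert_allclose(cm.values[: col2.size, 2], col2, atol=1e-12)


class TestCorrect:
    def test_unlabeled_sample_recovers_delta(self, serine_spec, table):
        cm = build_correction_matrix(serine_spec, table)
        spec = serine_spec.with_measured(cm.values[:, 0])
        result = correct(spec, table)
        expected = np.zeros(4)
        expected[0] = 1.0
        np.testing.assert_allclose(result.corrected_mid, expected, atol=1e-10)
        assert result.sse < 1e-20

    def test_forward_model_round_trip(self, table, rng):
        for _ in range(20):
            seed = int(rng.integers(2**31))
            spec = random_fragment(seed, max_atoms=25)
            w = random_weights(spec, seed + 1)
            measured = forward_measure(spec, w, noise_cv=0.0, table=table)
            result = correct(spec.with_measured(measured), table)
            np.testing.assert_allclose(result.corrected_mid, w, atol=1e-8)
            assert result.sse < 1e-16

    def test_sum_conservation_on_consistent_data(self, serine_spec, table, rng):
        # columns sum to one, so an exactly solvable measurement conserves
        # total mass: left-multiplying the forward model by a row of ones
        cm = build_correction_matrix(serine_spec, table)
        w = rng.dirichlet(np.ones(4)) * 0.9995  # slightly off-unit total
        spec = serine_spec.with_measured(cm.values @ w)
        result = correct(spec, table)
        assert result.corrected_mid.sum() == pytest.approx(0.9995, abs=1e-6)

    def test_sum_conservation_tryptophan(self, tryptophan_spec, table):
        result = correct(tryptophan_spec, table)
        assert result.corrected_mid.sum() == pytest.approx(
            sum(tryptophan_spec.measured_mid), abs=1e-6
        )

    def test_negative_components_retained_and_flagged(self, tryptophan_spec, table):
        result = correct(tryptophan_spec, table)
        assert np.any(result.corrected_mid < 0)
        assert any("negative" in w for w in result.warnings)

    def test_off_unit_measured_sum_renormalized_with_warning(self, table):
        spec = FragmentSpec(
            "x", {"C": 2, "H": 4}, {"C": 2}, "C", measured_mid=[1.8, 0.15, 0.05]
        )
        result = correct(spec, table)
        assert any("renormalized" in w for w in result.warnings)
        # solved against the renormalized vector, so total mass is near one
        # (not exact: the padded system is inconsistent, residuals absorb some)
        assert result.corrected_mid.sum() == pytest.approx(1.0, abs=1e-3)

    def test_sse_equals_squared_residual_norm(self, tryptophan_spec, table):
        result = correct(tryptophan_spec, table)
        assert result.sse == pytest.approx(result.residuals @ result.residuals,
                                           abs=1e-12)

    def test_high_res_all_equals_reduced_tracer_only_formula(self, table, rng):
        measured = rng.dirichlet(np.ones(6))
        full = FragmentSpec(
            "x", parse_formula("C5H10N2O3S"), {"C": 5}, "C", high_res="all",
            measured_mid=measured,
        )
        reduced = FragmentSpec(
            "x", {"C": 5}, {"C": 5}, "C", high_res="none", measured_mid=measured
        )
        np.testing.assert_allclose(
            correct(full, table).corrected_mid,
            correct(reduced, table).corrected_mid,
            atol=1e-10,
        )

    def test_idempotent_on_already_consistent_data(self, serine_spec, table):
        cm = build_correction_matrix(serine_spec, table)
        sc = np.array([0.4, 0.3, 0.2, 0.1])
        spec = serine_spec.with_measured(cm.values @ sc)
        result = correct(spec, table)
        np.testing.assert_allclose(result.corrected_mid, sc, atol=1e-10)

    def test_assumed_purity_drop_shifts_weight_to_higher_labels(self, table):
        # measured MID generated at P*E = 0.9: as the assumed purity falls,
        # the same spectrum implies more labeled atoms, never fewer
        base = FragmentSpec("x", {"C": 4, "H": 6, "O": 2}, {"C": 4}, "C",
                            tracer_enrichment=0.9)
        measured = forward_measure(base, [0.2, 0.3, 0.3, 0.15, 0.05], table=table)
        mean_labels = []
        for assumed in (1.0, 0.95, 0.9):
            spec = FragmentSpec("x", {"C": 4, "H": 6, "O": 2}, {"C": 4}, "C",
                                tracer_enrichment=assumed,
                                measured_mid=measured)
            mid = correct(spec, table).corrected_mid
            mean_labels.append(np.arange(5) @ mid)
        assert mean_labels[0] <= mean_labels[1] <= mean_labels[2]
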