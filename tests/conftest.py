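import numpy as np
import pytest

from midcorrect import FragmentSpec, default_table, parse_formula

TRYPTOPHAN_INPUT = """\
FragmentName: TryptophanProtonated

FragmentFormula: C11H13N2O2

CanAcquireLabel: C11H13N2O2

MIDm: 0.88885 0.106829 0.004322

LabeledElement: C

TracerEnrichment: 1

LabelEnrichment: 1

HighRes: N O H
"""


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture
def tryptophan_spec():
    """Protonated tryptophan from an unlabeled sample, high-res carbon tracing."""
    return FragmentSpec(
        name="TryptophanProtonated",
        fragment_formula=parse_formula("C11H13N2O2"),
        can_acquire_label=parse_formula("C11H13N2O2"),
        labeled_element="C",
        tracer_enrichment=1.0,
        label_enrichment=1.0,
        high_res=frozenset({"N", "O", "H"}),
        measured_mid=[0.88885, 0.106829, 0.004322],
    )


@pytest.fixture
def serine_spec():
    """Serine (C3H7NO3) in a 13C-glucose tracing experiment, low resolution."""
    return FragmentSpec(
        name="Serine",
        fragment_formula=parse_formula("C3H7NO3"),
        can_acquire_label=parse_formula("C3H7NO3"),
        labeled_element="C",
    )


@pytest.fixture
def tryptophan_file(tmp_path):
    path = tmp_path / "tryptophan.txt"
    path.write_text(TRYPTOPHAN_INPUT)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
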