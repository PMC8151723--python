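"""Reading the plain-text fragment input format and writing results.

The input format is a key:value text file with eight keys::

    FragmentName: TryptophanProtonated
    FragmentFormula: C11H13N2O2
    CanAcquireLabel: C11H13N2O2
    MIDm: 0.88885 0.106829 0.004322
    LabeledElement: C
    TracerEnrichment: 1
    LabelEnrichment: 1
    HighRes: N O H

Keys are case-sensitive, key order is not significant, blank lines are
ignored, and lines starting with ``#`` are treated as comments. Enrichment
values are fractions in [0, 1]. ``HighRes`` lists element symbols separated
by spaces, or the single word ``all`` or ``none``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .correction import FragmentSpec, CorrectionResult, correct
from .isotope import AbundanceTable, FormulaError, ParameterError, parse_formula

__all__ = [
    "InputFileError",
    "format_result",
    "parse_input_file",
    "parse_input_text",
    "run_correction",
    "serialize_spec",
    "write_result",
]

logger = logging.getLogger("midcorrect")

REQUIRED_KEYS = (
    "FragmentName",
    "FragmentFormula",
    "CanAcquireLabel",
    "MIDm",
    "LabeledElement",
    "TracerEnrichment",
    "LabelEnrichment",
    "HighRes",
)


class InputFileError(ValueError):
    """A fragment input file is malformed; the message names line and key."""


def _collect_pairs(text: str, source: str) -> dict[str, tuple[int, str]]:
    pairs: dict[str, tuple[int, str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise InputFileError(
                f"{source}, line {lineno}: expected 'Key: value', got {line!r}"
            )
        key, _, value = line.partition(":")
        key = key.strip()
        if key in pairs:
            raise InputFileError(
                f"{source}, line {lineno}: duplicate key {key!r}"
            )
        pairs[key] = (lineno, value.strip())
    return pairs


def _parse_fraction(pairs, key: str, source: str) -> float:
    lineno, raw = pairs[key]
    try:
        value = float(raw)
    except ValueError:
        raise InputFileError(
            f"{source}, line {lineno}: {key} value {raw!r} is not a number"
        ) from None
    if not 0.0 <= value <= 1.0:
        raise InputFileError(
            f"{source}, line {lineno}: {key} must be a fraction in [0, 1], "
            f"got {value}; if the value is a percent, divide by 100"
        )
    return value


def parse_input_text(
    text: str,
    source: str = "<input>",
    table: AbundanceTable | None = None,
) -> FragmentSpec:
    """Parse the key:value fragment format from a string."""
    pairs = _collect_pairs(text, source)
    missing = [k for k in REQUIRED_KEYS if k not in pairs]
    if missing:
        raise InputFileError(f"{source}: missing key(s) {', '.join(missing)}")

    def formula_of(key):
        lineno, raw = pairs[key]
        try:
            return parse_formula(raw, table)
        except FormulaError as exc:
            raise InputFileError(
                f"{source}, line {lineno}: {key}: {exc}"
            ) from None

    lineno, raw_mid = pairs["MIDm"]
    try:
        mid = [float(token) for token in raw_mid.split()]
    except ValueError:
        raise InputFileError(
            f"{source}, line {lineno}: MIDm contains a malformed number in "
            f"{raw_mid!r}"
        ) from None
    if not mid:
        raise InputFileError(f"{source}, line {lineno}: MIDm is empty")
    if any(v < 0 for v in mid):
        raise InputFileError(
            f"{source}, line {lineno}: MIDm values must be non-negative"
        )

    lineno_hr, raw_hr = pairs["HighRes"]
    high_res = raw_hr.strip()
    if high_res.lower() not in ("all", "none"):
        tokens = high_res.split()
        from .isotope import default_table

        tbl = table if table is not None else default_table()
        for token in tokens:
            if token not in tbl:
                raise InputFileError(
                    f"{source}, line {lineno_hr}: HighRes lists unknown "
                    f"element {token!r}"
                )
        high_res = frozenset(tokens)
    else:
        high_res = high_res.lower()

    try:
        return FragmentSpec(
            name=pairs["FragmentName"][1],
            fragment_formula=formula_of("FragmentFormula"),
            can_acquire_label=formula_of("CanAcquireLabel"),
            labeled_element=pairs["LabeledElement"][1],
            tracer_enrichment=_parse_fraction(pairs, "TracerEnrichment", source),
            label_enrichment=_parse_fraction(pairs, "LabelEnrichment", source),
            high_res=high_res,
            measured_mid=mid,
        )
    except (ValueError, ParameterError) as exc:
        raise InputFileError(f"{source}: {exc}") from None


def parse_input_file(path, table: AbundanceTable | None = None) -> FragmentSpec:
    """Parse one fragment input file into a validated :class:`FragmentSpec`."""
    path = Path(path)
    return parse_input_text(path.read_text(), source=str(path), table=table)


def parse_batch_text(text: str, source: str = "<input>", table=None):
    """Split a multi-record file into FragmentSpecs.

    A new record starts at each ``FragmentName:`` line, so single-record
    files with blank lines between keys parse unchanged.
    """
    blocks: list[list[str]] = []
    for raw in text.splitlines():
        stripped = raw.strip()
        if stripped.startswith("FragmentName"):
            blocks.append([])
        if blocks:
            blocks[-1].append(raw)
    if not blocks:
        raise InputFileError(f"{source}: no FragmentName record found")
    return [
        parse_input_text("\n".join(block), source=f"{source}[record {i}]", table=table)
        for i, block in enumerate(blocks)
    ]


def _format_counts(counts: dict) -> str:
    return "".join(
        f"{el}{n if n > 1 else ''}" for el, n in counts.items()
    )


def serialize_spec(spec: FragmentSpec) -> str:
    """Render a FragmentSpec back into the key:value input format."""
    if isinstance(spec.high_res, str):
        high_res = spec.high_res
    else:
        high_res = " ".join(sorted(spec.high_res)) if spec.high_res else "none"
    mid = " ".join(repr(v) for v in (spec.measured_mid or ()))
    return (
        f"FragmentName: {spec.name}\n"
        f"FragmentFormula: {_format_counts(spec.fragment_formula)}\n"
        f"CanAcquireLabel: {_format_counts(spec.can_acquire_label)}\n"
        f"MIDm: {mid}\n"
        f"LabeledElement: {spec.labeled_element}\n"
        f"TracerEnrichment: {spec.tracer_enrichment!r}\n"
        f"LabelEnrichment: {spec.label_enrichment!r}\n"
        f"HighRes: {high_res}\n"
    )


def format_result(result: CorrectionResult) -> str:
    """Console report: name, corrected MID to 6 decimals, SSE, warnings."""
    lines = [f"Fragment: {result.name}" if result.name else "Fragment:"]
    lines.append(
        "MIDc: " + " ".join(f"{v:.6f}" for v in result.corrected_mid)
    )
    lines.append(f"SSE: {result.sse:.6e}")
    for message in result.warnings:
        lines.append(f"Warning: {message}")
    return "\n".join(lines) + "\n"


def run_correction(spec_or_path, table: AbundanceTable | None = None) -> CorrectionResult:
    """Correct a fragment given a FragmentSpec or an input-file path.

    Logs the corrected MID and SSE and returns the full result object, so
    pipelines can consume ``result.mid_c`` and ``result.sse`` directly. The
    file and programmatic routes give identical results on identical values.
    """
    if isinstance(spec_or_path, FragmentSpec):
        spec = spec_or_path
    else:
        spec = parse_input_file(spec_or_path, table=table)
    result = correct(spec, table=table)
    logger.info(
        "%s: MIDc = %s, SSE = %.6e",
        spec.name,
        np.array2string(result.corrected_mid, precision=6),
        result.sse,
    )
    return result


def write_result(result: CorrectionResult, destination, format: str = "text") -> None:
    """Write a correction result as a text report or CSV.

    CSV has one row per tracer-label count with columns ``label_count``,
    ``corrected_fraction`` and ``warning`` (set to ``negative`` on rows whose
    corrected component is below zero); file-level warnings appear as ``#``
    comment lines before the header.
    """
    destination = Path(destination)
    if format == "text":
        destination.write_text(format_result(result))
    elif format == "csv":
        with destination.open("w", newline="") as fh:
            for message in result.warnings:
                fh.write(f"# {message}\n")
            writer = csv.writer(fh)
            writer.writerow(["label_count", "corrected_fraction", "warning"])
            for k, value in enumerate(result.corrected_mid):
                writer.writerow(
                    [k, repr(float(value)), "negative" if value < 0 else ""]
                )
    else:
        raise ValueError(f"unknown output format {format!r} (use text or csv)")
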