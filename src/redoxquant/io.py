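"""Readers and writers for PSM tables, results tables, and the packaged
47-peptide reference fold-change table.

The PSM table dialect is plain TSV with a documented header (see
:data:`PSM_COLUMNS`), emulating a reporter-intensity export from a search
engine.  No vendor binary formats are parsed.
"""

from __future__ import annotations

import csv
import importlib.resources
from typing import Iterable, TextIO, Union

import pandas as pd

from .design import ChannelDesign, IODO_LABELS, ITRAQ_LABELS
from .peptides import PeptideParseError, parse_modified_sequence
from .psm import PSMRecord, PSMSet

PSM_COLUMNS = (
    ["peptide", "accessions", "replicate", "fraction"]
    + [f"iodo_{label}" for label in IODO_LABELS]
    + [f"itraq_{label}" for label in ITRAQ_LABELS]
)


class TableFormatError(ValueError):
    """A PSM table is missing mandatory columns or contains malformed rows."""


def read_psm_table(source: Union[str, TextIO], design: ChannelDesign) -> PSMSet:
    """Read a TSV of PSM reporter intensities into a :class:`PSMSet`.

    Empty and zero intensity cells are both stored as missing.  Malformed rows
    raise :class:`TableFormatError` naming the offending line.
    """
    if isinstance(source, str):
        with open(source, newline="") as fh:
            return read_psm_table(fh, design)

    reader = csv.DictReader(source, delimiter="\t")
    header = reader.fieldnames or []
    missing = [col for col in PSM_COLUMNS if col != "fraction" and col not in header]
    if missing:
        raise TableFormatError(f"PSM table missing mandatory columns: {missing}")
    known = set(PSM_COLUMNS)
    unknown = [
        col
        for col in header
        if col.startswith(("iodo_", "itraq_")) and col not in known
    ]
    if unknown:
        raise TableFormatError(
            f"reporter columns {unknown} do not match the channel design"
        )

    records = []
    for lineno, row in enumerate(reader, start=2):
        try:
            peptide = parse_modified_sequence(
                row["peptide"],
                [a for a in row["accessions"].split(";") if a],
            )
            iodo = _parse_intensities(row, "iodo_", IODO_LABELS)
            itraq = _parse_intensities(row, "itraq_", ITRAQ_LABELS)
            records.append(
                PSMRecord(
                    peptide=peptide,
                    replicate=row["replicate"],
                    fraction=row.get("fraction") or None,
                    iodo_intensities=iodo,
                    itraq_intensities=itraq,
                )
            )
        except (PeptideParseError, ValueError, KeyError) as exc:
            raise TableFormatError(f"line {lineno}: {exc}") from exc
    try:
        return PSMSet(records=tuple(records), design=design)
    except ValueError as exc:
        raise TableFormatError(str(exc)) from exc


def _parse_intensities(
    row: dict, prefix: str, labels: Iterable[str]
) -> dict[str, float]:
    out = {}
    for label in labels:
        cell = row.get(prefix + label, "")
        if cell is None or cell.strip() == "":
            continue
        value = float(cell)
        if value == 0:
            continue  # measured zeros are unobservable; treat as missing
        out[label] = value
    return out


def write_psm_table(psmset: PSMSet, target: Union[str, TextIO]) -> None:
    """Write a :class:`PSMSet` in the TSV dialect read by :func:`read_psm_table`.

    Floats are written with ``repr`` precision so that write/read round-trips
    reproduce every intensity exactly.
    """
    if isinstance(target, str):
        with open(target, "w", newline="") as fh:
            write_psm_table(psmset, fh)
            return
    writer = csv.writer(target, delimiter="\t", lineterminator="\n")
    writer.writerow(PSM_COLUMNS)
    frame = psmset.to_frame()
    for _, row in frame.iterrows():
        out = []
        for col in PSM_COLUMNS:
            value = row[col]
            if col.startswith(("iodo_", "itraq_")):
                out.append("" if pd.isna(value) else repr(float(value)))
            else:
                out.append(str(value))
        writer.writerow(out)


RESULTS_COLUMNS = (
    ["peptide", "accession", "cys_positions"]
    + [f"iodo_fc_{tp}" for tp in (5, 30, 120)]
    + [f"iodo_p_{tp}" for tp in (5, 30, 120)]
    + [f"itraq_fc_{tp}" for tp in (5, 30, 120)]
    + [f"itraq_p_{tp}" for tp in (5, 30, 120)]
    + ["label", "flags"]
)


def write_results_table(calls, target: Union[str, TextIO]) -> None:
    """Write per-peptide redox calls as TSV, one row per peptide.

    Fold changes are rounded to two decimals, matching the conventional
    presentation of published fold-change tables; p-values keep four
    significant digits.
    """
    if isinstance(target, str):
        with open(target, "w", newline="") as fh:
            write_results_table(calls, fh)
            return
    if not calls:
        raise ValueError("no redox calls to write")
    writer = csv.writer(target, delimiter="\t", lineterminator="\n")
    writer.writerow(RESULTS_COLUMNS)
    for call in calls:
        row = [
            call.peptide,
            call.accession,
            ";".join(str(p) for p in call.cys_positions),
        ]
        for results in (call.iodo_results, call.itraq_results):
            row += [_fmt_fc(results.get(tp)) for tp in (5, 30, 120)]
            row += [_fmt_p(results.get(tp)) for tp in (5, 30, 120)]
        row.append(call.label)
        row.append(";".join(sorted(call.flags)))
        writer.writerow(row)


def _fmt_fc(result) -> str:
    if result is None or result.mean_fc is None:
        return ""
    return f"{result.mean_fc:.2f}"


def _fmt_p(result) -> str:
    if result is None or result.p_value is None:
        return ""
    return f"{result.p_value:.4g}"


def load_table1_fixture() -> pd.DataFrame:
    """The packaged table of 47 significant redox-regulated peptides.

    Columns: annotated peptide, protein accession, description, iodoTMT fold
    changes at 5/30/120 min, iTRAQ fold changes at 5/30/120 min, and whether
    an intramolecular disulfide was predicted for the site.  Two peptide
    strings appear twice with slightly different fold changes; both rows are
    kept verbatim as published.
    """
    resource = importlib.resources.files("redoxquant.data").joinpath("table1.tsv")
    with resource.open("r") as fh:
        return pd.read_csv(fh, sep="\t")
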