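"""Readers and writers for the long-format CSV dialect.

Two files describe a study: ``frequencies.csv`` with columns
``participant_id, symptom_id, frequency`` and ``pcr.csv`` with columns
``participant_id, cause_id, effect_id, pcr``.  UTF-8, header row required.
Missing *by intention* is an empty cell; missing *by design* is never written
(it is recomputed from the frequencies on load).  A present PCR value for an
ineligible pair signals corrupted input and is rejected.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import SymptomCatalog
from .records import (
    Missing,
    ParticipantRecord,
    PCRDataError,
    _check_frequency,
    _check_pcr,
)

FREQUENCY_COLUMNS = ["participant_id", "symptom_id", "frequency"]
PCR_COLUMNS = ["participant_id", "cause_id", "effect_id", "pcr"]


def _open_reader(path: str | Path, required: Sequence[str]) -> tuple[csv.DictReader, object]:
    handle = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(required):
        handle.close()
        raise PCRDataError(
            f"{path}: expected header {','.join(required)}, "
            f"got {reader.fieldnames}"
        )
    return reader, handle


def _parse_int(text: str, what: str, path: str | Path, row_number: int) -> int:
    try:
        return int(text.strip())
    except (ValueError, AttributeError):
        raise PCRDataError(
            f"{path}, row {row_number}: malformed {what} {text!r}"
        ) from None


def load_frequency_table(
    path: str | Path, catalog: SymptomCatalog
) -> list[ParticipantRecord]:
    """Read frequencies.csv into per-participant records (frequencies only).

    Items with no row, and rows with an empty frequency cell, are missing by
    intention.  Participants keep first-appearance order; errors name the
    offending row (header = row 1).
    """
    valid_ids = set(catalog.ids)
    reader, handle = _open_reader(path, FREQUENCY_COLUMNS)
    records: dict[str, ParticipantRecord] = {}
    seen: set[tuple[str, int]] = set()
    try:
        for row_number, row in enumerate(reader, start=2):
            pid = (row["participant_id"] or "").strip()
            if not pid:
                raise PCRDataError(f"{path}, row {row_number}: empty participant_id")
            sid = _parse_int(row["symptom_id"], "symptom_id", path, row_number)
            if sid not in valid_ids:
                raise PCRDataError(
                    f"{path}, row {row_number}: unknown symptom id {sid}"
                )
            if (pid, sid) in seen:
                raise PCRDataError(
                    f"{path}, row {row_number}: duplicate entry for "
                    f"participant {pid!r}, symptom {sid}"
                )
            seen.add((pid, sid))
            cell = (row["frequency"] or "").strip()
            if pid not in records:
                records[pid] = ParticipantRecord(
                    participant_id=pid,
                    frequencies={i: Missing.BY_INTENTION for i in catalog.ids},
                )
            if cell:
                value = _parse_int(cell, "frequency", path, row_number)
                try:
                    records[pid].frequencies[sid] = _check_frequency(value)
                except PCRDataError as err:
                    raise PCRDataError(f"{path}, row {row_number}: {err}") from None
    finally:
        handle.close()
    return list(records.values())


def load_pcr_table(
    path: str | Path,
    records: Iterable[ParticipantRecord],
    catalog: SymptomCatalog,
) -> list[ParticipantRecord]:
    """Attach pcr.csv ratings to frequency records and validate.

    Eligible pairs absent from the file become missing by intention; a present
    value for an ineligible pair raises (corrupted input).  Returns the same
    records, now satisfying every record invariant.
    """
    records = list(records)
    by_id = {r.participant_id: r for r in records}
    eligible = {r.participant_id: set(r.eligible_pairs()) for r in records}
    reader, handle = _open_reader(path, PCR_COLUMNS)
    try:
        for row_number, row in enumerate(reader, start=2):
            pid = (row["participant_id"] or "").strip()
            if pid not in by_id:
                raise PCRDataError(
                    f"{path}, row {row_number}: unknown participant {pid!r}"
                )
            cause = _parse_int(row["cause_id"], "cause_id", path, row_number)
            effect = _parse_int(row["effect_id"], "effect_id", path, row_number)
            cell = (row["pcr"] or "").strip()
            pair = (cause, effect)
            if pair not in eligible[pid]:
                if cell:
                    raise PCRDataError(
                        f"{path}, row {row_number}: PCR value for ineligible "
                        f"pair {pair} of participant {pid!r} (an endpoint has "
                        f"frequency 0 or missing) — corrupted input"
                    )
                continue  # blank rating for an ineligible pair carries no information
            record = by_id[pid]
            if pair in record.pcr:
                raise PCRDataError(
                    f"{path}, row {row_number}: duplicate PCR entry for "
                    f"participant {pid!r}, pair {pair}"
                )
            if cell:
                value = _parse_int(cell, "pcr", path, row_number)
                try:
                    record.pcr[pair] = _check_pcr(value)
                except PCRDataError as err:
                    raise PCRDataError(f"{path}, row {row_number}: {err}") from None
            else:
                record.pcr[pair] = Missing.BY_INTENTION
    finally:
        handle.close()
    for record in records:
        for pair in eligible[record.participant_id]:
            record.pcr.setdefault(pair, Missing.BY_INTENTION)
        record.validate(catalog)
    return records


def write_frequency_table(
    records: Iterable[ParticipantRecord], path: str | Path
) -> None:
    """Write frequencies.csv; by-intention cells are left blank."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(FREQUENCY_COLUMNS)
        for record in records:
            for sid in sorted(record.frequencies):
                value = record.frequencies[sid]
                writer.writerow(
                    [record.participant_id, sid, value if isinstance(value, int) else ""]
                )


def write_pcr_table(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    """Write pcr.csv: one row per eligible pair; by-design slots are omitted."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(PCR_COLUMNS)
        for record in records:
            for (cause, effect) in sorted(record.pcr):
                value = record.pcr[(cause, effect)]
                writer.writerow(
                    [
                        record.participant_id,
                        cause,
                        effect,
                        value if isinstance(value, int) else "",
                    ]
                )


def load_study(
    frequencies_path: str | Path,
    pcr_path: str | Path,
    catalog: SymptomCatalog,
) -> list[ParticipantRecord]:
    """Load and validate a full study from its two CSV files."""
    records = load_frequency_table(frequencies_path, catalog)
    return load_pcr_table(pcr_path, records, catalog)
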