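"""Readers and writers for the formats the pipeline touches.

Measurement tables are delimited text (comma or tab) with mandatory
columns ``specimen_id, site_id, FWL, HWL, TL, FL`` — forewing, hindwing,
tibia and femur lengths, all in millimeters.  Sequences travel as plain
FASTA.  Barcode-repository exports are tab-separated records carrying an
id, a COI sequence, and coordinates, with configurable column names.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .types import (
    Call,
    DomainError,
    FormatError,
    MorphMeasurements,
    SiteSummary,
    Source,
    Specimen,
)

MEASUREMENT_COLUMNS = ("specimen_id", "site_id", "FWL", "HWL", "TL", "FL")

#: IUPAC nucleotide one-letter codes (plus gap) accepted on FASTA input.
_IUPAC_NT = set("ACGTURYSWKMBDHVN-")


def _sniff_delimiter(header_line: str, path: Path) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    raise FormatError(
        f"{path}: cannot find a comma or tab delimiter in the header; "
        "pass delimiter explicitly"
    )


def read_measurements(
    table_path: str | Path,
    delimiter: Optional[str] = None,
    skip_bad: bool = False,
) -> list[Specimen]:
    """Read a worker-measurement table into Specimen records.

    One Specimen per data row, in file order, with ``morph`` populated
    from the four length columns (mm).  Columns beyond the mandatory six
    are preserved in ``Specimen.metadata``.  A header-only file yields an
    empty list.  A missing mandatory column raises :class:`FormatError`
    naming it; a non-numeric measurement raises a row-numbered
    :class:`FormatError` unless ``skip_bad`` is set, in which case the
    row is reported via a warning and excluded.
    """
    table_path = Path(table_path)
    with open(table_path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{table_path}: empty file (no header)")
        delim = delimiter or _sniff_delimiter(first, table_path)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in MEASUREMENT_COLUMNS:
            if col not in header:
                raise FormatError(
                    f"{table_path}: missing mandatory column {col!r} "
                    f"(found {header})"
                )
        extra_cols = [c for c in header if c not in MEASUREMENT_COLUMNS]

        specimens: list[Specimen] = []
        for row_no, row in enumerate(reader, start=2):
            try:
                values = {}
                for col in ("FWL", "HWL", "TL", "FL"):
                    raw = (row[col] or "").strip()
                    try:
                        values[col] = float(raw)
                    except ValueError:
                        raise FormatError(
                            f"{table_path}, row {row_no}: non-numeric "
                            f"{col} value {raw!r}"
                        ) from None
                    if not math.isfinite(values[col]):
                        raise FormatError(
                            f"{table_path}, row {row_no}: non-finite {col}"
                        )
                morph = MorphMeasurements(
                    forewing_mm=values["FWL"],
                    hindwing_mm=values["HWL"],
                    femur_mm=values["FL"],
                    tibia_mm=values["TL"],
                )
            except (FormatError, DomainError) as exc:
                if skip_bad:
                    warnings.warn(f"skipping bad row: {exc}", stacklevel=2)
                    continue
                raise
            specimens.append(
                Specimen(
                    specimen_id=row["specimen_id"],
                    site_id=row["site_id"],
                    morph=morph,
                    metadata={c: row[c] for c in extra_cols},
                )
            )
    ids = [s.specimen_id for s in specimens]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{table_path}: duplicate specimen_id values {dupes}")
    return specimens


def write_measurements(
    specimens: Iterable[Specimen], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write Specimens with morphometrics back out (round-trips read_measurements)."""
    path = Path(path)
    specimens = list(specimens)
    extra = sorted({k for s in specimens for k in s.metadata})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([*MEASUREMENT_COLUMNS, *extra])
        for s in specimens:
            if s.morph is None:
                raise DomainError(f"specimen {s.specimen_id} has no measurements")
            writer.writerow(
                [
                    s.specimen_id,
                    s.site_id,
                    repr(s.morph.forewing_mm),
                    repr(s.morph.hindwing_mm),
                    repr(s.morph.tibia_mm),
                    repr(s.morph.femur_mm),
                    *(s.metadata.get(k, "") for k in extra),
                ]
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercased sequence) pairs, in file order.

    IDs are the first whitespace-delimited token of each header.  A
    sequence containing characters outside the IUPAC nucleotide alphabet
    raises :class:`FormatError` naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise FormatError(
                f"record {rec.id!r}: non-IUPAC nucleotide characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True)
class BoldColumns:
    """Column-name mapping for barcode-repository TSV exports."""

    record_id: str = "processid"
    sequence: str = "nucleotides"
    latitude: str = "lat"
    longitude: str = "lon"


def read_bold_tsv(
    path: str | Path, columns: BoldColumns = BoldColumns()
) -> list[Specimen]:
    """Read a barcode-repository TSV into reference Specimens.

    COI sequences are stored under marker name ``"COI"``.  Records
    lacking a sequence or coordinates are flagged (``no-sequence``,
    ``no-coordinates``), never silently dropped.  Unmappable columns
    raise :class:`FormatError` listing the headers that are present.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        wanted = {
            "record_id": columns.record_id,
            "sequence": columns.sequence,
            "latitude": columns.latitude,
            "longitude": columns.longitude,
        }
        missing = [name for name in wanted.values() if name not in header]
        if missing:
            raise FormatError(
                f"{path}: cannot map columns {missing}; available headers: {header}"
            )
        specimens = []
        for row in reader:
            seq = (row[columns.sequence] or "").strip().upper().replace("-", "")
            flags = []
            lat = lon = None
            try:
                lat = float(row[columns.latitude])
                lon = float(row[columns.longitude])
            except (TypeError, ValueError):
                flags.append("no-coordinates")
            if not seq:
                flags.append("no-sequence")
            sp = Specimen(
                specimen_id=row[columns.record_id],
                site_id="",
                source=Source.REFERENCE,
                latitude=lat,
                longitude=lon,
                sequences={"COI": seq} if seq else {},
                flags=flags,
            )
            specimens.append(sp)
    return specimens


def summarize_sites(specimens: Sequence[Specimen]) -> list[SiteSummary]:
    """Tally African-mitotype bees per site from RFLP / COI-SNP calls.

    Every specimen must carry a confident mitotype call; sites are
    returned in first-appearance order.  The 0..k category histogram of
    African counts per site is derivable via :func:`site_category_histogram`.
    """
    per_site: dict[str, list[Call]] = {}
    for sp in specimens:
        call = sp.mitotype_call()
        if call is None:
            raise DomainError(
                f"specimen {sp.specimen_id} has no confident mitotype call"
            )
        per_site.setdefault(sp.site_id, []).append(call.mitotype)
    return [
        SiteSummary(
            site_id=site,
            n_bees=len(calls),
            n_african_mito=sum(c is Call.AFRICAN for c in calls),
        )
        for site, calls in per_site.items()
    ]


def site_category_histogram(
    summaries: Iterable[SiteSummary], bees_per_site: int = 3
) -> list[int]:
    """Counts of sites with 0, 1, ..., k African bees among k sampled.

    Sites with a different number of sampled bees raise
    :class:`DomainError` (the histogram is only defined at fixed k).
    """
    hist = [0] * (bees_per_site + 1)
    for s in summaries:
        if s.n_bees != bees_per_site:
            raise DomainError(
                f"site {s.site_id} has {s.n_bees} bees, expected {bees_per_site}"
            )
        hist[s.n_african_mito] += 1
    return hist
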