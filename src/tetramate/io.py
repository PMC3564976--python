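"""File-format adapters.

Dialects used throughout the package:

* marker FASTA — header ``>strainID|locus|source[|cloneID]`` with
  configurable separator;
* genotype TSV — columns ``strain, ploidy, mat_a, mat_b, flags,
  country, locality``; allele lists semicolon-separated, blank cells
  are explicit missing data; flags are re-derived on read;
* crossing CSV — first row and column hold ids, cells in
  ``{+, -, ?, blank}``; blank means the cross was not performed;
  upper-triangle-only input is accepted, symmetry is validated when
  both triangles are present.

All writers go through a temp-file-then-rename step so a failed run
never leaves a partial file.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mating_model import CrossingMatrix
from .types import (
    CrossOutcome,
    FunctionalProxyPair,
    Locus,
    MarkerSequence,
    MatingGenotype,
    Ploidy,
    PopulationTable,
    Source,
)

_SYMBOL_TO_OUTCOME = {
    "+": CrossOutcome.compatible,
    "-": CrossOutcome.incompatible,
    "?": CrossOutcome.unresolved,
}
_OUTCOME_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_OUTCOME.items()}


class FormatError(ValueError):
    """Malformed input file; message carries the location."""


def _atomic_write(path: str | Path, write_fn) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as handle:
            write_fn(handle)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- marker FASTA ----------------------------------------------------------


def read_marker_fasta(path: str | Path, sep: str = "|") -> list[MarkerSequence]:
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        fields = rec.id.split(sep)
        if len(fields) not in (3, 4):
            raise FormatError(
                f"{path}: record {i + 1} ({rec.id!r}): expected "
                f"strainID{sep}locus{sep}source[{sep}cloneID]"
            )
        strain, locus_s, source_s = fields[:3]
        try:
            locus = Locus(locus_s)
            source = Source(source_s)
        except ValueError as exc:
            raise FormatError(f"{path}: record {i + 1}: {exc}") from exc
        clone_id = fields[3] if len(fields) == 4 else None
        records.append(
            MarkerSequence(strain, locus, str(rec.seq).upper(), source, clone_id)
        )
    return records


def write_marker_fasta(
    path: str | Path, seqs: Iterable[MarkerSequence], sep: str = "|"
) -> None:
    records = []
    for s in seqs:
        parts = [s.strain_id, s.locus.value, s.source.value]
        if s.clone_id is not None:
            parts.append(s.clone_id)
        records.append(
            SeqRecord(Seq(s.sequence), id=sep.join(parts), description="")
        )

    def _write(handle):
        SeqIO.write(records, handle, "fasta")

    _atomic_write(path, _write)


# -- genotype TSV ----------------------------------------------------------

GENOTYPE_COLUMNS = ["strain", "ploidy", "mat_a", "mat_b", "flags", "country", "locality"]


def _parse_alleles(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(a.strip() for a in cell.split(";") if a.strip())


def read_genotype_tsv(path: str | Path) -> PopulationTable:
    entries = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(GENOTYPE_COLUMNS[:4]) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ploidy = Ploidy(row["ploidy"].strip())
                entries.append(
                    MatingGenotype.make(
                        row["strain"].strip(),
                        ploidy,
                        _parse_alleles(row["mat_a"]),
                        _parse_alleles(row["mat_b"]),
                        country=(row.get("country") or "").strip() or None,
                        locality=(row.get("locality") or "").strip() or None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return PopulationTable(entries)


def write_genotype_tsv(path: str | Path, table: PopulationTable) -> None:
    def _write(handle):
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(GENOTYPE_COLUMNS)
        for e in table:
            writer.writerow(
                [
                    e.strain_id,
                    e.ploidy.value,
                    ";".join(sorted(e.a_alleles)),
                    ";".join(sorted(e.b_alleles)),
                    ";".join(sorted(f.value for f in e.flags)),
                    e.country or "",
                    e.locality or "",
                ]
            )

    _atomic_write(path, _write)


# -- functional/proxy table ------------------------------------------------


def read_functional_proxy_tsv(path: str | Path) -> list[FunctionalProxyPair]:
    pairs = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"strain", "functional_a", "functional_b", "proxy_a", "proxy_b"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            pairs.append(
                FunctionalProxyPair(
                    strain_id=row["strain"].strip(),
                    functional_a=row["functional_a"].strip(),
                    functional_b=row["functional_b"].strip(),
                    proxy_a=row["proxy_a"].strip(),
                    proxy_b=row["proxy_b"].strip(),
                )
            )
    return pairs


# -- crossing CSV ----------------------------------------------------------


def read_crossing_csv(path: str | Path) -> CrossingMatrix:
    with open(path, newline="") as handle:
        rows = list(csv.reader(handle))
    if not rows:
        raise FormatError(f"{path}: empty file")
    ids = [c.strip() for c in rows[0][1:] if c.strip()]
    matrix = CrossingMatrix(ids=ids)
    seen: dict[tuple[str, str], tuple[int, CrossOutcome]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or not row[0].strip():
            continue
        row_id = row[0].strip()
        if row_id not in ids:
            raise FormatError(f"{path}: line {lineno}: unknown row id {row_id!r}")
        for col, cell in enumerate(row[1:]):
            cell = cell.strip()
            if not cell:
                continue
            if col >= len(ids):
                raise FormatError(f"{path}: line {lineno}: too many cells")
            col_id = ids[col]
            if cell not in _SYMBOL_TO_OUTCOME:
                raise FormatError(
                    f"{path}: line {lineno}: invalid symbol {cell!r} "
                    f"(column {col_id})"
                )
            outcome = _SYMBOL_TO_OUTCOME[cell]
            key = tuple(sorted((row_id, col_id)))
            if key in seen and row_id != col_id:
                prev_line, prev = seen[key]
                if prev is not outcome:
                    raise FormatError(
                        f"{path}: line {lineno}: asymmetric outcome for "
                        f"({key[0]}, {key[1]}) vs line {prev_line}"
                    )
                continue
            seen[key] = (lineno, outcome)
            matrix.set(row_id, col_id, outcome)
    return matrix


def write_crossing_csv(path: str | Path, matrix: CrossingMatrix) -> None:
    def _write(handle):
        writer = csv.writer(handle)
        writer.writerow([""] + matrix.ids)
        for row_id in matrix.ids:
            cells = []
            for col_id in matrix.ids:
                outcome = matrix.get(row_id, col_id)
                cells.append("" if outcome is None else _OUTCOME_TO_SYMBOL[outcome])
            writer.writerow([row_id] + cells)

    _atomic_write(path, _write)


# -- assignment table / candidates / reports -------------------------------


def write_assignment_tsv(
    path: str | Path, seqs: list[MarkerSequence], assignment: dict[int, str]
) -> None:
    """Sequence-to-allele assignment table from the clustering step."""

    def _write(handle):
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["strain", "locus", "source", "clone_id", "allele"])
        for idx, s in enumerate(seqs):
            writer.writerow(
                [s.strain_id, s.locus.value, s.source.value, s.clone_id or "",
                 assignment[idx]]
            )

    _atomic_write(path, _write)


def write_candidates_tsv(path: str | Path, candidates) -> None:
    def _write(handle):
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            ["source", "strand", "start", "end", "length_aa", "caax", "notes"]
        )
        for c in candidates:
            writer.writerow(
                [
                    c.source_id,
                    c.strand or ".",
                    "" if c.start is None else c.start,
                    "" if c.end is None else c.end,
                    c.length_aa,
                    c.caax,
                    ";".join(c.score_notes),
                ]
            )

    _atomic_write(path, _write)


def write_candidates_gff3(path: str | Path, candidates) -> None:
    """Candidates with DNA coordinates as GFF3 (1-based inclusive)."""

    def _write(handle):
        handle.write("##gff-version 3\n")
        for i, c in enumerate(candidates, start=1):
            if c.start is None:
                continue
            handle.write(
                "\t".join(
                    [
                        c.source_id,
                        "tetramate",
                        "pheromone_precursor_candidate",
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        c.strand,
                        "0",
                        f"ID=phcand{i};caax={c.caax};length_aa={c.length_aa}",
                    ]
                )
                + "\n"
            )

    _atomic_write(path, _write)


def write_json_report(path: str | Path, report: dict) -> None:
    def _write(handle):
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")

    _atomic_write(path, _write)
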