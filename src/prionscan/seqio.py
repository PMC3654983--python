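"""Reading protein sequences and writing prediction files.

Readers return :class:`SequenceRecord` collections from FASTA or
UniProt/Swiss-Prot flat files (plain or gzip-compressed).  Writers emit
predictions either as a tab-separated table or in the compact per-taxon
dialect used for genome-wide prion surveys: one organism line
``>Organism: count`` followed by one line per prediction,
``id<TAB>start;score|domain-sequence``.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio import SwissProt as _BioSwissProt

from .alphabet import ALPHABET, encode

logger = logging.getLogger(__name__)

_GAP_CHARS = "-.*"
_GAP_RE = re.compile(r"[-.*]")


@dataclass
class SequenceRecord:
    """One protein sequence.

    ``residues`` is an uppercase string over the 20 standard amino acids plus
    the ambiguity letters B, J, O, U, X, Z.  ``organism`` may be empty for
    FASTA input.
    """

    id: str
    residues: str
    description: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.residues = self.residues.upper()
        encode(self.residues)  # raises naming the offending position

    def __len__(self) -> int:
        return len(self.residues)


def _open_maybe_gzip(source, mode: str = "rt") -> tuple[IO[str], bool]:
    """Return a text handle for a path or stream; gzip is detected by suffix."""
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode), True
    return open(path, mode), True


def read_fasta(source) -> list[SequenceRecord]:
    """Parse FASTA into normalized records.

    Lowercase residues are raised to uppercase and gap characters (``-``,
    ``.``, ``*``) stripped with a warning.  An entry left with no residues is
    an error naming its header; an empty file yields an empty list with a
    warning.  Duplicate ids are kept but later copies are suffixed ``.2``,
    ``.3``, ... for uniqueness in downstream outputs.
    """
    handle, owned = _open_maybe_gzip(source)
    try:
        records: list[SequenceRecord] = []
        seen: dict[str, int] = {}
        for entry in _BioSeqIO.parse(handle, "fasta"):
            raw = str(entry.seq).upper()
            clean = _GAP_RE.sub("", raw)
            if len(clean) != len(raw):
                logger.warning(
                    "record %s: stripped %d gap character(s)",
                    entry.id, len(raw) - len(clean),
                )
            if not clean:
                raise ValueError(f"FASTA entry {entry.description!r} has no residues")
            rec_id = entry.id
            if rec_id in seen:
                seen[rec_id] += 1
                new_id = f"{rec_id}.{seen[rec_id]}"
                logger.warning("duplicate id %s renamed to %s", rec_id, new_id)
                rec_id = new_id
            else:
                seen[rec_id] = 1
            records.append(
                SequenceRecord(
                    id=rec_id, residues=clean, description=entry.description
                )
            )
        if not records:
            logger.warning("no FASTA records found in input")
        return records
    finally:
        if owned:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], dest, width: int = 60) -> None:
    handle, owned = _open_maybe_gzip(dest, "wt")
    try:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = rec.id
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
    finally:
        if owned:
            handle.close()


def read_uniprot_flatfile(source) -> list[SequenceRecord]:
    """Parse UniProt/Swiss-Prot flat-file entries (ID/OS/SQ blocks).

    The record id is the first token of the ID line, the organism is the
    concatenated OS lines with the trailing period stripped, and the sequence
    comes from the SQ block with whitespace removed.  Entries without
    sequence are skipped with a warning; a truncated final entry (missing the
    ``//`` terminator) is an error.
    """
    handle, owned = _open_maybe_gzip(source)
    try:
        records: list[SequenceRecord] = []
        try:
            for entry in _BioSwissProt.parse(handle):
                organism = entry.organism.strip().rstrip(".")
                seq = entry.sequence.upper().replace(" ", "")
                if not seq:
                    logger.warning(
                        "entry %s has no sequence block; skipped", entry.entry_name
                    )
                    continue
                records.append(
                    SequenceRecord(
                        id=entry.entry_name,
                        residues=seq,
                        description=" ".join(entry.description.split()),
                        organism=organism,
                    )
                )
        except ValueError as exc:
            raise ValueError(
                f"truncated or malformed flat-file entry: {exc}"
            ) from exc
        return records
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# prediction writers


def _groups_by_organism(predictions, fallback: str) -> dict[str, list]:
    groups: dict[str, list] = {}
    for pred in predictions:
        org = getattr(pred, "organism", "") or fallback
        groups.setdefault(org, []).append(pred)
    return groups


def write_predictions_paper_format(
    predictions: Sequence,
    stream: IO[str],
    decimals: int = 2,
    fallback_organism: str = "unknown",
) -> None:
    """Write predictions in the per-taxon survey dialect.

    For each organism (first-appearance order) an organism line
    ``>name: count`` is written, then one line per prediction:
    ``protein_id<TAB>start;score|window_sequence`` with the score printed to
    ``decimals`` decimal places.  Predictions lacking an organism go to the
    ``fallback_organism`` group.
    """
    for org, preds in _groups_by_organism(predictions, fallback_organism).items():
        stream.write(f">{org}: {len(preds)}\n")
        for p in preds:
            stream.write(
                f"{p.protein_id}\t{p.start};"
                f"{p.score_bits:.{decimals}f}|{p.window_sequence}\n"
            )


@dataclass
class PaperFormatEntry:
    """One prediction parsed back from the per-taxon dialect."""

    organism: str
    protein_id: str
    start: int
    score_bits: float
    window_sequence: str


def read_predictions_paper_format(stream: IO[str]) -> list[PaperFormatEntry]:
    """Parse the per-taxon prediction dialect (round-trip of the writer)."""
    entries: list[PaperFormatEntry] = []
    organism = ""
    declared: dict[str, int] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            name, _, count = line[1:].rpartition(": ")
            organism = name
            declared[name] = int(count)
            continue
        pid, _, rest = line.partition("\t")
        pos, _, rest = rest.partition(";")
        score, _, seq = rest.partition("|")
        entries.append(
            PaperFormatEntry(organism, pid, int(pos), float(score), seq)
        )
    for org, count in declared.items():
        found = sum(1 for e in entries if e.organism == org)
        if found != count:
            raise ValueError(
                f"organism {org!r} declares {count} predictions, found {found}"
            )
    return entries


_TSV_COLUMNS = [
    "organism",
    "protein_id",
    "start",
    "end",
    "score_bits",
    "compositional_bits",
    "proline_correction_bits",
    "window_sequence",
]


def write_predictions_tsv(predictions: Sequence, stream: IO[str]) -> None:
    """Write predictions as a TSV table with 1-based inclusive coordinates."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for p in predictions:
        writer.writerow(
            [
                getattr(p, "organism", ""),
                p.protein_id,
                p.start,
                p.start + len(p.window_sequence) - 1,
                repr(p.score_bits),
                repr(p.compositional_bits),
                repr(p.proline_bits),
                p.window_sequence,
            ]
        )
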