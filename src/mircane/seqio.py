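"""FASTA input/output and elementary sequence arithmetic.

All sequences are normalised to the RNA alphabet ``{A, C, G, U, N}`` on
load; the original T/U convention of the source file is remembered in
:attr:`SequenceRecord.source_alphabet` so records can be written back in
their native alphabet.  Internal coordinates throughout the package are
0-based half-open; report output uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, TextIO, Union

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGUN")

#: IUPAC ambiguity codes that are accepted on input and collapsed to N.
_AMBIGUITY = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

_WRAP = 60  # fixed FASTA line width for reproducible output


class FastaError(ValueError):
    """Raised for malformed FASTA input (empty, duplicate ids, bad residues)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence normalised to the RNA alphabet.

    Parameters
    ----------
    id
        First whitespace-delimited token of the FASTA header.
    residues
        Upper-case RNA residues over ``{A, C, G, U, N}``.
    description
        Remainder of the header line (may be empty).
    source_alphabet
        ``"DNA"`` if the source sequence contained T, else ``"RNA"``.
    """

    id: str
    residues: str
    description: str = ""
    source_alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        if not self.residues:
            raise FastaError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise FastaError(
                f"sequence {self.id!r}: invalid residue {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, record_id: str = "?") -> tuple[str, str]:
    """Return ``(rna_residues, source_alphabet)`` for a raw sequence string.

    T is rewritten to U (and the record flagged as DNA); IUPAC ambiguity
    codes are collapsed to N; anything outside the IUPAC nucleotide codes
    raises :class:`FastaError` with the 1-based offending position.
    """
    up = raw.upper()
    out = []
    alphabet = "RNA"
    for i, c in enumerate(up):
        if c in "ACGUN":
            out.append(c)
        elif c == "T":
            out.append("U")
            alphabet = "DNA"
        elif c in _AMBIGUITY:
            out.append("N")
        else:
            raise FastaError(
                f"sequence {record_id!r}: character {c!r} at position {i + 1} "
                "is not an IUPAC nucleotide"
            )
    return "".join(out), alphabet


def read_fasta(path: Union[str, Path, TextIO]) -> List[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Multi-line sequences and CRLF line endings are tolerated.  Every record
    is normalised to RNA.  Raises :class:`FastaError` on an empty file, a
    duplicate id, or residues outside the IUPAC nucleotide codes.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = []
        seen = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            residues, alphabet = normalize_residues(str(rec.seq), rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(
                SequenceRecord(rec.id, residues, desc, alphabet)
            )
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not records:
        raise FastaError(f"no records in FASTA input {path!r}")
    return records


def write_fasta(records: Iterable[SequenceRecord],
                path: Union[str, Path, TextIO]) -> None:
    """Write records as FASTA, wrapping at 60 columns.

    Records whose ``source_alphabet`` is DNA are written back with T.
    """
    handle = open(path, "w") if isinstance(path, (str, Path)) else path
    try:
        for rec in records:
            seq = rec.residues
            if rec.source_alphabet == "DNA":
                seq = seq.replace("U", "T")
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(seq), _WRAP):
                handle.write(seq[i:i + _WRAP] + "\n")
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def fasta_string(records: Iterable[SequenceRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


def gc_percent(seq: Union[SequenceRecord, str]) -> float:
    """G+C content as a percentage of sequence length.

    N counts toward the length but not toward G+C.  Raises ``ValueError``
    on an empty sequence.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise ValueError("gc_percent of empty sequence is undefined")
    gc = residues.count("G") + residues.count("C")
    return 100.0 * gc / len(residues)


def reverse_complement(seq: Union[SequenceRecord, str]):
    """Reverse complement over the RNA alphabet (A<->U, G<->C, N<->N)."""
    if isinstance(seq, SequenceRecord):
        return replace(seq, residues=reverse_complement(seq.residues))
    return seq.translate(_COMPLEMENT)[::-1]
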