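"""FASTA I/O and IUPAC nucleotide utilities for COI barcode records.

Barcode records are plain DNA strings (the ~650 bp COI amplicon consensus,
primer-trimmed or not) over the 15-letter IUPAC alphabet.  Species and
sampling-group labels travel in the FASTA description line as optional
whitespace-separated ``species=<name>`` / ``group=<name>`` tokens, so the
files stay readable by any other FASTA-aware tool.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "IUPAC_BASES",
    "SeqRecord",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_mask",
    "SeqFormatError",
]

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# bitmask encoding (A=1, C=2, G=4, T=8) for fast subset/intersection tests
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_IUPAC_MASK = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_BASES.items()
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}


class SeqFormatError(ValueError):
    """Raised for malformed FASTA input or invalid sequence characters."""


def iupac_mask(code: str) -> int:
    """Return the 4-bit base-set mask of one IUPAC code (A=1, C=2, G=4, T=8)."""
    try:
        return _IUPAC_MASK[code]
    except KeyError:
        raise SeqFormatError(f"invalid IUPAC nucleotide code {code!r}") from None


@dataclass(frozen=True)
class SeqRecord:
    """One barcode sequence with identifier and optional labels.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    sequence : str
        Uppercase IUPAC DNA.  Lowercase input is accepted and uppercased;
        ``U`` is rejected (DNA only).
    description : str
        Free text carried on the FASTA header (label tokens removed).
    declared_species : str, optional
        Species the sample was sold/labelled as.
    group : str, optional
        Sample group, e.g. a sampling year.
    """

    id: str
    sequence: str
    description: str = ""
    declared_species: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqFormatError("record id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise SeqFormatError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in IUPAC_BASES:
                raise SeqFormatError(
                    f"record {self.id!r}: invalid character {ch!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement (involution, length-preserving)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(sequence.upper()))
    except KeyError as exc:
        raise SeqFormatError(f"invalid IUPAC nucleotide code {exc.args[0]!r}") from None


def _parse_header(header: str) -> tuple[str, str, str | None, str | None]:
    parts = header.split()
    rec_id = parts[0] if parts else ""
    species = group = None
    rest: list[str] = []
    for tok in parts[1:]:
        if tok.startswith("species="):
            species = tok[len("species="):].replace("_", " ")
        elif tok.startswith("group="):
            group = tok[len("group="):]
        else:
            rest.append(tok)
    return rec_id, " ".join(rest), species, group


def read_fasta(source: Union[str, Path, TextIO]) -> list[SeqRecord]:
    """Read a FASTA file or text stream into a list of :class:`SeqRecord`.

    Headers are split as ``id description``; ``species=``/``group=`` tokens in
    the description populate the corresponding record fields.  Duplicate ids,
    empty sequences and non-IUPAC characters are hard errors.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.exists():
            handle: TextIO = path.open()
        elif isinstance(source, str) and source.lstrip().startswith(">"):
            handle = io.StringIO(source)
        else:
            raise FileNotFoundError(source)
        close = True
    else:
        handle, close = source, False

    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for header, seq in SimpleFastaParser(handle):
            rec_id, desc, species, group = _parse_header(header)
            if rec_id in seen:
                raise SeqFormatError(f"duplicate record id {rec_id!r}")
            seen.add(rec_id)
            records.append(
                SeqRecord(
                    id=rec_id,
                    sequence=seq.replace(" ", ""),
                    description=desc,
                    declared_species=species,
                    group=group,
                )
            )
    finally:
        if close:
            handle.close()
    return records


def write_fasta(records: Iterable[SeqRecord], wrap: int = 70) -> str:
    """Serialize records to FASTA text, wrapping sequence lines at ``wrap``.

    Species and group labels are written back as description tokens, so
    ``read_fasta(write_fasta(records))`` round-trips all fields.
    """
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    out: list[str] = []
    for rec in records:
        tokens = []
        if rec.description:
            tokens.append(rec.description)
        if rec.declared_species is not None:
            tokens.append(f"species={rec.declared_species.replace(' ', '_')}")
        if rec.group is not None:
            tokens.append(f"group={rec.group}")
        header = rec.id if not tokens else rec.id + " " + " ".join(tokens)
        out.append(">" + header)
        for i in range(0, len(rec.sequence), wrap):
            out.append(rec.sequence[i : i + wrap])
    return "\n".join(out) + ("\n" if out else "")
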