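"""Restriction enzymes, recognition-site scanning and in-silico digestion.

Recognition sites are written in caret notation (``^GATC`` for MboI,
``G^ANTC`` for HinfI): the caret marks where the top strand is cleaved.
Scanning is IUPAC-aware on both sides.  A sequence position *confirms* a
pattern position when the sequence base's set is a subset of the pattern
code's set; if the sets merely intersect (e.g. an ``N`` in the sequence
against a ``C`` in the pattern) the window is only a *candidate* site —
reported separately and never used for fragment arithmetic, so ambiguous
base calls cannot fabricate band patterns.

Coordinates are 0-based, half-open; "cut at position p" means the backbone
is severed between p−1 and p.  The double-stranded break of a site found on
the bottom strand is represented by its top-strand nick, which under the
symmetric cut geometry of orthodox type II enzymes lies at the same offset
from the window start as for a top-strand site; for palindromic enzymes
(all five shipped here) both-strand scanning therefore coincides exactly
with top-strand scanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import IUPAC_BASES, SeqRecord, iupac_mask, reverse_complement

__all__ = [
    "Enzyme",
    "SiteScan",
    "PrimerPair",
    "parse_enzyme",
    "find_sites",
    "digest",
    "insilico_pcr",
    "load_enzyme_table",
    "default_enzymes",
    "digest_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: named IUPAC recognition pattern + cut offset.

    ``cut_offset`` is the top-strand cleavage position relative to the
    pattern start, in ``[0, len(pattern)]``.
    """

    name: str
    pattern: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError(f"enzyme {self.name}: pattern must be at least 2 bases")
        for ch in self.pattern:
            if ch not in IUPAC_BASES:
                raise ValueError(
                    f"enzyme {self.name}: invalid IUPAC code {ch!r} in pattern"
                )
        if not 0 <= self.cut_offset <= len(self.pattern):
            raise ValueError(f"enzyme {self.name}: cut offset outside pattern")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.pattern) == self.pattern


@dataclass(frozen=True)
class SiteScan:
    """Cut coordinates from one scan.

    ``cut_positions`` are confirmed cuts (0-based; cut occurs before the
    index).  ``candidate_positions`` hold cuts whose windows match only
    through sequence-side ambiguity; the two lists are disjoint.
    """

    cut_positions: tuple[int, ...]
    candidate_positions: tuple[int, ...]


@dataclass(frozen=True)
class PrimerPair:
    """PCR primer pair; ``reverse`` is given 5'→3' on the bottom strand.

    Tails (e.g. M13 sequencing tails) are carried verbatim into the
    amplicon.  Matching allows up to ``max_mismatch`` IUPAC-aware
    mismatches and no indels.
    """

    forward: str
    reverse: str
    forward_tail: str = ""
    reverse_tail: str = ""
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")


def parse_enzyme(name: str, caret_notation: str) -> Enzyme:
    """Build an :class:`Enzyme` from caret notation, e.g. ``("MboI", "^GATC")``."""
    if caret_notation.count("^") != 1:
        raise ValueError(
            f"enzyme {name}: notation {caret_notation!r} must contain exactly one '^'"
        )
    offset = caret_notation.index("^")
    pattern = caret_notation.replace("^", "")
    return Enzyme(name=name, pattern=pattern.upper(), cut_offset=offset)


def _window_match(seq_masks: Sequence[int], start: int, pat_masks: Sequence[int]) -> int:
    """Classify window: 2 = confirmed, 1 = candidate (ambiguity only), 0 = none."""
    status = 2
    for off, pmask in enumerate(pat_masks):
        smask = seq_masks[start + off]
        if smask & pmask == 0:
            return 0
        if smask & ~pmask:
            status = 1
    return status


def _scan_windows(
    sequence: str, enzyme: Enzyme, both_strands: bool = True
) -> list[tuple[int, int, int]]:
    """Yield (window_start, strand, status) for all matching windows.

    strand is +1 for the recognition pattern on the top strand, -1 for the
    bottom strand; status 2 = confirmed, 1 = candidate.
    """
    seq = sequence.upper()
    length, pat_len = len(seq), len(enzyme.pattern)
    if pat_len > length:
        return []
    seq_masks = [iupac_mask(c) for c in seq]
    top = [iupac_mask(c) for c in enzyme.pattern]
    strands: list[tuple[int, list[int]]] = [(+1, top)]
    if both_strands:
        rc = reverse_complement(enzyme.pattern)
        if rc != enzyme.pattern:
            strands.append((-1, [iupac_mask(c) for c in rc]))
    hits: list[tuple[int, int, int]] = []
    for strand, masks in strands:
        for i in range(length - pat_len + 1):
            status = _window_match(seq_masks, i, masks)
            if status:
                hits.append((i, strand, status))
    return hits


def find_sites(sequence: str, enzyme: Enzyme, both_strands: bool = True) -> SiteScan:
    """Scan a linear double-stranded sequence for recognition sites.

    Overlapping matches all count.  A window at ``i`` contributes the cut
    ``i + cut_offset`` (top-strand nick; see module docstring for the
    bottom-strand convention).  Confirmed cuts take precedence: a position
    appears in ``candidate_positions`` only if no confirmed window also
    produces it.
    """
    confirmed: set[int] = set()
    candidate: set[int] = set()
    for start, _strand, status in _scan_windows(sequence, enzyme, both_strands):
        cut = start + enzyme.cut_offset
        (confirmed if status == 2 else candidate).add(cut)
    return SiteScan(
        cut_positions=tuple(sorted(confirmed)),
        candidate_positions=tuple(sorted(candidate - confirmed)),
    )


def digest(sequence: str, enzyme: Enzyme) -> list[int]:
    """Digest a linear sequence; return fragment lengths in sequence order.

    Only confirmed cuts are used; zero-length fragments (cuts at the very
    ends or coincident cuts) are dropped.  Fragment lengths always sum to
    the sequence length.
    """
    length = len(sequence)
    scan = find_sites(sequence, enzyme, both_strands=True)
    boundaries = sorted({0, length, *scan.cut_positions})
    frags = [b - a for a, b in zip(boundaries, boundaries[1:])]
    return [f for f in frags if f > 0]


def _mismatches(seq: str, start: int, primer_masks: Sequence[int]) -> int:
    n = 0
    for off, pmask in enumerate(primer_masks):
        if iupac_mask(seq[start + off]) & pmask == 0:
            n += 1
    return n


def _primer_matches(seq: str, primer: str, max_mismatch: int) -> list[int]:
    masks = [iupac_mask(c) for c in primer.upper()]
    return [
        i
        for i in range(len(seq) - len(masks) + 1)
        if _mismatches(seq, i, masks) <= max_mismatch
    ]


def insilico_pcr(template: SeqRecord | str, primers: PrimerPair) -> str | None:
    """Extract the amplicon a primer pair would produce from a template.

    The leftmost forward-primer match and the rightmost downstream match of
    the reverse primer's complement delimit the amplicon (both primer
    footprints included); tails are prepended/appended verbatim.  Returns
    ``None`` when either primer finds no match or the footprints overlap.
    """
    seq = template.sequence if isinstance(template, SeqRecord) else template.upper()
    fwd_hits = _primer_matches(seq, primers.forward, primers.max_mismatch)
    if not fwd_hits:
        logger.info("in-silico PCR: forward primer has no match")
        return None
    f_start = fwd_hits[0]
    f_end = f_start + len(primers.forward)
    rc_rev = reverse_complement(primers.reverse)
    rev_hits = [h for h in _primer_matches(seq, rc_rev, primers.max_mismatch) if h >= f_start]
    if not rev_hits:
        logger.info("in-silico PCR: reverse primer has no downstream match")
        return None
    r_start = rev_hits[-1]
    if r_start < f_end:
        logger.info("in-silico PCR: primer footprints overlap; no product")
        return None
    core = seq[f_start : r_start + len(rc_rev)]
    return primers.forward_tail + core + primers.reverse_tail


# ---------------------------------------------------------------------------
# Enzyme tables and digest reports

def load_enzyme_table(source: str | Path) -> list[Enzyme]:
    """Load enzymes from a TSV with columns ``name`` and ``site`` (caret notation)."""
    path = Path(source)
    enzymes: list[Enzyme] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_name, i_site = header.index("name"), header.index("site")
        except ValueError:
            raise ValueError(
                f"{path}: enzyme table must have 'name' and 'site' columns"
            ) from None
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            enzymes.append(parse_enzyme(fields[i_name], fields[i_site]))
    return enzymes


def default_enzymes() -> list[Enzyme]:
    """The five bundled enzymes: HpaII, HinfI, MboI, RsaI and HindIII."""
    ref = resources.files("coibar.data").joinpath("enzymes.tsv")
    with resources.as_file(ref) as path:
        return load_enzyme_table(path)


def digest_table(records: Iterable[SeqRecord], enzymes: Iterable[Enzyme]) -> str:
    """TSV digest report: record_id, enzyme, n_sites, fragment_sizes."""
    lines = ["record_id\tenzyme\tn_sites\tfragment_sizes"]
    for rec in records:
        for enz in enzymes:
            frags = digest(rec.sequence, enz)
            n_sites = len(find_sites(rec.sequence, enz).cut_positions)
            lines.append(
                f"{rec.id}\t{enz.name}\t{n_sites}\t" + ",".join(map(str, frags))
            )
    return "\n".join(lines) + "\n"
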