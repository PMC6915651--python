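"""Shared fixtures: enzymes, hand-built panels, and the brute-force scan oracle."""

from __future__ import annotations

import itertools
import random

import pytest

from coibar.restriction import Enzyme, default_enzymes
from coibar.seqio import IUPAC_BASES, SeqRecord, reverse_complement


@pytest.fixture(scope="session")
def enzymes() -> dict[str, Enzyme]:
    return {e.name: e for e in default_enzymes()}


@pytest.fixture(scope="session")
def mboi(enzymes) -> Enzyme:
    return enzymes["MboI"]


@pytest.fixture(scope="session")
def hinfi(enzymes) -> Enzyme:
    return enzymes["HinfI"]


def brute_force_sites(sequence: str, enzyme: Enzyme) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Oracle scanner: classify windows by enumerating every concrete
    expansion of the (possibly ambiguous) sequence window.

    A window is a confirmed site when *every* expansion matches the
    recognition pattern, a candidate when only some do.  Independent of the
    production scanner (set enumeration here, bitmask subset tests there).
    """
    seq = sequence.upper()
    pat_strands = [enzyme.pattern]
    rc = reverse_complement(enzyme.pattern)
    if rc != enzyme.pattern:
        pat_strands.append(rc)
    confirmed: set[int] = set()
    candidate: set[int] = set()
    L = len(enzyme.pattern)
    for pat in pat_strands:
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            outcomes = []
            for expansion in itertools.product(*[IUPAC_BASES[c] for c in window]):
                outcomes.append(
                    all(b in IUPAC_BASES[p] for b, p in zip(expansion, pat))
                )
            cut = i + enzyme.cut_offset
            if outcomes and all(outcomes):
                confirmed.add(cut)
            elif any(outcomes):
                candidate.add(cut)
    return tuple(sorted(confirmed)), tuple(sorted(candidate - confirmed))


def random_iupac_sequence(rng: random.Random, length: int, ambiguity_rate: float = 0.02) -> str:
    """Random DNA with occasional ambiguity codes (for scanner stress tests)."""
    codes = sorted(IUPAC_BASES)
    out = []
    for _ in range(length):
        if rng.random() < ambiguity_rate:
            out.append(rng.choice(codes))
        else:
            out.append(rng.choice("ACGT"))
    return "".join(out)


def polyA_with_sites(length: int, planted: dict[str, list[int]], enzymes_by_name) -> str:
    """Deterministic poly-A backbone (siteless for the five bundled enzymes)
    with recognition sites written at the requested cut positions."""
    seq = ["A"] * length
    for name, cuts in planted.items():
        enz = enzymes_by_name[name]
        for cut in cuts:
            start = cut - enz.cut_offset
            concrete = enz.pattern.replace("N", "A")
            seq[start : start + len(concrete)] = list(concrete)
    return "".join(seq)


@pytest.fixture(scope="session")
def make_labeled_record():
    def _make(rec_id: str, sequence: str, species: str) -> SeqRecord:
        return SeqRecord(id=rec_id, sequence=sequence, declared_species=species)

    return _make
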