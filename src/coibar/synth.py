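"""Seeded synthetic barcode panels with planted restriction-site layouts.

The generator emulates a validated multi-species reference panel: each
species gets a random backbone sequence carrying *no* recognition site of
any candidate enzyme, into which a species-specific set of sites for one
"planted" enzyme is written so that the resulting virtual-gel patterns are
pairwise non-matching across species.  Within-species copies receive random
substitutions (intraspecific variation) constrained never to create or
destroy a recognition site of any listed enzyme, so the planted truth stays
exact.  All randomness flows from one integer seed; identical inputs give
byte-identical panels.

Defaults mirror the study conditions the toolkit targets: five species,
~700 bp amplicons, five candidate enzymes of which one (MboI) separates
every species pair.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from typing import Mapping, Sequence

from .discriminate import ReferencePanel
from .gel import GelParams, GelPattern, make_pattern, patterns_match
from .restriction import Enzyme, default_enzymes, digest, find_sites
from .seqio import SeqRecord

__all__ = ["SynthTruth", "PanelInfeasibleError", "make_panel", "make_clade_variant"]

_BASES = "ACGT"
_MAX_ATTEMPTS = 10_000


class PanelInfeasibleError(RuntimeError):
    """Raised when no site layout satisfying all constraints can be found."""


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth of a generated panel.

    ``cut_positions`` maps species -> planted cut coordinates for the
    planted enzyme; ``expected_patterns`` holds the corresponding gel
    patterns; ``variant_labels`` maps record id -> clade label.
    """

    seed: int
    planted_enzyme: str
    cut_positions: Mapping[str, tuple[int, ...]]
    expected_patterns: Mapping[str, GelPattern]
    variant_labels: Mapping[str, str]
    params: GelParams

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "planted_enzyme": self.planted_enzyme,
            "params": {
                "min_band": self.params.min_band,
                "tolerance": self.params.tolerance,
            },
            "species": {
                sp: {
                    "cut_positions": list(self.cut_positions[sp]),
                    "expected_bands": [[s, m] for s, m in self.expected_patterns[sp].bands],
                }
                for sp in self.cut_positions
            },
            "variant_labels": dict(self.variant_labels),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _has_any_site(seq: str, enzymes: Sequence[Enzyme]) -> bool:
    return any(find_sites(seq, e).cut_positions for e in enzymes)


def _site_windows(seq: str, enzymes: Sequence[Enzyme]) -> list[tuple[int, int]]:
    """(start, end) windows of all confirmed sites of all enzymes."""
    from .restriction import _scan_windows  # internal scanning helper

    wins = []
    for e in enzymes:
        for start, _strand, status in _scan_windows(seq, e):
            if status == 2:
                wins.append((start, start + len(e.pattern)))
    return wins


def _scrub_sites(
    seq: list[str],
    enzymes: Sequence[Enzyme],
    rng: random.Random,
    protected: Sequence[tuple[int, int]] = (),
) -> None:
    """Point-mutate until no enzyme has a confirmed site, sparing ``protected``.

    Each round mutates one position inside one offending window; bounded to
    avoid livelock on adversarial layouts.
    """
    prot = set()
    for a, b in protected:
        prot.update(range(a, b))
    for _ in range(_MAX_ATTEMPTS):
        wins = [
            (a, b)
            for a, b in _site_windows("".join(seq), enzymes)
            if any(p not in prot for p in range(a, b))
        ]
        if not wins:
            return
        a, b = wins[0]
        free = [p for p in range(a, b) if p not in prot]
        pos = rng.choice(free)
        seq[pos] = rng.choice([c for c in _BASES if c != seq[pos]])
    raise PanelInfeasibleError("could not scrub restriction sites from backbone")


def _concrete(pattern: str, rng: random.Random) -> str:
    from .seqio import IUPAC_BASES

    return "".join(
        c if c in _BASES else rng.choice(sorted(IUPAC_BASES[c])) for c in pattern
    )


def _plan_layouts(
    length: int,
    n_species: int,
    enzyme: Enzyme,
    params: GelParams,
    rng: random.Random,
) -> list[list[int]]:
    """Choose per-species cut-position sets with pairwise non-matching patterns."""
    pat_len = len(enzyme.pattern)
    margin = max(2 * pat_len, 10)
    step = max(pat_len * 2, length // 60)
    grid = list(range(margin, length - margin, step))
    candidates: list[list[int]] = [[]]  # no cut: one full-length band
    candidates += [[c] for c in grid]
    candidates += [
        [c1, c2]
        for i, c1 in enumerate(grid)
        for c2 in grid[i + 1 :]
        if c2 - c1 >= 2 * pat_len
    ]

    def pattern_of(cuts: list[int]) -> GelPattern:
        bounds = [0, *cuts, length]
        frags = [b - a for a, b in zip(bounds, bounds[1:]) if b - a > 0]
        return make_pattern(frags, params)

    chosen: list[list[int]] = []
    chosen_patterns: list[GelPattern] = []
    for cuts in candidates:
        pat = pattern_of(cuts)
        if len(pat) == 0:
            continue
        if all(not patterns_match(pat, p) for p in chosen_patterns):
            chosen.append(cuts)
            chosen_patterns.append(pat)
        if len(chosen) == n_species:
            return chosen
    raise PanelInfeasibleError(
        f"cannot place {n_species} pairwise-distinct patterns in {length} bp "
        f"(min_band {params.min_band}, tolerance {params.tolerance})"
    )


def _build_species_sequence(
    length: int,
    cuts: Sequence[int],
    enzymes: Sequence[Enzyme],
    planted: Enzyme,
    rng: random.Random,
) -> str:
    pat_len = len(planted.pattern)
    for _ in range(100):
        seq = [rng.choice(_BASES) for _ in range(length)]
        windows = []
        ok = True
        for cut in cuts:
            start = cut - planted.cut_offset
            if start < 0 or start + pat_len > length:
                ok = False
                break
            site = _concrete(planted.pattern, rng)
            seq[start : start + pat_len] = list(site)
            windows.append((start, start + pat_len))
        if not ok:
            raise PanelInfeasibleError("planted cut too close to a sequence end")
        try:
            _scrub_sites(seq, enzymes, rng, protected=windows)
        except PanelInfeasibleError:
            continue
        s = "".join(seq)
        if tuple(find_sites(s, planted).cut_positions) == tuple(sorted(cuts)) and not any(
            find_sites(s, e).cut_positions for e in enzymes if e.name != planted.name
        ):
            return s
    raise PanelInfeasibleError("could not realize the planted site layout")


def _mutate_neutrally(
    seq: str, rate: float, enzymes: Sequence[Enzyme], rng: random.Random
) -> str:
    """Apply substitutions at ``rate`` per site without changing any site set."""
    if rate <= 0:
        return seq
    reference_sites = {e.name: find_sites(seq, e).cut_positions for e in enzymes}
    out = list(seq)
    for pos in range(len(out)):
        if rng.random() >= rate:
            continue
        alternatives = [c for c in _BASES if c != out[pos]]
        rng.shuffle(alternatives)
        original = out[pos]
        for alt in alternatives:
            out[pos] = alt
            s = "".join(out)
            if all(
                find_sites(s, e).cut_positions == reference_sites[e.name]
                for e in enzymes
            ):
                break
            out[pos] = original
    return "".join(out)


def make_panel(
    seed: int,
    n_species: int = 5,
    n_per_species: int = 2,
    length: int = 700,
    enzymes: Sequence[Enzyme] | None = None,
    planted_enzyme: str = "MboI",
    intraspecific_rate: float = 0.005,
    params: GelParams | None = None,
) -> tuple[ReferencePanel, SynthTruth]:
    """Generate a labelled reference panel with a known discriminating enzyme.

    Every non-planted enzyme is scrubbed from every sequence (decoys never
    cut); the planted enzyme's sites are species-specific and chosen so the
    per-species gel patterns are pairwise non-matching under ``params``.
    """
    if length < 300:
        raise ValueError("length must be >= 300")
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    enzymes = list(enzymes) if enzymes is not None else default_enzymes()
    by_name = {e.name: e for e in enzymes}
    if planted_enzyme not in by_name:
        raise ValueError(f"planted enzyme {planted_enzyme!r} not in enzyme list")
    planted = by_name[planted_enzyme]
    params = params or GelParams()
    rng = random.Random(seed)

    layouts = _plan_layouts(length, n_species, planted, params, rng)
    species_records: dict[str, tuple[SeqRecord, ...]] = {}
    cut_positions: dict[str, tuple[int, ...]] = {}
    expected: dict[str, GelPattern] = {}
    variant_labels: dict[str, str] = {}
    for i, cuts in enumerate(layouts):
        # no underscores: the FASTA label dialect reads them as spaces
        sp = f"sp{i + 1:02d}"
        backbone = _build_species_sequence(length, cuts, enzymes, planted, rng)
        recs = []
        for j in range(n_per_species):
            s = backbone if j == 0 else _mutate_neutrally(
                backbone, intraspecific_rate, enzymes, rng
            )
            rec = SeqRecord(
                id=f"{sp}_r{j + 1:02d}",
                sequence=s,
                declared_species=sp,
                group="synthetic",
            )
            recs.append(rec)
            variant_labels[rec.id] = "variant_1"
        species_records[sp] = tuple(recs)
        cut_positions[sp] = tuple(sorted(cuts))
        expected[sp] = make_pattern(digest(backbone, planted), params)

    panel = ReferencePanel(species=species_records)
    truth = SynthTruth(
        seed=seed,
        planted_enzyme=planted.name,
        cut_positions=cut_positions,
        expected_patterns=expected,
        variant_labels=variant_labels,
        params=params,
    )
    return panel, truth


def make_clade_variant(
    record: SeqRecord, enzyme: Enzyme, mode: str, seed: int = 0
) -> SeqRecord:
    """Derive an intraspecific variant by gaining or losing one site.

    ``mode="add-site"`` writes one new recognition site with minimal
    substitutions; ``mode="remove-site"`` destroys one existing site with a
    single substitution.  Length is preserved and the gel pattern is
    guaranteed to differ from the original.
    """
    if mode not in {"add-site", "remove-site"}:
        raise ValueError("mode must be 'add-site' or 'remove-site'")
    rng = random.Random(seed)
    seq = record.sequence
    pat_len = len(enzyme.pattern)
    before_cuts = find_sites(seq, enzyme).cut_positions
    before_pattern = make_pattern(digest(seq, enzyme))

    def finish(new_seq: str) -> SeqRecord:
        return SeqRecord(
            id=record.id + ("+site" if mode == "add-site" else "-site"),
            sequence=new_seq,
            description=record.description,
            declared_species=record.declared_species,
            group=record.group,
        )

    if mode == "add-site":
        starts = list(range(len(seq) - pat_len + 1))
        # prefer positions needing the fewest substitutions, tie-broken by seed
        rng.shuffle(starts)

        def hamming(start: int, site: str) -> int:
            return sum(1 for k in range(pat_len) if seq[start + k] != site[k])

        scored = []
        for start in starts:
            site = _concrete(enzyme.pattern, rng)
            scored.append((hamming(start, site), start, site))
        for _, start, site in sorted(scored, key=lambda t: t[0]):
            cand = seq[:start] + site + seq[start + pat_len :]
            cuts = find_sites(cand, enzyme).cut_positions
            if len(cuts) != len(before_cuts) + 1 or not set(before_cuts) <= set(cuts):
                continue
            frags_before = digest(seq, enzyme)
            frags_after = digest(cand, enzyme)
            if len(frags_after) != len(frags_before) + 1:
                continue
            if patterns_match(make_pattern(frags_after), before_pattern):
                continue
            return finish(cand)
        raise PanelInfeasibleError("no position yields a clean extra site")

    if not before_cuts:
        raise ValueError("remove-site requires at least one existing site")
    windows = [(c - enzyme.cut_offset, c - enzyme.cut_offset + pat_len) for c in before_cuts]
    rng.shuffle(windows)
    for a, b in windows:
        positions = list(range(max(a, 0), min(b, len(seq))))
        rng.shuffle(positions)
        for pos in positions:
            for alt in rng.sample(_BASES, 4):
                if alt == seq[pos]:
                    continue
                cand = seq[:pos] + alt + seq[pos + 1 :]
                cuts = find_sites(cand, enzyme).cut_positions
                if len(cuts) != len(before_cuts) - 1 or not set(cuts) <= set(before_cuts):
                    continue
                if patterns_match(make_pattern(digest(cand, enzyme)), before_pattern):
                    continue
                return finish(cand)
    raise PanelInfeasibleError("could not destroy a site without side effects")
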