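"""Virtual agarose gel: visible band patterns and tolerance-based comparison.

A digest's fragment list becomes a band pattern by (1) discarding fragments
below the visibility threshold (default 100 bp — small fragments run off or
are too faint on a 3% gel) and (2) merging comigrating fragments whose
sizes differ by at most a relative tolerance (default 10%, since gel sizes
are read off a ladder only approximately) into a single band at their
rounded mean.  Band multiplicity is recorded for reporting but ignored when
matching patterns, because band intensity is not reliably readable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "DEFAULT_MIN_BAND",
    "DEFAULT_TOLERANCE",
    "GelParams",
    "GelPattern",
    "make_pattern",
    "patterns_match",
    "pattern_distance",
    "read_band_table",
]

#: Minimum visible band size in bp.
DEFAULT_MIN_BAND = 100
#: Relative size tolerance (fraction of the larger band) for comigration
#: merging and for pattern matching.  Single documented constant,
#: overridable everywhere it is used.
DEFAULT_TOLERANCE = 0.10


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class GelParams:
    """Gel model parameters: visibility threshold and size tolerance."""

    min_band: int = DEFAULT_MIN_BAND
    tolerance: float = DEFAULT_TOLERANCE
    max_band: int | None = None

    def __post_init__(self) -> None:
        if self.min_band < 0:
            raise ValueError("min_band must be >= 0")
        if not 0 <= self.tolerance < 1:
            raise ValueError("tolerance must be in [0, 1)")


@dataclass(frozen=True)
class GelPattern:
    """Visible bands as ``(size, multiplicity)`` sorted by size descending."""

    bands: tuple[tuple[int, int], ...]
    params: GelParams = field(default_factory=GelParams)

    def __post_init__(self) -> None:
        sizes = [s for s, _ in self.bands]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("band sizes must be strictly decreasing")
        if any(s < self.params.min_band for s in sizes):
            raise ValueError("band below min_band")
        if any(m < 1 for _, m in self.bands):
            raise ValueError("multiplicities must be >= 1")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def _rel_diff(a: float, b: float) -> float:
    return abs(a - b) / max(a, b)


def make_pattern(fragments: Iterable[float], params: GelParams | None = None) -> GelPattern:
    """Convert fragment sizes (bp) into the visible band pattern.

    Fragments below ``min_band`` (and above ``max_band``, if set) are
    dropped; remaining sizes are sorted descending and adjacent bands within
    relative ``tolerance`` are merged into one band at the
    multiplicity-weighted rounded mean, repeated until stable.
    """
    params = params or GelParams()
    sizes = [f for f in fragments if f > 0]
    if any(f <= 0 for f in fragments):
        raise ValueError("fragment sizes must be positive")
    sizes = [f for f in sizes if f >= params.min_band]
    if params.max_band is not None:
        sizes = [f for f in sizes if f <= params.max_band]
    # merge largest-first; rounding happens inside the loop so the final
    # band list is stable under a re-run (idempotence)
    bands: list[list[int]] = [[_round_half_up(s), 1] for s in sorted(sizes, reverse=True)]
    changed = True
    while changed:
        changed = False
        for i in range(len(bands) - 1):
            (sa, ma), (sb, mb) = bands[i], bands[i + 1]
            if _rel_diff(sa, sb) <= params.tolerance:
                merged = _round_half_up((sa * ma + sb * mb) / (ma + mb))
                bands[i : i + 2] = [[merged, ma + mb]]
                changed = True
                break
    return GelPattern(bands=tuple((s, m) for s, m in bands), params=params)


def _check_comparable(a: GelPattern, b: GelPattern) -> None:
    if a.params.min_band != b.params.min_band:
        raise ValueError(
            "patterns built with different min_band are not comparable "
            f"({a.params.min_band} vs {b.params.min_band})"
        )


def patterns_match(a: GelPattern, b: GelPattern, tolerance: float | None = None) -> bool:
    """True iff the two patterns would look identical on a gel.

    Band counts (ignoring multiplicity) must be equal and, pairing bands in
    descending-size order, every pair must lie within relative
    ``tolerance``.  Symmetric and reflexive.
    """
    _check_comparable(a, b)
    tol = a.params.tolerance if tolerance is None else tolerance
    if len(a) != len(b):
        return False
    return all(_rel_diff(sa, sb) <= tol for sa, sb in zip(a.sizes, b.sizes))


def pattern_distance(a: GelPattern, b: GelPattern, tolerance: float | None = None) -> float:
    """Fraction of unmatched bands between two patterns, in [0, 1].

    Bands are greedily matched in descending-size order within relative
    ``tolerance``; distance = 1 − 2·matched / (|a| + |b|).  Two empty
    patterns have distance 0 by convention; the distance is 0 exactly when
    :func:`patterns_match` holds.
    """
    _check_comparable(a, b)
    tol = a.params.tolerance if tolerance is None else tolerance
    if len(a) == 0 and len(b) == 0:
        return 0.0
    used = [False] * len(b)
    matched = 0
    for sa in a.sizes:
        for j, sb in enumerate(b.sizes):
            if not used[j] and _rel_diff(sa, sb) <= tol:
                used[j] = True
                matched += 1
                break
    return 1.0 - (2.0 * matched) / (len(a) + len(b))


def read_band_table(source) -> dict[str, list[int]]:
    """Read observed band sizes: TSV with ``sample_id`` and comma-joined bp sizes."""
    from pathlib import Path

    text = Path(source).read_text()
    out: dict[str, list[int]] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if ln == 1 and fields[0].lower() in {"sample_id", "sample"}:
            continue
        if len(fields) < 2:
            raise ValueError(f"band table line {ln}: expected sample_id<TAB>sizes")
        sample, sizes = fields[0], fields[1]
        out[sample] = [int(s) for s in sizes.split(",") if s.strip()]
    return out
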