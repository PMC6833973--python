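"""Anchor-motif search and voltage-sensor segment windows.

The conserved four-residue NxxD motif at the N-half of S3 (and its
family variants FxxD and C/S-x-x-D) anchors three analysis windows:

* S3    — from the motif to the annotated C-end of S3;
* S3-S4 — from the motif to the annotated C-end of S4;
* S1-S4 — the whole sensor, from the annotated N-end of S1 to the
  C-end of S4.

Boundary annotations are inputs (curated from sequence databases and
the literature), never inferred.  All positions are 1-based; windows
are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .msa_consensus import AMINO_ACIDS

_ANY = frozenset(AMINO_ACIDS)


class InconsistentAnnotationError(ValueError):
    """Anchor and boundary annotation disagree."""


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate 4-residue pattern; position 4 is always the
    conserved acidic charge-transfer-center aspartate."""

    name: str
    position_sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.position_sets) != 4:
            raise ValueError("motif patterns are exactly 4 positions long")
        if "D" not in self.position_sets[3]:
            raise ValueError("position 4 must admit the conserved Asp (D)")

    def matches_at(self, sequence: str, start: int) -> bool:
        """True if the pattern matches at 1-based position ``start``."""
        window = sequence[start - 1 : start + 3]
        if len(window) < 4:
            return False
        return all(res in s for res, s in zip(window, self.position_sets))


def _pattern(name: str, p1: str, p2: str, p3: str, p4: str) -> MotifPattern:
    def to_set(spec: str) -> frozenset[str]:
        return _ANY if spec == "x" else frozenset(spec)

    return MotifPattern(name, tuple(to_set(p) for p in (p1, p2, p3, p4)))


#: NxxD and the family variants observed in Kv7 (C/S-x-x-D) and in
#: CNG-like channels (FxxD).
BUILTIN_PATTERNS: dict[str, MotifPattern] = {
    "NxxD": _pattern("NxxD", "N", "x", "x", "D"),
    "FxxD": _pattern("FxxD", "F", "x", "x", "D"),
    "C/SxxD": _pattern("C/SxxD", "CS", "x", "x", "D"),
}


@dataclass(frozen=True)
class SegmentBoundaries:
    """Per-family boundary annotation (1-based, inclusive residue numbers)."""

    family_id: str
    s1_start: int | None = None
    s3_start: int | None = None
    s3_end: int | None = None
    s4_end: int | None = None
    motif_variant: str = "NxxD"
    source: str = ""


@dataclass(frozen=True)
class SegmentWindows:
    """The three analysis windows for one family.

    Each window is a half-open 1-based interval ``(start, end)`` or
    ``None`` when the needed boundary is not annotated.  When all three
    are defined they nest: s3 ⊂ s3s4 ⊂ s1s4, and s3 starts at the
    anchor.
    """

    family_id: str
    anchor_position: int
    s3_window: tuple[int, int] | None
    s3s4_window: tuple[int, int] | None
    s1s4_window: tuple[int, int] | None
    boundary_source: str = ""

    def subsequence(self, sequence: str, segment: str) -> str:
        window = getattr(self, f"{segment}_window")
        if window is None:
            raise ValueError(f"window {segment!r} is not defined")
        start, end = window
        return sequence[start - 1 : end - 1]


def find_anchor_motif(
    sequence: str,
    patterns: Iterable[MotifPattern] | None = None,
) -> list[tuple[str, int]]:
    """All matches of all patterns, in sequence order (1-based starts).

    Equivalent to a brute-force scan of every 4-residue window; returns
    an empty list when nothing matches.
    """
    if len(sequence) < 4:
        raise ValueError("sequence shorter than the 4-residue motif")
    pats = list(patterns) if patterns is not None else list(BUILTIN_PATTERNS.values())
    hits: list[tuple[str, int]] = []
    for start in range(1, len(sequence) - 2):
        for pat in pats:
            if pat.matches_at(sequence, start):
                hits.append((pat.name, start))
    return hits


def choose_anchor(
    matches: Sequence[tuple[str, int]],
    boundaries: SegmentBoundaries,
) -> int:
    """Pick the unique anchor among motif matches.

    The match closest to the annotated S3 N-terminus wins (the motif is
    treated as the unique S3a anchor); without an ``s3_start``
    annotation the earliest match compatible with the S3 C-end is used.
    """
    if not matches:
        raise InconsistentAnnotationError(
            f"family {boundaries.family_id!r}: no motif match found"
        )
    candidates = [pos for _, pos in matches]
    if boundaries.s3_end is not None:
        inside = [p for p in candidates if p + 3 <= boundaries.s3_end]
        candidates = inside or candidates
    if boundaries.s3_start is not None:
        return min(candidates, key=lambda p: (abs(p - boundaries.s3_start), p))
    return min(candidates)


def extract_windows(
    sequence: str,
    anchor: int,
    boundaries: SegmentBoundaries,
) -> SegmentWindows:
    """Cut the S3 / S3-S4 / S1-S4 windows around a verified anchor.

    Windows whose boundary is missing are returned as ``None``; an
    anchor lying outside the annotated S3 raises
    :class:`InconsistentAnnotationError`.
    """
    if not 1 <= anchor <= len(sequence) - 3:
        raise InconsistentAnnotationError(
            f"anchor {anchor} outside sequence of length {len(sequence)}"
        )
    if boundaries.s3_end is not None and boundaries.s3_end < anchor + 3:
        raise InconsistentAnnotationError(
            f"family {boundaries.family_id!r}: anchor {anchor} inconsistent "
            f"with annotated S3 C-end {boundaries.s3_end}"
        )
    if boundaries.s3_start is not None and anchor < boundaries.s3_start:
        raise InconsistentAnnotationError(
            f"family {boundaries.family_id!r}: anchor {anchor} precedes "
            f"annotated S3 N-end {boundaries.s3_start}"
        )

    s3 = (anchor, boundaries.s3_end + 1) if boundaries.s3_end is not None else None
    s3s4 = (anchor, boundaries.s4_end + 1) if boundaries.s4_end is not None else None
    s1s4 = (
        (boundaries.s1_start, boundaries.s4_end + 1)
        if boundaries.s1_start is not None and boundaries.s4_end is not None
        else None
    )
    for name, win in (("s3", s3), ("s3s4", s3s4), ("s1s4", s1s4)):
        if win is not None and not (1 <= win[0] < win[1] <= len(sequence) + 1):
            raise InconsistentAnnotationError(
                f"family {boundaries.family_id!r}: window {name} {win} "
                f"outside sequence of length {len(sequence)}"
            )
    if s3 is not None and s3s4 is not None:
        if not (s3s4[0] <= s3[0] and s3[1] <= s3s4[1]):
            raise InconsistentAnnotationError("S3 window not nested in S3-S4")
    if s3s4 is not None and s1s4 is not None:
        if not (s1s4[0] <= s3s4[0] and s3s4[1] <= s1s4[1]):
            raise InconsistentAnnotationError("S3-S4 window not nested in S1-S4")
    return SegmentWindows(
        family_id=boundaries.family_id,
        anchor_position=anchor,
        s3_window=s3,
        s3s4_window=s3s4,
        s1s4_window=s1s4,
        boundary_source=boundaries.source,
    )


def read_boundaries_tsv(path: str | Path) -> dict[str, SegmentBoundaries]:
    """Read per-family boundary annotations.

    Columns: family_id, s1_start, s3_end, s4_end and optionally
    s3_start, motif_variant, source.  Empty cells mean "not annotated".
    """
    out: dict[str, SegmentBoundaries] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            fam = row["family_id"].strip()

            def num(key: str) -> int | None:
                value = (row.get(key) or "").strip()
                return int(value) if value else None

            out[fam] = SegmentBoundaries(
                family_id=fam,
                s1_start=num("s1_start"),
                s3_start=num("s3_start"),
                s3_end=num("s3_end"),
                s4_end=num("s4_end"),
                motif_variant=(row.get("motif_variant") or "NxxD").strip(),
                source=(row.get("source") or "").strip(),
            )
    return out


def write_windows_tsv(
    windows: Iterable[SegmentWindows], path: str | Path
) -> None:
    """BED-like TSV: family, segment, start, end (half-open 1-based), anchor."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["family_id", "segment", "start", "end", "anchor"])
        for win in windows:
            for segment in ("s3", "s3s4", "s1s4"):
                interval = getattr(win, f"{segment}_window")
                if interval is None:
                    continue
                writer.writerow(
                    [win.family_id, segment, interval[0], interval[1], win.anchor_position]
                )
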