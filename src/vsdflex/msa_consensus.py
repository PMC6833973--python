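"""Per-column statistics, ranked consensus sequences and logo matrices.

An aligned protein family is reduced to per-column residue frequency
profiles, from which three ranked consensus sequences are built (the
most, second-most and third-most frequent residue at every column).
The second and third ranks carry the within-family compositional
dispersion that downstream flexibility indices report as a standard
deviation across ranks.

Coordinates are 1-based throughout; intervals elsewhere in the package
are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

logger = logging.getLogger(__name__)

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
UNKNOWN: str = "X"
#: Placeholder written where a consensus rank does not exist
#: (fewer distinct residues than ranks, or a gap-majority column).
SENTINEL: str = "."

MAX_INFO_BITS: float = math.log2(20.0)

#: Residue colour classes used for logo rendering.  Side-chain character
#: drives the grouping: aliphatic hydrophobics, rigid aromatics, the
#: helix-stabilising alanine, small flexible residues, flexible polar
#: uncharged residues, charged residues, the helix-breaker proline, and
#: cysteine/histidine kept apart for their special chemistry.
COLOR_CLASSES: dict[str, str] = {
    "I": "red (hydrophobic)",
    "L": "red (hydrophobic)",
    "M": "red (hydrophobic)",
    "V": "red (hydrophobic)",
    "F": "dark red (aromatic rigid)",
    "W": "dark red (aromatic rigid)",
    "Y": "dark red (aromatic rigid)",
    "A": "salmon (α-helix stabilizing)",
    "G": "orange (small flexible)",
    "S": "orange (small flexible)",
    "N": "gray (polar uncharged flexible)",
    "Q": "gray (polar uncharged flexible)",
    "T": "gray (polar uncharged flexible)",
    "K": "dark blue (positive charged)",
    "R": "dark blue (positive charged)",
    "D": "teal (negative charged)",
    "E": "teal (negative charged)",
    "P": "purple (α-helix breaker)",
    "C": "black (Cys/His)",
    "H": "black (Cys/His)",
}


class AlignmentFormatError(ValueError):
    """Raised for unparseable or internally inconsistent alignment input."""


class EmptyInputError(ValueError):
    """Raised when an input file contains no sequence records."""


@dataclass(frozen=True)
class Alignment:
    """An aligned protein family.

    ``records`` is an ordered list of ``(sequence_id, residues)`` pairs
    where ``residues`` is an uppercase string over the 20 standard amino
    acids, the gap symbol ``-`` and the unknown symbol ``X``.
    """

    family_id: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"unequal sequence lengths in family {self.family_id!r}: "
                f"{sorted(lengths)}"
            )
        allowed = set(AMINO_ACIDS) | {GAP, UNKNOWN}
        for name, seq in self.records:
            bad = set(seq) - allowed
            if bad:
                raise AlignmentFormatError(
                    f"record {name!r} contains invalid symbols {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue composition of one alignment column (1-based position).

    ``frequencies`` are over non-gap, non-unknown residues and sum to 1
    whenever any standard residue is present; gaps and ``X`` count toward
    ``gap_fraction`` only.
    """

    position: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    gap_fraction: float

    def ranked(self) -> list[tuple[str, float]]:
        """Residues sorted by descending frequency, ties alphabetical."""
        return sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class ConsensusSet:
    """Ranked consensus sequences for one family.

    ``sequences[r]`` (r = 0..k-1) holds the (r+1)-th most frequent
    residue per column, with :data:`SENTINEL` where that rank does not
    exist.  Columns with ``gap_fraction >= 0.5`` are flagged and carry
    the sentinel in every rank.
    """

    family_id: str
    sequences: tuple[str, ...]
    ranked_frequencies: tuple[tuple[tuple[str, float], ...], ...]
    flagged_columns: frozenset[int] = field(default_factory=frozenset)

    @property
    def rank1(self) -> str:
        return self.sequences[0]

    @property
    def rank2(self) -> str | None:
        return self.sequences[1] if len(self.sequences) > 1 else None

    @property
    def rank3(self) -> str | None:
        return self.sequences[2] if len(self.sequences) > 2 else None

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column Shannon information content and letter heights (bits)."""

    positions: tuple[int, ...]
    info_bits: tuple[float, ...]
    heights: tuple[dict[str, float], ...]

    def color_class(self, residue: str) -> str:
        return residue_color_class(residue)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned family from a FASTA or Clustal file.

    Ragged (unequal-length) input and symbols outside the amino-acid
    alphabet are rejected with :class:`AlignmentFormatError`; an empty
    file raises :class:`EmptyInputError`.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        text = path.read_text() if path.exists() else ""
        if not text.strip():
            raise EmptyInputError(f"{path}: empty alignment file") from exc
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    records = tuple((rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in msa)
    if not records:
        raise EmptyInputError(f"{path}: no records")
    return Alignment(family_id=path.stem, records=records)


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column, invariant to record order."""
    n = aln.n_sequences
    profiles: list[ColumnProfile] = []
    for j in range(aln.length):
        column = [seq[j] for _, seq in aln.records]
        counts = Counter(column)
        n_gap = counts.pop(GAP, 0) + counts.pop(UNKNOWN, 0)
        total = sum(counts.values())
        freqs = {res: c / total for res, c in counts.items()} if total else {}
        profiles.append(
            ColumnProfile(
                position=j + 1,
                counts=dict(counts),
                frequencies=freqs,
                gap_fraction=n_gap / n,
            )
        )
    return profiles


def build_consensus_set(
    profiles: Sequence[ColumnProfile],
    family_id: str = "",
    k: int = 3,
) -> ConsensusSet:
    """Build the ``k`` ranked consensus sequences from column profiles.

    Rank r takes the r-th most frequent non-gap residue per column
    (ties broken alphabetically by one-letter code).  Columns with
    ``gap_fraction >= 0.5`` are flagged and excluded (sentinel in every
    rank); an all-gap column additionally logs a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not profiles:
        raise EmptyInputError("no column profiles given")
    seqs = [[] for _ in range(k)]
    ranked_all: list[tuple[tuple[str, float], ...]] = []
    flagged: set[int] = set()
    for prof in profiles:
        ranked = prof.ranked()
        ranked_all.append(tuple(ranked))
        if prof.gap_fraction >= 0.5 or not ranked:
            if not ranked:
                logger.warning(
                    "family %s: column %d is all-gap; sentinel emitted",
                    family_id, prof.position,
                )
            flagged.add(prof.position)
            for r in range(k):
                seqs[r].append(SENTINEL)
            continue
        for r in range(k):
            seqs[r].append(ranked[r][0] if r < len(ranked) else SENTINEL)
    return ConsensusSet(
        family_id=family_id,
        sequences=tuple("".join(s) for s in seqs),
        ranked_frequencies=tuple(ranked_all),
        flagged_columns=frozenset(flagged),
    )


def logo_matrix(profiles: Sequence[ColumnProfile]) -> LogoMatrix:
    """Shannon information content (bits) and letter heights per column.

    IC = log2(20) - H(column); letter height = frequency * IC, so
    heights sum to the column information content.  No small-sample
    correction is applied (kept off for determinism at any depth).
    """
    if not profiles:
        raise EmptyInputError("no column profiles given")
    positions, info, heights = [], [], []
    for prof in profiles:
        positions.append(prof.position)
        if not prof.frequencies:
            info.append(0.0)
            heights.append({})
            continue
        entropy = -sum(f * math.log2(f) for f in prof.frequencies.values() if f > 0)
        ic = max(0.0, MAX_INFO_BITS - entropy)
        info.append(ic)
        heights.append({res: f * ic for res, f in prof.frequencies.items()})
    return LogoMatrix(
        positions=tuple(positions),
        info_bits=tuple(info),
        heights=tuple(heights),
    )


def residue_color_class(residue: str) -> str:
    """Colour class of a standard amino acid (total mapping)."""
    try:
        return COLOR_CLASSES[residue.upper()]
    except KeyError:
        raise ValueError(f"unknown residue symbol: {residue!r}") from None


def write_consensus_fasta(cs: ConsensusSet, path: str | Path) -> None:
    """Write the ranked consensus sequences as FASTA (rank tag in header)."""
    with open(path, "w") as fh:
        for r, seq in enumerate(cs.sequences, start=1):
            fh.write(f">{cs.family_id}|rank{r}\n{seq}\n")


def write_logo_tsv(
    profiles: Sequence[ColumnProfile],
    logo: LogoMatrix,
    path: str | Path,
) -> None:
    """Logo matrix as TSV: position, residue, count, frequency, info_bits, color_class."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["position", "residue", "count", "frequency", "info_bits", "color_class"]
        )
        for prof, ic in zip(profiles, logo.info_bits):
            for res, freq in prof.ranked():
                writer.writerow(
                    [
                        prof.position,
                        res,
                        prof.counts[res],
                        f"{freq:.6g}",
                        f"{ic:.6g}",
                        residue_color_class(res),
                    ]
                )
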