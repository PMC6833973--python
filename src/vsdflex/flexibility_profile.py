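"""Normalized-B-factor flexibility profiles, mBf and the 1/mBf index.

A residue sequence is mapped through a packaged normalized-B-factor
scale, smoothed over a symmetric neighbour window (flexibility of a
side chain depends on its sequence neighbours), and reduced to the
mean B-factor mBf and the flexibility index 1/mBf.  Per-family indices
computed from the three ranked consensus sequences carry the
compositional dispersion as the standard deviation across ranks.

Index orientation: the packaged scales score flexible side chains
high, so the raw 1/mBf is *lower* for flexible segments.  Reported
family-level indices follow the opposite, field-standard convention
(larger index = more flexible); an affine calibration of mBf against
reference index values — fitted once via :func:`calibrate_scale` —
flips and rescales the axis.  Raw per-position values are always
available for audit.
"""

from __future__ import annotations

import csv
import io
import math
import statistics
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .msa_consensus import AMINO_ACIDS, SENTINEL, ConsensusSet, GAP
from .segment_annotation import SegmentWindows

_SCALE_FILES = {
    "bnorm-vihinen": "scale_bnorm_vihinen.tsv",
    "bnorm-karplus-schulz": "scale_bnorm_karplus_schulz.tsv",
}

CLASS_LABELS = ("rigid", "intermediate", "flexible")


class UnknownScaleError(KeyError):
    """Requested scale is not packaged."""


@dataclass(frozen=True)
class FlexibilityScale:
    """A per-residue normalized B-value scale with its smoothing window.

    ``calibration`` is an optional affine map ``(slope, intercept)``
    applied to mBf before inversion; it encodes the orientation and
    absolute level of the reported index (see module docstring).
    """

    name: str
    values: dict[str, float]
    window_length: int = 9
    window_weights: tuple[float, ...] = ()
    calibration: tuple[float, float] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        mean = sum(self.values[a] for a in AMINO_ACIDS) / 20.0
        if not 0.9 <= mean <= 1.1:
            raise ValueError(
                f"scale {self.name!r} not normalized: residue mean {mean:.3f}"
            )
        if self.window_length % 2 != 1 or self.window_length < 1:
            raise ValueError("window_length must be an odd positive integer")
        weights = self.window_weights
        if len(weights) != self.window_length:
            raise ValueError("window_weights length != window_length")
        if any(w < 0 for w in weights):
            raise ValueError("window weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("window weights must sum to 1")
        if any(abs(weights[i] - weights[-1 - i]) > 1e-12 for i in range(len(weights))):
            raise ValueError("window weights must be symmetric about the center")

    def calibrated_mbf(self, mbf: float) -> float:
        if self.calibration is None:
            return mbf
        slope, intercept = self.calibration
        return slope * mbf + intercept


@dataclass(frozen=True)
class FlexibilityProfile:
    """Per-position smoothed values and segment-level summary.

    ``index`` is exactly ``1 / mBf`` (mBf after any scale calibration);
    ``dispersion`` is the population standard deviation of the index
    across the available consensus ranks.
    """

    family_id: str
    segment_name: str
    values: tuple[float, ...]
    mbf: float
    index: float
    rank_indices: tuple[float, ...] = ()
    dispersion: float = 0.0
    class_label: str | None = None


def available_scales() -> list[str]:
    return sorted(_SCALE_FILES)


def _read_scale_text(text: str, name: str) -> FlexibilityScale:
    window_length = 9
    weights: tuple[float, ...] | None = None
    description_lines: list[str] = []
    values: dict[str, float] = {}
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("window_length:"):
                window_length = int(body.split(":", 1)[1])
            elif body.startswith("window_weights:"):
                raw = [float(v) for v in body.split(":", 1)[1].split()]
                total = sum(raw)
                weights = tuple(v / total for v in raw)
            elif body.startswith("orientation:"):
                pass
            else:
                description_lines.append(body)
            continue
        if line.strip():
            rows.append(line)
    reader = csv.DictReader(io.StringIO("\n".join(rows)), delimiter="\t")
    for row in reader:
        values[row["residue"].strip()] = float(row["value"])
    if weights is None:
        half = window_length // 2
        raw = [half + 1 - abs(i - half) for i in range(window_length)]
        weights = tuple(v / sum(raw) for v in raw)
    return FlexibilityScale(
        name=name,
        values=values,
        window_length=window_length,
        window_weights=weights,
        description=" ".join(description_lines),
    )


def load_scale(name: str = "bnorm-vihinen") -> FlexibilityScale:
    """Load a packaged scale by name (error lists available scales)."""
    if name not in _SCALE_FILES:
        raise UnknownScaleError(
            f"unknown scale {name!r}; available: {', '.join(available_scales())}"
        )
    text = (
        resources.files("vsdflex.data").joinpath(_SCALE_FILES[name]).read_text()
    )
    return _read_scale_text(text, name)


def smooth_profile(seq: str, scale: FlexibilityScale) -> np.ndarray:
    """Neighbour-weighted per-position values.

    Value at i is the weighted average of the raw residue values over
    the window centred at i; at the sequence ends the window is
    truncated and the remaining weights renormalized (so a homopolymer
    maps to a constant profile).  Sentinel/gap positions are dropped
    before smoothing.
    """
    seq = "".join(c for c in seq if c not in (SENTINEL, GAP))
    if not seq:
        raise ValueError("empty sequence (nothing left after sentinel removal)")
    raw = np.array([_residue_value(scale, c) for c in seq])
    half = scale.window_length // 2
    weights = np.asarray(scale.window_weights)
    n = len(raw)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = weights[lo - i + half : hi - i + half]
        out[i] = np.dot(w, raw[lo:hi]) / w.sum()
    return out


def _residue_value(scale: FlexibilityScale, residue: str) -> float:
    try:
        return scale.values[residue]
    except KeyError:
        raise ValueError(f"residue {residue!r} not in scale {scale.name!r}") from None


def mean_bfactor(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic-mean B-factor and the flexibility index 1/mBf."""
    if len(values) == 0:
        raise ValueError("empty value list")
    mbf = float(np.mean(values))
    if mbf <= 0:
        raise ValueError(f"mBf must be positive, got {mbf}")
    return mbf, 1.0 / mbf


def segment_index(seq: str, scale: FlexibilityScale) -> tuple[float, float]:
    """Smoothed mBf and index for one sequence (calibration applied)."""
    values = smooth_profile(seq, scale)
    mbf_raw, _ = mean_bfactor(values)
    mbf = scale.calibrated_mbf(mbf_raw)
    if mbf <= 0:
        raise ValueError("calibrated mBf is non-positive; check the calibration")
    return mbf, 1.0 / mbf


def consensus_weighted_index(
    cs: ConsensusSet,
    windows: SegmentWindows,
    scale: FlexibilityScale,
    segment: str = "s3",
) -> FlexibilityProfile:
    """Flexibility profile of one segment from the ranked consensus.

    The reported index comes from the rank-1 sequence; the dispersion
    is the population standard deviation of the indices of all ranks
    that exist in the window (ranks reduced to sentinels are excluded).
    """
    window = getattr(windows, f"{segment}_window")
    if window is None:
        raise ValueError(f"window {segment!r} is not annotated")
    if window[1] - 1 > cs.length:
        raise ValueError(
            f"window {window} exceeds consensus length {cs.length}"
        )
    rank_indices: list[float] = []
    rank1_values: np.ndarray | None = None
    rank1_mbf: float | None = None
    for r, full_seq in enumerate(cs.sequences):
        sub = windows.subsequence(full_seq, segment)
        if not sub.replace(SENTINEL, ""):
            continue
        values = smooth_profile(sub, scale)
        mbf_raw, _ = mean_bfactor(values)
        mbf = scale.calibrated_mbf(mbf_raw)
        if mbf <= 0:
            raise ValueError("calibrated mBf is non-positive")
        rank_indices.append(1.0 / mbf)
        if r == 0:
            rank1_values = values
            rank1_mbf = mbf
    if rank1_values is None or rank1_mbf is None:
        raise ValueError(
            f"family {cs.family_id!r}: rank-1 consensus empty in segment {segment!r}"
        )
    dispersion = float(np.std(rank_indices)) if len(rank_indices) > 1 else 0.0
    return FlexibilityProfile(
        family_id=cs.family_id,
        segment_name=segment,
        values=tuple(float(v) for v in rank1_values),
        mbf=rank1_mbf,
        index=1.0 / rank1_mbf,
        rank_indices=tuple(rank_indices),
        dispersion=dispersion,
    )


def calibrate_scale(
    scale: FlexibilityScale,
    references: Sequence[tuple[str, float]],
) -> FlexibilityScale:
    """Fit the affine mBf calibration against reference indices.

    ``references`` are ``(sequence, target_index)`` pairs.  Since the
    index is 1/mBf, the fit is an ordinary linear least-squares of
    ``1/target_index`` on the raw smoothed mBf of each sequence —
    deterministic, no iteration.
    """
    if len(references) < 2:
        raise ValueError("need at least two reference sequences to calibrate")
    base = replace(scale, calibration=None)
    x = np.array([mean_bfactor(smooth_profile(seq, base))[0] for seq, _ in references])
    y = np.array([1.0 / target for _, target in references])
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return replace(scale, calibration=(float(slope), float(intercept)))


def load_reference_consensus() -> list[tuple[str, str, float]]:
    """Packaged (family, S3 sequence, reference index) calibration set.

    The sequences are synthetic stand-ins for family S3 consensus
    sequences (see the fixture header); the reference indices are the
    corresponding values of the packaged functional table.
    """
    text = (
        resources.files("vsdflex.data")
        .joinpath("synthetic_s3_consensus.tsv")
        .read_text()
    )
    rows = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    reader = csv.DictReader(io.StringIO("\n".join(rows)), delimiter="\t")
    return [
        (row["family_id"], row["s3_sequence"], float(row["reference_index"]))
        for row in reader
    ]


def load_calibrated_scale(name: str = "bnorm-vihinen") -> FlexibilityScale:
    """Packaged scale with its calibration fitted to the reference set."""
    refs = [(seq, idx) for _, seq, idx in load_reference_consensus()]
    return calibrate_scale(load_scale(name), refs)


# ---------------------------------------------------------------- RSA

def load_rsa_scale() -> dict[str, float]:
    """Mean relative solvent accessibility fractions per residue."""
    text = resources.files("vsdflex.data").joinpath("rsa_mean.tsv").read_text()
    rows = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    reader = csv.DictReader(io.StringIO("\n".join(rows)), delimiter="\t")
    values = {row["residue"]: float(row["value"]) for row in reader}
    for res, val in values.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"RSA value for {res} outside [0, 1]: {val}")
    return values


def rsa_index(seq: str, rsa: Mapping[str, float]) -> float:
    """Mean RSA fraction of a sequence (sentinels/gaps dropped)."""
    seq = "".join(c for c in seq if c not in (SENTINEL, GAP))
    if not seq:
        raise ValueError("empty sequence")
    return float(np.mean([rsa[c] for c in seq]))


# ------------------------------------------------------- classification

def classify_flexibility(
    indices: Mapping[str, float],
    thresholds: tuple[float, float] | str = "tertile",
) -> dict[str, str]:
    """Assign rigid / intermediate / flexible classes.

    Indices follow the larger-is-more-flexible convention.  In
    ``"tertile"`` mode the 1/3 and 2/3 quantiles of the supplied values
    split the families; explicit ``(low, high)`` thresholds are also
    accepted.  A value exactly at a boundary goes to the lower (more
    rigid) class.
    """
    if thresholds == "tertile":
        if len(indices) < 3:
            raise ValueError("tertile mode needs at least 3 families")
        vals = np.array(sorted(indices.values()))
        low, high = float(np.quantile(vals, 1 / 3)), float(np.quantile(vals, 2 / 3))
    else:
        low, high = thresholds
        if not low <= high:
            raise ValueError("thresholds must satisfy low <= high")
    out = {}
    for family, idx in indices.items():
        if idx <= low:
            out[family] = "rigid"
        elif idx <= high:
            out[family] = "intermediate"
        else:
            out[family] = "flexible"
    return out


# ---------------------------------------------------------------- I/O

def write_profile_tsv(
    profiles: Iterable[FlexibilityProfile],
    sequences: Mapping[tuple[str, str], str],
    path: str | Path,
) -> None:
    """Per-position TSV: family, segment, position, residue, smoothed_value."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["family_id", "segment", "position", "residue", "smoothed_value"])
        for prof in profiles:
            seq = sequences.get((prof.family_id, prof.segment_name), "")
            clean = "".join(c for c in seq if c not in (SENTINEL, GAP))
            for i, value in enumerate(prof.values, start=1):
                residue = clean[i - 1] if i <= len(clean) else "?"
                writer.writerow(
                    [prof.family_id, prof.segment_name, i, residue, f"{value:.6g}"]
                )


def write_summary_tsv(
    profiles: Iterable[FlexibilityProfile], path: str | Path
) -> None:
    """Summary TSV: family, segment, mBf, index, dispersion, class."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["family_id", "segment", "mBf", "index", "dispersion", "class"])
        for prof in profiles:
            writer.writerow(
                [
                    prof.family_id,
                    prof.segment_name,
                    f"{prof.mbf:.6g}",
                    f"{prof.index:.6g}",
                    f"{prof.dispersion:.6g}",
                    prof.class_label or "",
                ]
            )
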