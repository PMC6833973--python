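"""Ground-truth generators for every pipeline input.

Aligned families with controlled per-column residue composition and an
implanted anchor motif; toy coordinate files with prescribed
donor-acceptor distances; functional tables with a prescribed
class-trait effect structure.  All generators are pure functions of
their spec and seed.

Sequences are sampled independently from the per-column distributions
(star topology): there is no phylogenetic correlation between rows,
which real family alignments do have.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .msa_consensus import AMINO_ACIDS, Alignment
from .segment_annotation import (
    BUILTIN_PATTERNS,
    MotifPattern,
    SegmentBoundaries,
    SegmentWindows,
    extract_windows,
)
from .flexibility_profile import FlexibilityScale, load_scale

#: Uniform background over the 20 standard residues.
UNIFORM_BACKGROUND: dict[str, float] = {a: 1.0 / 20.0 for a in AMINO_ACIDS}


class SpecError(ValueError):
    """Inconsistent generator specification."""


@dataclass(frozen=True)
class FamilySpec:
    """Specification of one synthetic aligned family.

    Column composition comes either from explicit
    ``column_distributions`` (one residue→probability map per column)
    or from ``region_targets``: ``(start, end, target_mean)`` half-open
    1-based intervals whose columns get a two-residue mixture achieving
    the target mean raw B-value under ``scale_name``.  Motif columns
    are overwritten by the implanted motif residues and are exempt from
    substitution noise.
    """

    family_id: str
    n_sequences: int = 50
    length: int = 60
    column_distributions: tuple[Mapping[str, float], ...] | None = None
    region_targets: tuple[tuple[int, int, float], ...] = ()
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(UNIFORM_BACKGROUND)
    )
    motif: str = "NxxD"
    implant_position: int = 1
    boundaries: SegmentBoundaries | None = None
    noise_rate: float = 0.0
    scale_name: str = "bnorm-vihinen"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 4:
            raise SpecError("need n_sequences >= 1 and length >= 4")
        if not 1 <= self.implant_position <= self.length - 3:
            raise SpecError("implant_position + 4 must fit inside the length")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise SpecError("noise_rate must be in [0, 1]")
        if self.column_distributions is not None:
            if len(self.column_distributions) != self.length:
                raise SpecError("one distribution per column required")
            for j, dist in enumerate(self.column_distributions):
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise SpecError(f"column {j + 1} distribution does not sum to 1")
        for start, end, _ in self.region_targets:
            if not 1 <= start < end <= self.length + 1:
                raise SpecError(f"region ({start}, {end}) outside the alignment")


@dataclass(frozen=True)
class FamilyGroundTruth:
    """What the generator knows: true windows, motif and compositions."""

    family_id: str
    motif_residues: str
    implant_position: int
    windows: SegmentWindows | None
    column_distributions: tuple[dict[str, float], ...]
    region_means: dict[tuple[int, int], float]


def composition_for_target(
    target_mean: float, scale: FlexibilityScale
) -> dict[str, float]:
    """Two-residue mixture whose expected raw B-value equals the target.

    Mixes the most rigid and the most flexible residue of the scale;
    the target must lie between their values.
    """
    rigid = min(scale.values, key=scale.values.get)
    flexible = max(scale.values, key=scale.values.get)
    lo, hi = scale.values[rigid], scale.values[flexible]
    if not lo <= target_mean <= hi:
        raise SpecError(
            f"target mean {target_mean} outside the attainable range [{lo}, {hi}]"
        )
    p = (target_mean - lo) / (hi - lo)
    return {rigid: 1.0 - p, flexible: p} if 0 < p < 1 else (
        {flexible: 1.0} if p >= 1 else {rigid: 1.0}
    )


def _motif_residues(pattern: MotifPattern, background: Mapping[str, float]) -> str:
    """Deterministic motif realization: the alphabetically first residue
    of each constrained position; fully degenerate positions take the
    most probable background residue (ties alphabetical)."""
    out = []
    for pos_set in pattern.position_sets:
        if len(pos_set) == 20:
            out.append(max(sorted(background), key=lambda r: background[r]))
        else:
            out.append(sorted(pos_set)[0])
    return "".join(out)


def generate_family_alignment(
    spec: FamilySpec,
) -> tuple[Alignment, FamilyGroundTruth]:
    """Sample an aligned family with known ground truth.

    Deterministic given the spec (including its seed).  The motif is
    present in every sequence at the implant position; substitution
    noise (replacement by a background draw) never touches the motif
    columns.
    """
    rng = np.random.default_rng(spec.seed)
    scale = load_scale(spec.scale_name)
    pattern = (
        BUILTIN_PATTERNS[spec.motif]
        if isinstance(spec.motif, str)
        else spec.motif
    )

    if spec.column_distributions is not None:
        dists = [dict(d) for d in spec.column_distributions]
    else:
        dists = [dict(spec.background) for _ in range(spec.length)]
        for start, end, target in spec.region_targets:
            mixture = composition_for_target(target, scale)
            for j in range(start - 1, end - 1):
                dists[j] = dict(mixture)

    motif = _motif_residues(pattern, spec.background)
    motif_cols = set(range(spec.implant_position - 1, spec.implant_position + 3))
    for offset, residue in enumerate(motif):
        dists[spec.implant_position - 1 + offset] = {residue: 1.0}

    bg_residues = sorted(spec.background)
    bg_probs = np.array([spec.background[r] for r in bg_residues])
    bg_probs = bg_probs / bg_probs.sum()

    records = []
    for i in range(spec.n_sequences):
        row = []
        for j, dist in enumerate(dists):
            residues = sorted(dist)
            probs = np.array([dist[r] for r in residues])
            res = residues[rng.choice(len(residues), p=probs / probs.sum())]
            if (
                spec.noise_rate > 0
                and j not in motif_cols
                and rng.random() < spec.noise_rate
            ):
                res = bg_residues[rng.choice(len(bg_residues), p=bg_probs)]
            row.append(res)
        records.append((f"{spec.family_id}_{i + 1}", "".join(row)))

    alignment = Alignment(family_id=spec.family_id, records=tuple(records))
    windows = None
    if spec.boundaries is not None:
        windows = extract_windows(
            "?" * spec.length, spec.implant_position, spec.boundaries
        )
    region_means = {
        (start, end): target for start, end, target in spec.region_targets
    }
    truth = FamilyGroundTruth(
        family_id=spec.family_id,
        motif_residues=motif,
        implant_position=spec.implant_position,
        windows=windows,
        column_distributions=tuple(dists),
        region_means=region_means,
    )
    return alignment, truth


# ------------------------------------------------------ toy structures

#: Minimal heavy-atom templates (local coordinates, Å) sufficient for
#: donor/acceptor geometry.  The functional atom sits at the origin.
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "LYS": [
        ("NZ", (0.0, 0.0, 0.0)),
        ("CE", (1.49, 0.0, 0.0)),
        ("CD", (2.25, 1.25, 0.0)),
        ("CA", (4.8, 2.6, 0.3)),
    ],
    "ARG": [
        ("NH1", (0.0, 0.0, 0.0)),
        ("NH2", (1.15, 1.95, 0.0)),
        ("NE", (2.05, -0.25, 0.0)),
        ("CZ", (1.08, 0.65, 0.0)),
        ("CA", (5.2, 1.4, 0.4)),
    ],
    "ASP": [
        ("OD1", (0.0, 0.0, 0.0)),
        ("OD2", (1.05, 1.85, 0.0)),
        ("CG", (0.95, 0.75, 0.0)),
        ("CA", (2.9, 1.1, 0.5)),
    ],
    "GLU": [
        ("OE1", (0.0, 0.0, 0.0)),
        ("OE2", (1.05, 1.85, 0.0)),
        ("CD", (0.95, 0.75, 0.0)),
        ("CA", (3.9, 1.3, 0.5)),
    ],
}

_FUNCTIONAL_ATOM = {"LYS": "NZ", "ARG": "NH1", "ASP": "OD1", "GLU": "OE1"}

_THREE_TO_ONE = {"LYS": "K", "ARG": "R", "ASP": "D", "GLU": "E"}


@dataclass(frozen=True)
class ToyStructureSpec:
    """Donor/acceptor residue pairs at prescribed distances.

    Each pair ``(donor_resname, acceptor_resname, distance)`` is placed
    in its own chain region, the prescribed distance realized between
    the donor and acceptor functional atoms (Lys NZ / Arg NH1 and
    Asp OD1 / Glu OE1).  ``jitter_seed`` randomizes a rigid rotation of
    each placed residue (distances are preserved).
    """

    pairs: tuple[tuple[str, str, float], ...]
    chain: str = "A"
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        for donor, acceptor, dist in self.pairs:
            if donor.upper() not in ("LYS", "ARG"):
                raise SpecError(f"invalid donor residue {donor!r}")
            if acceptor.upper() not in ("ASP", "GLU"):
                raise SpecError(f"invalid acceptor residue {acceptor!r}")
            if dist <= 0:
                raise SpecError("prescribed distances must be positive")


def _axis_rotation(rng: np.random.Generator) -> np.ndarray:
    """Random rotation about the donor→acceptor (x) axis.

    Restricting jitter to this axis keeps every non-functional atom on
    its side of the pair, so the prescribed functional-atom distance
    stays the minimum donor-set/acceptor-set distance.
    """
    theta = rng.uniform(0.0, 2.0 * math.pi)
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def generate_toy_structure(
    spec: ToyStructureSpec, path: str | Path, scale_name: str = "bnorm-vihinen"
) -> Path:
    """Write a toy PDB realizing the prescribed donor-acceptor distances.

    Occupancies are 1.00 and the B-factor column carries the raw
    normalized B-value of the residue (self-documenting).  Re-reading
    the file reproduces each prescribed distance to PDB coordinate
    precision (1e-3 Å).
    """
    scale = load_scale(scale_name)
    rng = np.random.default_rng(spec.jitter_seed)
    structure = gemmi.Structure()
    structure.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain(spec.chain)
    res_seq = 0
    for k, (donor_name, acceptor_name, dist) in enumerate(spec.pairs):
        origin = np.array([40.0 * k, 0.0, 0.0])
        for res_name, offset, flip in (
            (donor_name.upper(), np.zeros(3), -1.0),
            (acceptor_name.upper(), np.array([dist, 0.0, 0.0]), 1.0),
        ):
            res_seq += 1
            residue = gemmi.Residue()
            residue.name = res_name
            residue.seqid = gemmi.SeqId(res_seq, " ")
            rot = _axis_rotation(rng)
            template = _RESIDUE_TEMPLATES[res_name]
            anchor = dict(template)[_FUNCTIONAL_ATOM[res_name]]
            for atom_name, local in template:
                local = (flip * (local[0] - anchor[0]) + anchor[0], local[1], local[2])
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                rel = rot @ (np.array(local) - np.array(anchor))
                xyz = origin + offset + rel
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = scale.values[_THREE_TO_ONE[res_name]]
                residue.add_atom(atom)
            chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    structure.write_pdb(str(path))
    return path


# ---------------------------------------------------- functional tables

#: Index ranges the three classes are drawn from (1/mBf convention,
#: larger = more flexible), matching the span of the packaged fixture.
CLASS_INDEX_RANGES: dict[str, tuple[float, float]] = {
    "rigid": (1.38, 1.50),
    "intermediate": (1.50, 1.62),
    "flexible": (1.62, 1.80),
}


def generate_functional_table(
    trait_probability: Mapping[str, float],
    n_channels: int = 12,
    seed: int = 0,
    monotone_q10: bool = False,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Synthetic channel table with a known class-trait effect.

    Channels are assigned round-robin to the three flexibility classes;
    each channel's index is drawn uniformly from its class range and
    its binary trait from the class probability.  With
    ``monotone_q10`` a strictly decreasing map index → Q10 is added
    (flexible channels get low temperature coefficients).
    """
    for cls, p in trait_probability.items():
        if cls not in CLASS_INDEX_RANGES:
            raise SpecError(f"unknown class {cls!r}")
        if not 0.0 <= p <= 1.0:
            raise SpecError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    classes = list(CLASS_INDEX_RANGES)
    rows = []
    for i in range(n_channels):
        cls = classes[i % len(classes)]
        lo, hi = CLASS_INDEX_RANGES[cls]
        index = float(rng.uniform(lo, hi))
        trait = bool(rng.random() < trait_probability.get(cls, 0.0))
        row = {
            "channel": f"SYN{i + 1}",
            "class": cls,
            "s3_index": index,
            "trait": trait,
        }
        if monotone_q10:
            row["q10_act"] = 40.0 * math.exp(-3.0 * (index - 1.38))
        rows.append(row)
    frame = pd.DataFrame(rows)
    truth = {
        "trait_probability": dict(trait_probability),
        "classes": {r["channel"]: r["class"] for r in rows},
        "monotone_q10": monotone_q10,
    }
    return frame, truth
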