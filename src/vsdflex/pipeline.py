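"""End-to-end orchestration: alignments → consensus → windows →
flexibility → classification → correlation (and optional
charge-transfer-center geometry)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .msa_consensus import (
    build_consensus_set,
    column_profiles,
    read_alignment,
    write_consensus_fasta,
)
from .segment_annotation import (
    BUILTIN_PATTERNS,
    choose_anchor,
    extract_windows,
    find_anchor_motif,
    read_boundaries_tsv,
    write_windows_tsv,
)
from .flexibility_profile import (
    available_scales,
    classify_flexibility,
    consensus_weighted_index,
    load_calibrated_scale,
    load_scale,
    write_summary_tsv,
)
from .functional_correlation import (
    load_functional_table,
    midpoint,
    rank_correlation,
    s3_index_fit,
)

logger = logging.getLogger(__name__)

SEGMENTS = ("s3", "s3s4", "s1s4")


class PipelineError(RuntimeError):
    """A pipeline stage failed."""


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass
class RunConfig:
    alignments_dir: str
    boundaries_tsv: str
    out_dir: str
    functional_table: str | None = None  # None = packaged fixture
    structures_dir: str | None = None
    scale: str = "bnorm-vihinen"
    calibrate: bool = True
    classification: str = "tertile"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Collect every configuration error (no fail-fast)."""
    errors: list[str] = []
    if not Path(config.alignments_dir).is_dir():
        errors.append(f"alignments_dir not found: {config.alignments_dir}")
    if not Path(config.boundaries_tsv).is_file():
        errors.append(f"boundaries_tsv not found: {config.boundaries_tsv}")
    if config.structures_dir is not None and not Path(config.structures_dir).is_dir():
        errors.append(f"structures_dir not found: {config.structures_dir}")
    if (
        config.functional_table is not None
        and not Path(config.functional_table).is_file()
    ):
        errors.append(f"functional_table not found: {config.functional_table}")
    if config.scale not in available_scales():
        errors.append(
            f"unknown scale {config.scale!r}; available: {available_scales()}"
        )
    if config.classification != "tertile":
        errors.append("classification must be 'tertile'")
    return errors


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    Outputs per family: consensus FASTA, windows TSV, per-segment
    flexibility summary; across families: classification, Spearman
    correlation of the S3 index against the gating-charge midpoint,
    and the modified-exponential trend fits.
    """
    errors = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    scale = (
        load_calibrated_scale(config.scale)
        if config.calibrate
        else load_scale(config.scale)
    )
    boundaries = read_boundaries_tsv(config.boundaries_tsv)

    alignment_paths = sorted(
        p
        for p in Path(config.alignments_dir).iterdir()
        if p.suffix.lower() in (".fasta", ".fa", ".aln", ".clustal")
    )
    if not alignment_paths:
        raise PipelineError(f"no alignments found in {config.alignments_dir}")

    profiles = []
    sequences: dict[tuple[str, str], str] = {}
    windows_out = []
    manifest_families = []
    for path in alignment_paths:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal") else "fasta"
        aln = read_alignment(path, fmt)
        family = aln.family_id
        if family not in boundaries:
            raise PipelineError(f"family {family!r} missing from boundaries TSV")
        bounds = boundaries[family]
        cols = column_profiles(aln)
        consensus = build_consensus_set(cols, family_id=family)
        write_consensus_fasta(consensus, out_dir / f"{family}.consensus.fasta")
        pattern = BUILTIN_PATTERNS.get(bounds.motif_variant)
        patterns = [pattern] if pattern else None
        matches = find_anchor_motif(consensus.rank1, patterns)
        anchor = choose_anchor(matches, bounds)
        windows = extract_windows(consensus.rank1, anchor, bounds)
        windows_out.append(windows)
        for segment in SEGMENTS:
            if getattr(windows, f"{segment}_window") is None:
                continue
            prof = consensus_weighted_index(consensus, windows, scale, segment)
            profiles.append(prof)
            sequences[(family, segment)] = windows.subsequence(
                consensus.rank1, segment
            )
        manifest_families.append(
            {"family_id": family, "n_sequences": aln.n_sequences, "anchor": anchor}
        )

    write_windows_tsv(windows_out, out_dir / "windows.tsv")

    s3_indices = {
        p.family_id: p.index for p in profiles if p.segment_name == "s3"
    }
    classes = (
        classify_flexibility(s3_indices)
        if len(s3_indices) >= 3
        else {f: "" for f in s3_indices}
    )
    profiles = [
        dataclasses.replace(p, class_label=classes.get(p.family_id))
        for p in profiles
    ]
    write_summary_tsv(profiles, out_dir / "flexibility_summary.tsv")

    functional = (
        load_functional_table()
        if config.functional_table is None
        else load_functional_table(table1=config.functional_table)
    )
    # join against the voltage/temperature table; the stretch table may
    # repeat channels with separately transcribed indices
    table1 = [r for r in functional if r.source_table != "table2"]
    joined = [
        (s3_indices[fam], midpoint(rec.charge_e0))
        for fam in s3_indices
        for rec in table1
        if rec.key == fam and rec.charge_e0 is not None
    ]
    correlation_report: dict[str, object] = {"n_joined": len(joined)}
    if len(joined) >= 3:
        rho, p_value = rank_correlation(joined, seed=config.seed)
        correlation_report.update({"spearman_rho": rho, "p_value": p_value})
    fit_report = {}
    try:
        for variant in ("rank", "charge"):
            fit = s3_index_fit(functional, x_variable=variant)
            fit_report[variant] = {
                "a": fit.a, "b": fit.b, "c": fit.c,
                "r_squared": fit.r_squared, "n_points": fit.n_points,
            }
    except Exception as exc:  # fit is reported, never fatal
        fit_report["error"] = str(exc)
    correlation_report["modified_exponential_fit"] = fit_report
    with open(out_dir / "correlation_report.json", "w") as fh:
        json.dump(correlation_report, fh, indent=2)

    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "scale": scale.name,
        "calibration": scale.calibration,
        "families": manifest_families,
        "n_profiles": len(profiles),
        "join_count": len(joined),
        "outputs": sorted(
            p.name for p in out_dir.iterdir() if p.name != "manifest.json"
        ),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
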