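"""End-to-end pipeline: inputs -> footprints -> A-sites -> pause/metagene/reporter.

All stage parameters default to the published analysis values (A-site
offsets 16/15/14 by length, 20-22 and 27-29 nt classes, inclusive 0.5
footprints/codon ORF filter, five excluded codons per ORF end, >= 6 K/R
in a 10-residue polybasic window).  Every run writes its artifacts as
TSV/JSON under an output directory plus a machine-readable run report
recording parameters and per-stage counts; outputs carry no timestamps
so identical configurations produce identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .asite import DEFAULT_OFFSETS, CLASSES, map_asites
from .metagene import KR_WINDOW, MIN_KR, METAGENE_WINDOW, detect_all, metagene_profile
from .orfs import orf_index, read_orfs
from .pause import (
    EDGE_EXCLUDE,
    MIN_DENSITY,
    MIN_OCCURRENCES,
    build_density_profiles,
    combine_classes,
    dicodon_scores,
    filter_orfs,
    pause_score_table,
)
from .preprocess import (
    ExactMatchMapper,
    dedup,
    extract_umi_and_trim,
    read_sam,
    read_truth_tsv,
    restrict_lengths,
)
from .reporter import BOUNDARY_FLANK, ReporterModel, readthrough_index, reporter_occupancy


class ConfigError(Exception):
    """Invalid configuration or missing input files (exit code 2)."""


class DataError(Exception):
    """Malformed input data (exit code 1)."""


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    transcriptome_fasta: str
    orf_table: str
    out_dir: str
    # exactly one read source: raw FASTQ, alignment TSV, or SAM
    reads_fastq: str | None = None
    alignments_tsv: str | None = None
    alignments_sam: str | None = None
    # reporter (optional)
    segments_tsv: str | None = None
    reporter_transcript: str | None = None
    reporter_insert: str | None = None
    # preprocessing
    linker_sequence: str = "ATCGT" + "TGATCGGAAGAGCACACGTCTGAA"
    umi_length: int = 7
    min_overlap: int = 6
    dedup_before_length_filter: bool = True
    # analysis parameters (published defaults)
    offsets: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    min_density: float = MIN_DENSITY
    edge_exclude: int = EDGE_EXCLUDE
    combined_class_density: bool = False
    min_occurrences: int = MIN_OCCURRENCES
    top_n: int = 10
    min_kr: int = MIN_KR
    kr_window: int = KR_WINDOW
    metagene_window: int = METAGENE_WINDOW
    boundary_flank: int = BOUNDARY_FLANK
    seed: int = 0

    def validate(self) -> None:
        sources = [self.reads_fastq, self.alignments_tsv, self.alignments_sam]
        if sum(s is not None for s in sources) != 1:
            raise ConfigError(
                "exactly one of reads_fastq / alignments_tsv / alignments_sam is required"
            )
        for label, path in [
            ("transcriptome_fasta", self.transcriptome_fasta),
            ("orf_table", self.orf_table),
            ("reads", next(s for s in sources if s is not None)),
        ]:
            if not Path(path).exists():
                raise ConfigError(f"{label} not found: {path}")
        if self.segments_tsv is not None:
            if not Path(self.segments_tsv).exists():
                raise ConfigError(f"segments_tsv not found: {self.segments_tsv}")
            if not (self.reporter_transcript and self.reporter_insert):
                raise ConfigError(
                    "segments_tsv requires reporter_transcript and reporter_insert"
                )
        if set(self.offsets) != set(DEFAULT_OFFSETS):
            raise ConfigError(
                f"offset table must cover exactly lengths {sorted(DEFAULT_OFFSETS)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "offsets" in raw:
            cfg.offsets = {int(k): int(v) for k, v in raw["offsets"].items()}
        return cfg


def _load_footprints(config: PipelineConfig, orfs) -> tuple[pd.DataFrame, dict[str, Any]]:
    counts: dict[str, Any] = {}
    if config.reads_fastq is not None:
        trim = extract_umi_and_trim(
            config.reads_fastq,
            config.linker_sequence,
            umi_length=config.umi_length,
            min_overlap=config.min_overlap,
        )
        counts["trim"] = trim.counts
        mapper = ExactMatchMapper(orfs)
        footprints, map_counts = mapper.map_reads(trim.kept)
        counts["map"] = map_counts
    elif config.alignments_tsv is not None:
        footprints = read_truth_tsv(config.alignments_tsv)
        counts["aligned_input"] = len(footprints)
    else:
        footprints = read_sam(config.alignments_sam)
        counts["aligned_input"] = len(footprints)
    return footprints, counts


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage, write artifacts under ``config.out_dir``, return the report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "parameters": _jsonable(asdict(config)),
        "counts": {},
    }

    try:
        orfs = read_orfs(config.transcriptome_fasta, config.orf_table)
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    index = orf_index(orfs)
    report["counts"]["orfs"] = len(orfs)

    footprints, load_counts = _load_footprints(config, orfs)
    report["counts"].update(load_counts)

    if config.dedup_before_length_filter:
        deduped = dedup(footprints)
        restricted, length_counts = restrict_lengths(deduped)
    else:
        restricted0, length_counts = restrict_lengths(footprints)
        restricted = dedup(restricted0)
    report["counts"]["dedup_removed"] = len(footprints) - len(dedup(footprints))
    report["counts"]["length_filter"] = length_counts
    restricted.to_csv(out / "footprints.tsv", sep="\t", index=False)

    calls = map_asites(restricted, index, offsets=config.offsets)
    report["counts"]["asite_out_of_cds"] = int((~calls["in_cds"]).sum())
    calls.to_csv(out / "asite_calls.tsv", sep="\t", index=False)

    profiles, excluded = build_density_profiles(calls, index, config.edge_exclude)
    if config.combined_class_density:
        profiles = combine_classes(profiles)
    report["counts"]["orfs_no_interior"] = excluded
    retained = filter_orfs(profiles, config.min_density)
    report["counts"]["profiles_retained"] = {
        cls: sum(1 for (_, c) in retained if c == cls) for cls in CLASSES
    }

    scores = pause_score_table(retained)
    scores.to_csv(out / "pause_scores.tsv", sep="\t", index=False)
    table = dicodon_scores(retained, index)
    table.summary(config.min_occurrences).to_csv(out / "dicodon_scores.tsv", sep="\t", index=False)
    for cls in CLASSES:
        table.rank(cls, config.top_n, config.min_occurrences).to_csv(
            out / f"top_dicodons_{cls}.tsv", sep="\t", index=False
        )

    tracts, skipped = detect_all(orfs, config.min_kr, config.kr_window)
    report["counts"]["polybasic_tracts"] = len(tracts)
    report["counts"]["untranslatable_skipped"] = skipped
    pd.DataFrame(
        [(t.transcript_id, t.start_codon_index, t.kr_count_in_window) for t in tracts],
        columns=["transcript_id", "start_codon_index", "kr_count_in_window"],
    ).to_csv(out / "polybasic_tracts.tsv", sep="\t", index=False)
    meta_frames = []
    for cls in CLASSES:
        prof = metagene_profile(retained, tracts, cls, config.metagene_window)
        meta_frames.append(prof.to_frame())
        report["counts"][f"metagene_tracts_{cls}"] = prof.n_tracts
    pd.concat(meta_frames, ignore_index=True).to_csv(
        out / "metagene.tsv", sep="\t", index=False
    )

    if config.segments_tsv is not None:
        model = ReporterModel.from_tsv(
            config.segments_tsv, config.reporter_transcript, config.reporter_insert
        )
        orf = index.get(model.transcript_id)
        if orf is None:
            raise DataError(f"reporter transcript {model.transcript_id!r} not in ORF table")
        occ = reporter_occupancy(calls, model, orf.codon_count)
        occ.to_frame().to_csv(out / "reporter_occupancy.tsv", sep="\t", index=False)
        index_report = {
            "readthrough_index": readthrough_index(occ, model, flank=config.boundary_flank),
            "peaks": {cls: sorted(occ.peak(cls)) for cls in CLASSES},
        }
        with open(out / "readthrough.json", "w") as fh:
            json.dump(index_report, fh, indent=2)
        report["reporter"] = index_report

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
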