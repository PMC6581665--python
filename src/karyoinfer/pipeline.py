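"""End-to-end pipelines and the serialisable run report.

Chains the per-module operations into the two standard analyses:

* karyotype pipeline: summaries (from raw measurements or a summary
  table) → homolog matching → fusion-candidate detection → hybrid
  prediction;
* sequence pipeline: FASTA + clade map → p-distance matrix →
  within/between-clade summary → NUMT translation screen.

Reports are plain dicts serialised to versioned JSON so a run is fully
described by its own output (config echo included).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

from . import __version__
from .errors import ComputationError, ValidationError
from .morphometrics import (KaryotypeProfile, read_karyotype_summaries,
                            read_measurements, summarize_karyotype,
                            write_karyotype_summaries)
from .rearrangement import (DEFAULT_THRESHOLD, detect_fusion_candidates,
                            match_homologs, predict_hybrid)
from .seqdist import (best_reading_frame, clade_summary, distance_matrix,
                      read_clade_map, read_fasta, translate_and_screen,
                      write_distance_matrix)
from .synthetic import DEFAULT_SEED

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

REFERENCE_SUMMARIES = "wasp_karyotype_summaries.tsv"


@dataclass
class PipelineConfig:
    """Configuration shared by the pipelines; echoed verbatim in reports."""

    karyotype_inputs: tuple[str, ...] = ()
    input_kind: str = "summary"  # "summary" | "measurements"
    fasta: str | None = None
    clade_map: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = 0.05
    deletion: str = "pairwise"
    merge_submetacentric: bool = True
    seed: int = DEFAULT_SEED
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.input_kind not in ("summary", "measurements"):
            raise ValidationError(f"unknown input_kind {self.input_kind!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["karyotype_inputs"] = list(self.karyotype_inputs)
        return d


def load_reference_karyotypes() -> dict[str, KaryotypeProfile]:
    """The packaged published summaries for the two wasp karyotypes
    (ids ``n5`` and ``n6``)."""
    with resources.as_file(
            resources.files("karyoinfer.data") / REFERENCE_SUMMARIES) as path:
        return read_karyotype_summaries(path)


def _load_profiles(config: PipelineConfig) -> list[KaryotypeProfile]:
    profiles: list[KaryotypeProfile] = []
    for path in config.karyotype_inputs:
        p = Path(path)
        if not p.exists():
            raise ValidationError(f"input file not found: {p}")
        if config.input_kind == "summary":
            profiles.extend(read_karyotype_summaries(p).values())
        else:
            plates = read_measurements(p)
            profiles.append(summarize_karyotype(
                plates, karyotype_id=p.stem,
                merge_submetacentric=config.merge_submetacentric))
    return profiles


def run_karyotype_pipeline(config: PipelineConfig) -> dict:
    """Summaries → matching → fusion candidates → hybrid, as one report.

    Needs exactly two karyotypes.  When haploid numbers are equal the
    fusion stage is skipped with a warning (event direction undefined);
    otherwise the lower-n karyotype is treated as the putative fusion
    carrier.
    """
    warnings: list[str] = []
    profiles = _load_profiles(config)
    if len(profiles) != 2:
        raise ValidationError(f"karyotype pipeline needs exactly 2 karyotypes, "
                              f"got {len(profiles)}")
    a, b = profiles
    if a.haploid_number > b.haploid_number:
        a, b = b, a  # a: lower (or equal) haploid number

    matching = match_homologs(a, b, threshold=config.threshold)
    candidates = []
    if a.haploid_number == b.haploid_number:
        warnings.append("equal haploid numbers: fusion/fission stage skipped")
    else:
        try:
            candidates = detect_fusion_candidates(a, b, matching, alpha=config.alpha)
        except ComputationError as exc:
            warnings.append(f"fusion stage skipped: {exc}")
    hybrid = predict_hybrid(a, b, matching)

    report = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "config": config.to_dict(),
        "karyotypes": {
            p.karyotype_id: {
                "haploid_number": p.haploid_number,
                "chromosomes": [asdict(c) for c in p.chromosomes],
            } for p in (a, b)
        },
        "matching": matching.to_dict(),
        "fusion_candidates": [c.to_dict() for c in candidates],
        "hybrid": hybrid.to_dict(),
        "warnings": warnings,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_karyotype_summaries((a, b), out / "karyotype_summaries.tsv")
        (out / "karyotype_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_seqdist_pipeline(config: PipelineConfig) -> dict:
    """Distance matrix, clade summary and NUMT screen, as one report."""
    if not config.fasta:
        raise ValidationError("seqdist pipeline needs a FASTA input")
    fasta = Path(config.fasta)
    if not fasta.exists():
        raise ValidationError(f"input file not found: {fasta}")
    seqs = read_fasta(fasta)
    matrix = distance_matrix(seqs, deletion=config.deletion)

    warnings: list[str] = []
    summary = None
    if config.clade_map:
        cm_path = Path(config.clade_map)
        if not cm_path.exists():
            raise ValidationError(f"input file not found: {cm_path}")
        clades = read_clade_map(cm_path)
        summary = clade_summary(matrix, clades)
    elif len(seqs) > 1:
        warnings.append("no clade map supplied: distance matrix only")

    screen = {}
    for sid, seq in zip(seqs.ids, seqs.sequences):
        frame = best_reading_frame(seq)
        _, flags = translate_and_screen(seq, frame)
        screen[sid] = {"frame": frame, **flags.to_dict()}
        if flags.internal_stops:
            warnings.append(
                f"{sid}: internal stop codon(s) at codon(s) "
                f"{list(flags.internal_stops)} in best frame {frame} — possible NUMT")

    report = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "config": config.to_dict(),
        "n_sequences": len(seqs),
        "alignment_length": seqs.alignment_length,
        "clade_summary": summary.to_dict() if summary else None,
        "numt_screen": screen,
        "warnings": warnings,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_distance_matrix(matrix, out / "p_distances.tsv")
        (out / "seqdist_report.json").write_text(json.dumps(report, indent=2))
    report["matrix"] = matrix.to_dict()
    return report


def report_roundtrip(report: dict) -> bool:
    """True if the report survives JSON serialisation losslessly (i.e. every
    value is JSON-representable without coercion)."""
    return json.loads(json.dumps(report)) == report
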