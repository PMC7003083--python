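"""End-to-end orchestration: filter -> assign -> map -> classify -> report.

`run_all` is the library entry point behind the ``run-all`` CLI
subcommand; it consumes in-memory objects so tests and the synthetic
generator can drive it without touching disk.  `invoke_external` is the
optional thin hook for running a user-declared search/mapping command;
the pipeline is fully functional on precomputed files.
"""

from __future__ import annotations

import hashlib
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .io_formats import HitRecord, MappingRecord, dataclass_to_dict
from .model import TaxonomyMap, Thresholds, XenocdsError
from .reporting import AssemblyReport, summarize
from .synteny_classification import (ScaffoldTable, break_at_gaps,
                                     build_scaffold_table, classify_foreign)
from .taxonomic_assignment import CdsAnnotation, assign_all

log = logging.getLogger(__name__)


@dataclass
class RunRecord:
    """Provenance of one run: checksums, thresholds, per-stage counts.

    Identical inputs and config yield an identical record, so the file is
    reproducible byte-for-byte; wall-clock timing goes to the log stream
    only.
    """

    input_checksums: Dict[str, str] = field(default_factory=dict)
    thresholds: Optional[Dict] = None
    tool_versions: Dict[str, str] = field(default_factory=dict)
    stage_counts: Dict[str, int] = field(default_factory=dict)


@dataclass
class PipelineResult:
    annotations: List[CdsAnnotation]
    table: ScaffoldTable
    report: AssemblyReport
    run_record: RunRecord


def run_all(
    scaffolds: Mapping[str, str],
    cds: Mapping[str, str],
    hits: Sequence[HitRecord],
    taxonomy: TaxonomyMap,
    mappings: Sequence[MappingRecord],
    thresholds: Thresholds = Thresholds(),
    gene_of: Optional[Mapping[str, str]] = None,
    contig_scale: bool = False,
    gap_run: int = 10,
) -> PipelineResult:
    """Run the full annotation pipeline on one assembly.

    Stages: input filters; similarity-based stage-1 assignment (CDS
    without hits become orphans); synteny-based stage-2 classification of
    foreign candidates; per-assembly summary.  With ``contig_scale`` the
    synteny stage runs on contigs obtained by breaking scaffolds at runs
    of >= ``gap_run`` ambiguous bases.
    """
    from .io_formats import filter_inputs

    kept_scaffolds, kept_cds = filter_inputs(scaffolds, cds, gene_of, thresholds)
    log.info("input filter: %d/%d scaffolds, %d/%d CDS kept",
             len(kept_scaffolds), len(scaffolds), len(kept_cds), len(cds))

    annotations = assign_all(hits, list(kept_cds), taxonomy, thresholds)

    scaffold_lengths = {sid: len(s) for sid, s in kept_scaffolds.items()}
    eff_mappings: Sequence[MappingRecord] = mappings
    if contig_scale:
        eff_mappings, scaffold_lengths = break_at_gaps(
            kept_scaffolds, mappings, gap_run=gap_run)

    table = build_scaffold_table(annotations, eff_mappings, thresholds)
    annotations = classify_foreign(annotations, table)
    report = summarize(annotations, table, scaffold_lengths)

    record = RunRecord(
        thresholds=dataclass_to_dict(thresholds),
        stage_counts={
            "scaffolds_in": len(scaffolds),
            "scaffolds_kept": len(kept_scaffolds),
            "cds_in": len(cds),
            "cds_kept": len(kept_cds),
            "hits_in": len(hits),
            "mapped_cds": len(table.cds_scaffolds),
            "foreign_candidates": report.n_foreign,
        },
    )
    return PipelineResult(annotations=annotations, table=table,
                          report=report, run_record=record)


def checksum_files(paths: Mapping[str, str]) -> Dict[str, str]:
    out = {}
    for name, p in sorted(paths.items()):
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        out[name] = h.hexdigest()
    return out


def invoke_external(
    tool: str,
    command_template: str,
    substitutions: Mapping[str, str],
    version_command: Optional[str] = None,
) -> Tuple[str, str]:
    """Run a user-declared external search/mapping command.

    ``command_template`` uses ``{in}``/``{out}``-style placeholders
    rendered verbatim from ``substitutions``.  Returns (captured stdout,
    version string).  A missing binary produces a clear error suggesting
    precomputed-file mode; a nonzero exit propagates with the tool's
    stderr.
    """
    if tool not in ("search", "map"):
        raise XenocdsError(f"unknown external tool role {tool!r}")
    try:
        command = command_template.format(**substitutions)
    except KeyError as exc:
        raise XenocdsError(f"unfilled placeholder in command template: {exc}") from None
    binary = command.split()[0]
    if shutil.which(binary) is None:
        raise XenocdsError(
            f"external {tool} tool {binary!r} not found on PATH; "
            "run it yourself and supply its output via the precomputed-file flags")
    version = ""
    if version_command:
        vp = subprocess.run(version_command.split(), capture_output=True, text=True)
        version = (vp.stdout or vp.stderr).strip().splitlines()[0] if (vp.stdout or vp.stderr) else ""
    proc = subprocess.run(command.split(), capture_output=True, text=True)
    if proc.returncode != 0:
        raise XenocdsError(
            f"external {tool} command failed (exit {proc.returncode}): {proc.stderr.strip()}")
    return proc.stdout, version
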