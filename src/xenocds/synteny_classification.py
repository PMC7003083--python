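"""Stage 2: scaffold co-localization splits foreign candidates into
HGT candidates, contaminant candidates and uncertain.

Only foreign candidates and confident-resident CDS are mapped onto the
assembly.  Mappings must reach 100 bp aligned length and 95% identity.  A
foreign candidate is

* an HGT candidate if any of its scaffolds carries the resident tag
  (seeded by a mapped confident-resident CDS and propagated across
  scaffolds linked by chimeric alignments);
* a contaminant candidate if some scaffold of its carries at least one
  *other* mapped foreign CDS (of any group — a mixed-origin scaffold still
  counts, and is later surfaced by the consistency test);
* uncertain otherwise (unmapped, or the sole mapped CDS on its scaffolds).

A chimeric CDS cannot corroborate itself: its second chimeric part never
counts as the "other" CDS for the contaminant rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .io_formats import MappingRecord
from .model import Stage1, Stage2, Thresholds, XenocdsError
from .taxonomic_assignment import CdsAnnotation

log = logging.getLogger(__name__)


@dataclass
class ScaffoldTable:
    """Scaffold -> mapped CDS index with chimera links and resident tags."""

    members: Dict[str, List[Tuple[str, Stage1]]] = field(default_factory=dict)
    chimera_links: Set[FrozenSet[str]] = field(default_factory=set)
    arthropod_tagged: Set[str] = field(default_factory=set)
    cds_scaffolds: Dict[str, Tuple[str, ...]] = field(default_factory=dict)

    def foreign_cds_on(self, scaffold_id: str) -> List[str]:
        return [cid for cid, s1 in self.members.get(scaffold_id, [])
                if s1 is Stage1.FOREIGN]


def build_scaffold_table(
    annotations: Sequence[CdsAnnotation],
    mappings: Sequence[MappingRecord],
    thresholds: Thresholds,
) -> ScaffoldTable:
    """Index surviving mappings by scaffold and propagate the resident tag.

    Mappings below the length/identity floor are dropped.  Only CDS whose
    stage-1 category is foreign or confident-resident enter the table
    (those are the only ones mapped); a mapping for a CDS absent from the
    annotations is ignored with a warning.  The resident tag is seeded on
    every scaffold holding a mapped confident-resident CDS and closed over
    the connected components of the chimera-link graph.
    """
    t = thresholds
    stage1_of = {a.cds_id: a.stage1 for a in annotations}
    table = ScaffoldTable()

    surviving: Dict[str, List[MappingRecord]] = {}
    for rec in mappings:
        if rec.aln_len_bp < t.min_map_len_bp or rec.identity_pct < t.min_map_identity_pct:
            continue
        s1 = stage1_of.get(rec.cds_id)
        if s1 is None:
            log.warning("mapping for unannotated CDS %s ignored", rec.cds_id)
            continue
        if s1 not in (Stage1.FOREIGN, Stage1.CONFIDENT_ARTHROPOD):
            continue
        surviving.setdefault(rec.cds_id, []).append(rec)

    for cds_id in sorted(surviving):
        recs = sorted(surviving[cds_id], key=lambda r: r.part_index)
        scaffolds = []
        for rec in recs:
            if rec.scaffold_id not in scaffolds:
                scaffolds.append(rec.scaffold_id)
            table.members.setdefault(rec.scaffold_id, []).append(
                (cds_id, stage1_of[cds_id]))
        table.cds_scaffolds[cds_id] = tuple(scaffolds)
        if len(scaffolds) >= 2:
            for i in range(len(scaffolds) - 1):
                table.chimera_links.add(frozenset((scaffolds[i], scaffolds[i + 1])))

    # de-duplicate a chimeric CDS listed twice on one scaffold
    for sid in table.members:
        seen = set()
        dedup = []
        for item in table.members[sid]:
            if item[0] not in seen:
                seen.add(item[0])
                dedup.append(item)
        table.members[sid] = dedup

    seeds = {sid for sid, items in table.members.items()
             if any(s1 is Stage1.CONFIDENT_ARTHROPOD for _, s1 in items)}
    graph = nx.Graph()
    graph.add_nodes_from(seeds)
    for pair in table.chimera_links:
        a, b = tuple(pair) if len(pair) == 2 else (next(iter(pair)),) * 2
        graph.add_edge(a, b)
    tagged: Set[str] = set()
    for component in nx.connected_components(graph):
        if component & seeds:
            tagged |= component
    table.arthropod_tagged = tagged
    return table


def classify_foreign(
    annotations: Sequence[CdsAnnotation],
    table: ScaffoldTable,
) -> List[CdsAnnotation]:
    """Attach the stage-2 label to every annotation.

    Foreign candidates get exactly one of hgt_candidate /
    contaminant_candidate / uncertain; everything else gets
    not_applicable.  Scaffold ids of surviving mappings are recorded on
    the annotation for reporting.
    """
    out = []
    for a in annotations:
        scaffolds = table.cds_scaffolds.get(a.cds_id, ())
        if a.stage1 is not Stage1.FOREIGN:
            out.append(replace(a, scaffolds=scaffolds))
            continue
        if not scaffolds:
            label = Stage2.UNCERTAIN
        elif any(s in table.arthropod_tagged for s in scaffolds):
            label = Stage2.HGT_CANDIDATE
        elif any(other != a.cds_id
                 for s in scaffolds for other in table.foreign_cds_on(s)):
            label = Stage2.CONTAMINANT_CANDIDATE
        else:
            label = Stage2.UNCERTAIN
        out.append(replace(a, stage2=label, scaffolds=scaffolds))
    return out


def table_from_annotations(annotations: Sequence[CdsAnnotation]) -> ScaffoldTable:
    """Rebuild the scaffold index from classified annotations.

    The annotation TSV records the surviving scaffolds of every mapped
    CDS, which is enough to reconstruct membership, chimera links and
    resident tags — so downstream commands (consistency, report) can run
    from the annotation file alone.
    """
    table = ScaffoldTable()
    for a in annotations:
        if not a.scaffolds or a.stage1 not in (Stage1.FOREIGN, Stage1.CONFIDENT_ARTHROPOD):
            continue
        table.cds_scaffolds[a.cds_id] = a.scaffolds
        for sid in a.scaffolds:
            table.members.setdefault(sid, []).append((a.cds_id, a.stage1))
        for i in range(len(a.scaffolds) - 1):
            table.chimera_links.add(frozenset((a.scaffolds[i], a.scaffolds[i + 1])))
    seeds = {sid for sid, items in table.members.items()
             if any(s1 is Stage1.CONFIDENT_ARTHROPOD for _, s1 in items)}
    graph = nx.Graph()
    graph.add_nodes_from(seeds)
    for pair in table.chimera_links:
        nodes = tuple(pair)
        if len(nodes) == 2:
            graph.add_edge(*nodes)
    tagged: Set[str] = set()
    for component in nx.connected_components(graph):
        if component & seeds:
            tagged |= component
    table.arthropod_tagged = tagged
    return table


# --------------------------------------------------------------------------
# In-silico fragmentation
# --------------------------------------------------------------------------

def fragment_assembly(
    mappings: Sequence[MappingRecord],
    scaffold_lengths: Mapping[str, int],
    split_factor: int,
    seed: int = 0,
) -> Tuple[List[MappingRecord], Dict[str, int]]:
    """Split every scaffold into ``split_factor`` pieces.

    Each scaffold's mapped CDS records, ordered by start coordinate, are
    partitioned into ``split_factor`` contiguous chunks assigned to new
    scaffold ids ``<sid>|frag<j>``; scaffold lengths are divided into
    near-equal pieces.  Chunk boundaries at indices ``i*n//f`` make the
    partitions nested across factors that divide each other, so repeated
    halving refines (never re-merges) earlier splits.  ``split_factor=1``
    is the identity.  Deterministic; ``seed`` is accepted for interface
    uniformity but the partition involves no randomness.
    """
    if split_factor < 1:
        raise XenocdsError(f"split_factor must be >= 1, got {split_factor}")
    if split_factor == 1:
        return list(mappings), dict(scaffold_lengths)

    by_scaffold: Dict[str, List[MappingRecord]] = {}
    for rec in mappings:
        by_scaffold.setdefault(rec.scaffold_id, []).append(rec)

    new_mappings: List[MappingRecord] = []
    new_lengths: Dict[str, int] = {}
    f = split_factor
    for sid in sorted(set(scaffold_lengths) | set(by_scaffold)):
        length = scaffold_lengths.get(sid, 0)
        piece = length // f
        for j in range(f):
            frag_id = f"{sid}|frag{j}"
            new_lengths[frag_id] = piece + (length - piece * f if j == f - 1 else 0)
        recs = sorted(by_scaffold.get(sid, []),
                      key=lambda r: (r.start, r.end, r.cds_id, r.part_index))
        n = len(recs)
        for j in range(f):
            lo, hi = j * n // f, (j + 1) * n // f
            for rec in recs[lo:hi]:
                new_mappings.append(replace(rec, scaffold_id=f"{sid}|frag{j}"))
    return new_mappings, new_lengths


# --------------------------------------------------------------------------
# Contig-scale mode
# --------------------------------------------------------------------------

def break_at_gaps(
    scaffolds: Mapping[str, str],
    mappings: Sequence[MappingRecord],
    gap_run: int = 10,
) -> Tuple[List[MappingRecord], Dict[str, int]]:
    """Re-run classification inputs at contig scale.

    Scaffolds are broken at runs of at least ``gap_run`` ambiguous bases
    (N/n); mappings are reassigned to the contig containing their start
    coordinate, with coordinates shifted accordingly.  Useful when the
    scaffolding itself is in doubt; expected to push more foreign
    candidates into the uncertain class.
    """
    import re

    if gap_run < 1:
        raise XenocdsError("gap_run must be >= 1")
    pattern = re.compile(f"[Nn]{{{gap_run},}}")
    contig_spans: Dict[str, List[Tuple[str, int, int]]] = {}
    lengths: Dict[str, int] = {}
    for sid, seq in scaffolds.items():
        spans = []
        prev = 0
        idx = 0
        for m in pattern.finditer(seq):
            if m.start() > prev:
                spans.append((f"{sid}|ctg{idx}", prev + 1, m.start()))
                idx += 1
            prev = m.end()
        if len(seq) > prev:
            spans.append((f"{sid}|ctg{idx}", prev + 1, len(seq)))
        contig_spans[sid] = spans
        for cid, lo, hi in spans:
            lengths[cid] = hi - lo + 1

    new_mappings = []
    for rec in mappings:
        spans = contig_spans.get(rec.scaffold_id)
        if spans is None:
            new_mappings.append(rec)
            continue
        for cid, lo, hi in spans:
            if lo <= rec.start <= hi:
                new_mappings.append(replace(
                    rec, scaffold_id=cid,
                    start=rec.start - lo + 1,
                    end=min(rec.end, hi) - lo + 1))
                break
    return new_mappings, lengths
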