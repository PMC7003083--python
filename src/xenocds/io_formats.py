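"""Readers and writers for the external formats the pipeline touches.

Covered here: FASTA (scaffolds, CDS) through Biopython; the 12-column
tabular protein-search output ("outfmt 6" layout) that stage 1 consumes;
three CDS-to-scaffold mapping dialects (GFF3, PAF, and a normalized
internal TSV); the annotation TSV + JSON sidecar the pipeline writes; and
the assembly input pre-filters (short scaffolds, short CDS, longest
transcript per gene).

Coordinates are 1-based inclusive everywhere internally.  GFF3 is already
1-based and passes through unchanged; PAF is 0-based half-open and is
shifted on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .model import TaxonomyMap, TaxonomyError, Thresholds, XenocdsError

log = logging.getLogger(__name__)


class ParseError(XenocdsError):
    """A malformed input file; the message carries file and line number."""


# --------------------------------------------------------------------------
# Records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    """One protein-similarity hit of a translated CDS against the reference set."""

    query_id: str
    subject_id: str
    subject_species: str
    identity_pct: float
    aln_len: int
    evalue: float
    bitscore: float

    @property
    def rank_key(self):
        """Sort key: ascending E-value, ties by bitscore desc then subject id."""
        return (self.evalue, -self.bitscore, self.subject_id)


@dataclass(frozen=True)
class MappingRecord:
    """One CDS placement on a scaffold, 1-based inclusive coordinates.

    ``part_index`` is 1 for ordinary alignments; a chimeric CDS (5' and 3'
    ends on different scaffolds) contributes a part 1 and a part 2 record.
    """

    cds_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    aln_len_bp: int
    identity_pct: float
    part_index: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ParseError(
                f"mapping of {self.cds_id}: end {self.end} < start {self.start}")
        if self.strand not in "+-":
            raise ParseError(f"mapping of {self.cds_id}: bad strand {self.strand!r}")


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercased sequence mapping.

    Duplicate record ids are an error; an empty file yields an empty
    mapping with a warning.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().replace("-", "").replace(" ", "")
    if not seqs:
        warnings.warn(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# Input pre-filters
# --------------------------------------------------------------------------

def filter_inputs(
    scaffolds: Mapping[str, str],
    cds: Mapping[str, str],
    gene_of: Optional[Mapping[str, str]] = None,
    thresholds: Thresholds = Thresholds(),
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Apply the assembly input filters.

    Scaffolds shorter than ``min_scaffold_len_bp`` are discarded; per gene
    only the longest CDS is kept (ties broken by lexicographically smallest
    CDS id); CDS shorter than ``min_cds_len_bp`` are discarded.  When
    ``gene_of`` is empty or missing an id, each CDS is its own gene.
    Output order follows input order; the filters never fail.
    """
    gene_of = gene_of or {}
    kept_scaffolds = {sid: s for sid, s in scaffolds.items()
                      if len(s) >= thresholds.min_scaffold_len_bp}

    best_per_gene: Dict[str, str] = {}
    for cid, seq in cds.items():
        gene = gene_of.get(cid, cid)
        incumbent = best_per_gene.get(gene)
        if incumbent is None:
            best_per_gene[gene] = cid
        else:
            cur = (len(cds[incumbent]), incumbent)
            cand = (len(seq), cid)
            # longest wins; on a length tie the smaller id wins
            if cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                best_per_gene[gene] = cid
    selected = set(best_per_gene.values())
    kept_cds = {cid: s for cid, s in cds.items()
                if cid in selected and len(s) >= thresholds.min_cds_len_bp}
    return kept_scaffolds, kept_cds


# --------------------------------------------------------------------------
# Protein-similarity hits (12-column tabular, "outfmt 6" layout)
# --------------------------------------------------------------------------

def read_hits(
    path,
    taxonomy: TaxonomyMap,
    species_delimiter: str = "|",
    species_lookup: Optional[Mapping[str, str]] = None,
) -> List[HitRecord]:
    """Parse a 12-column tab-separated hit table.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  The subject species is resolved either
    through ``species_lookup`` (sseqid -> species) or, by default, as the
    sseqid prefix before ``species_delimiter``.  Every resolved species
    must exist in the taxonomy table; all unresolvable subject ids are
    collected and reported together with their line numbers.
    """
    hits: List[HitRecord] = []
    bad: List[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            sseqid = cols[1]
            if species_lookup is not None:
                species = species_lookup.get(sseqid)
            elif species_delimiter in sseqid:
                species = sseqid.split(species_delimiter, 1)[0]
            else:
                species = None
            if species is None or species not in taxonomy:
                bad.append(f"line {lineno}: {sseqid!r}")
                continue
            try:
                rec = HitRecord(
                    query_id=cols[0],
                    subject_id=sseqid,
                    subject_species=species,
                    identity_pct=float(cols[2]),
                    aln_len=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            if not 0.0 <= rec.identity_pct <= 100.0 or rec.aln_len < 1 or rec.evalue < 0:
                raise ParseError(f"{path}:{lineno}: out-of-range hit fields")
            hits.append(rec)
    if bad:
        raise TaxonomyError(
            f"{path}: {len(bad)} subject id(s) with unresolvable species: "
            + "; ".join(bad[:20]) + ("; ..." if len(bad) > 20 else "")
        )
    return hits


# --------------------------------------------------------------------------
# CDS-to-scaffold mappings
# --------------------------------------------------------------------------

_TSV_COLUMNS = ("cds_id", "scaffold_id", "start", "end", "strand",
                "aln_len_bp", "identity_pct", "part_index")


def _read_mappings_tsv(path) -> List[MappingRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TSV_COLUMNS:
            raise ParseError(f"{path}:1: expected header {'/'.join(_TSV_COLUMNS)}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            c = line.split("\t")
            if len(c) != len(_TSV_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
            try:
                records.append(MappingRecord(
                    cds_id=c[0], scaffold_id=c[1], start=int(c[2]), end=int(c[3]),
                    strand=c[4], aln_len_bp=int(c[5]), identity_pct=float(c[6]),
                    part_index=int(c[7])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return records


def _read_mappings_paf(path) -> List[MappingRecord]:
    """PAF rows -> records; 0-based half-open target coords shifted to 1-based.

    Identity is matches / alignment-block-length.  A query with two
    retained rows whose *query* intervals are near-disjoint (overlap below
    10% of the shorter interval) is treated as a chimeric pair, parts
    ordered by query start; otherwise only the best row survives
    downstream selection.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            c = line.split("\t")
            if len(c) < 12:
                raise ParseError(f"{path}:{lineno}: PAF needs >= 12 columns")
            try:
                qstart, qend = int(c[2]), int(c[3])
                tstart, tend = int(c[7]), int(c[8])
                nmatch, blocklen = int(c[9]), int(c[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if blocklen <= 0:
                raise ParseError(f"{path}:{lineno}: non-positive alignment block length")
            rows.append(dict(
                cds_id=c[0], qstart=qstart, qend=qend, strand=c[4],
                scaffold_id=c[5], start=tstart + 1, end=tend,
                aln_len_bp=tend - tstart,
                identity_pct=100.0 * nmatch / blocklen,
            ))

    by_query: Dict[str, list] = {}
    for r in rows:
        by_query.setdefault(r["cds_id"], []).append(r)

    records: List[MappingRecord] = []
    for cds_id in by_query:
        qrows = sorted(by_query[cds_id],
                       key=lambda r: (-r["identity_pct"], -r["aln_len_bp"],
                                      r["scaffold_id"]))
        best = qrows[0]
        chimera_mate = None
        for other in qrows[1:]:
            lo = max(best["qstart"], other["qstart"])
            hi = min(best["qend"], other["qend"])
            shorter = min(best["qend"] - best["qstart"], other["qend"] - other["qstart"])
            if shorter > 0 and max(0, hi - lo) < 0.10 * shorter:
                chimera_mate = other
                break
        if chimera_mate is None:
            pair = [(1, best)]
        else:
            first, second = sorted((best, chimera_mate), key=lambda r: r["qstart"])
            pair = [(1, first), (2, second)]
        for part, r in pair:
            records.append(MappingRecord(
                cds_id=cds_id, scaffold_id=r["scaffold_id"], start=r["start"],
                end=r["end"], strand=r["strand"], aln_len_bp=r["aln_len_bp"],
                identity_pct=r["identity_pct"], part_index=part))
    return records


def _parse_gff_attributes(field: str) -> Dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, _, v = item.partition("=")
            out[k.strip()] = v.strip()
    return out


def _read_mappings_gff3(path) -> List[MappingRecord]:
    """GFF3 alignment features -> records (coordinates pass through, 1-based).

    The CDS id is taken from the first token of ``Target``, else ``Name``,
    else ``ID``.  An id suffix ``.path1``/``.path2`` (spliced-aligner
    chimera convention) or an explicit ``part=`` attribute gives the part
    index.  Percent identity comes from an ``identity=``/``Identity=``
    attribute; features without one are an error (the mapping filter needs
    it).  Only ``mRNA``, ``gene`` and ``cDNA_match`` features are read.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            c = line.split("\t")
            if len(c) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if c[2] not in ("mRNA", "gene", "cDNA_match"):
                continue
            attrs = _parse_gff_attributes(c[8])
            if "Target" in attrs:
                cds_id = attrs["Target"].split()[0]
            elif "Name" in attrs:
                cds_id = attrs["Name"]
            elif "ID" in attrs:
                cds_id = attrs["ID"]
            else:
                raise ParseError(f"{path}:{lineno}: no Target/Name/ID attribute")
            part = 1
            for suffix, idx in ((".path1", 1), (".path2", 2)):
                if cds_id.endswith(suffix):
                    cds_id, part = cds_id[: -len(suffix)], idx
            if "part" in attrs:
                part = int(attrs["part"])
            identity = attrs.get("identity", attrs.get("Identity"))
            if identity is None:
                raise ParseError(f"{path}:{lineno}: missing identity attribute")
            try:
                start, end = int(c[3]), int(c[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(MappingRecord(
                cds_id=cds_id, scaffold_id=c[0], start=start, end=end,
                strand=c[6] if c[6] in "+-" else "+",
                aln_len_bp=end - start + 1,
                identity_pct=float(identity), part_index=part))
    return records


def select_best_placements(records: Sequence[MappingRecord]) -> List[MappingRecord]:
    """Keep one best placement per (cds, part): highest identity, then
    longest alignment, then lexicographically smallest scaffold id."""
    best: Dict[Tuple[str, int], MappingRecord] = {}
    for rec in records:
        key = (rec.cds_id, rec.part_index)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        a = (-rec.identity_pct, -rec.aln_len_bp, rec.scaffold_id)
        b = (-cur.identity_pct, -cur.aln_len_bp, cur.scaffold_id)
        if a < b:
            best[key] = rec
    return sorted(best.values(), key=lambda r: (r.cds_id, r.part_index))


def read_mappings(
    path,
    dialect: str = "tsv",
    scaffold_lengths: Optional[Mapping[str, int]] = None,
) -> List[MappingRecord]:
    """Read CDS-to-scaffold mappings in one of the declared dialects.

    Returns normalized records (1-based inclusive), at most one best
    placement per CDS plus one chimeric second part.  When scaffold
    lengths are supplied, coordinates exceeding them are an error;
    otherwise that check is skipped with a logged warning.
    """
    readers = {"tsv": _read_mappings_tsv, "paf": _read_mappings_paf,
               "gff3": _read_mappings_gff3}
    if dialect not in readers:
        raise ParseError(f"unknown mapping dialect {dialect!r}; expected tsv/paf/gff3")
    records = select_best_placements(readers[dialect](path))
    if scaffold_lengths is None:
        log.warning("no scaffold lengths supplied; coordinate bound checks skipped")
    else:
        for rec in records:
            length = scaffold_lengths.get(rec.scaffold_id)
            if length is not None and not (1 <= rec.start <= rec.end <= length):
                raise ParseError(
                    f"mapping of {rec.cds_id}: coords {rec.start}-{rec.end} outside "
                    f"scaffold {rec.scaffold_id} (length {length})")
    return records


def write_mappings_tsv(records: Iterable[MappingRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.cds_id, r.part_index)):
            fh.write(f"{r.cds_id}\t{r.scaffold_id}\t{r.start}\t{r.end}\t{r.strand}\t"
                     f"{r.aln_len_bp}\t{r.identity_pct:g}\t{r.part_index}\n")


# --------------------------------------------------------------------------
# Annotation output
# --------------------------------------------------------------------------

_ANNOT_COLUMNS = ("cds_id", "stage1", "foreign_group", "stage2", "scaffold_id",
                  "n_top_hits", "majority_fraction_observed")


def _sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_annotations(
    annotations,  # Sequence[CdsAnnotation]; duck-typed to avoid a cycle
    path,
    thresholds: Optional[Thresholds] = None,
    input_paths: Optional[Mapping[str, str]] = None,
) -> None:
    """Write the per-CDS annotation TSV plus a JSON sidecar.

    The TSV is sorted by cds_id so identical runs are byte-identical; the
    sidecar records the thresholds used and sha256 checksums of the named
    input files.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for a in sorted(annotations, key=lambda a: a.cds_id):
            scaffold = ",".join(a.scaffolds) if a.scaffolds else "."
            group = a.foreign_group or "."
            fh.write(f"{a.cds_id}\t{a.stage1.value}\t{group}\t{a.stage2.value}\t"
                     f"{scaffold}\t{a.n_top}\t{a.majority_fraction_observed:.4f}\n")
    sidecar = {
        "thresholds": (dataclass_to_dict(thresholds) if thresholds else None),
        "input_checksums": {name: _sha256_of(p)
                            for name, p in sorted((input_paths or {}).items())},
        "n_records": len(list(annotations)),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def dataclass_to_dict(obj) -> Dict:
    import dataclasses
    return dataclasses.asdict(obj)


def read_annotations(path):
    """Read back an annotation TSV written by :func:`write_annotations`."""
    from .taxonomic_assignment import CdsAnnotation
    from .model import Stage1, Stage2
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _ANNOT_COLUMNS:
            raise ParseError(f"{path}:1: unexpected annotation header")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            c = line.split("\t")
            if len(c) != len(_ANNOT_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(_ANNOT_COLUMNS)} columns")
            out.append(CdsAnnotation(
                cds_id=c[0],
                stage1=Stage1(c[1]),
                foreign_group=None if c[2] == "." else c[2],
                stage2=Stage2(c[3]),
                scaffolds=() if c[4] == "." else tuple(c[4].split(",")),
                n_top=int(c[5]),
                group_counts={},
                majority_fraction_observed=float(c[6]),
            ))
    return out
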