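"""Seeded generator of complete pipeline inputs with planted ground truth.

The generator emulates a host genome assembly carrying the disturbances
the pipeline is built to detect: whole contaminant scaffolds (a
co-sequenced foreign organism), horizontally transferred genes sitting on
host scaffolds, chimeric host genes spanning two scaffolds, orphan genes
without similarity evidence, and assembly fragmentation.  Host and
contaminant sequences come from two order-1 Markov composition models —
an AT-rich host (insect-like, ~38% GC) and a GC-rich foreign model
(~68% GC), mixed by ``composition_divergence`` — which is enough to make
the classes separable by tetranucleotide PCA without any
sequence-evolution machinery.

Hits are synthesized rather than computed by a real aligner: each CDS's
top hits reflect its true origin (eight hits to species of the true
group, two to other metazoans), corrupted at rate ``hit_noise``.  The
hit-table contract is exactly what stage 1 consumes, so real search
output can be substituted file-for-file.

Everything is deterministic given the seed, and every emitted CDS is
covered exactly once by the ground-truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import MappingRecord, write_fasta, write_mappings_tsv
from .model import (FOREIGN_GROUP_NAMES, GROUP_NAMES, Stage1, Stage2,
                    TaxonomyMap, XenocdsError)
from .synteny_classification import fragment_assembly

_BASES = np.array(list("ACGT"))

# AT-rich host model: every row favors A/T with a mild same-base repeat bias.
_HOST_TRANSITION = np.array([
    [0.36, 0.17, 0.15, 0.32],
    [0.32, 0.21, 0.15, 0.32],
    [0.32, 0.15, 0.21, 0.32],
    [0.32, 0.15, 0.17, 0.36],
])

# GC-rich foreign model with a strong G/C preference and CG/GC structure.
_ALT_TRANSITION = np.array([
    [0.14, 0.34, 0.38, 0.14],
    [0.12, 0.32, 0.42, 0.14],
    [0.14, 0.42, 0.32, 0.12],
    [0.14, 0.38, 0.34, 0.14],
])

_GENE_LEN_BP = 900          # planted CDS length
_SPACER_BP = 200            # intergenic spacer between planted genes
_MAP_IDENTITY = 99.0        # identity of synthesized placements


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of one synthetic assembly."""

    n_host_scaffolds: int = 12
    host_scaffold_len_bp: int = 12000
    genes_per_scaffold: int = 8
    n_contaminant_scaffolds: int = 4
    contaminant_genes_per_scaffold: int = 3
    n_hgt_genes: int = 5
    n_chimeric_host_genes: int = 2
    n_orphan_genes: int = 2
    composition_divergence: float = 0.5
    hit_noise: float = 0.0
    fragmentation_split: int = 1
    seed: int = 0
    contaminant_groups: Tuple[str, ...] = ("eubacteria",)
    plant_mixed_scaffold: bool = False   # add one scaffold with 1 eubacterial + 2 fungal CDS

    def __post_init__(self) -> None:
        for name in ("n_host_scaffolds", "host_scaffold_len_bp", "genes_per_scaffold",
                     "n_contaminant_scaffolds", "contaminant_genes_per_scaffold",
                     "n_hgt_genes", "n_chimeric_host_genes", "n_orphan_genes"):
            if getattr(self, name) < 0:
                raise XenocdsError(f"{name} must be >= 0")
        for name in ("composition_divergence", "hit_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise XenocdsError(f"{name} must be in [0,1]")
        if self.fragmentation_split < 1:
            raise XenocdsError("fragmentation_split must be >= 1")
        for g in self.contaminant_groups:
            if g not in FOREIGN_GROUP_NAMES:
                raise XenocdsError(f"unknown contaminant group {g!r}")


@dataclass
class Fixture:
    """All generated inputs plus the ground-truth manifest.

    ``scaffolds`` always holds the unfragmented sequences; when
    ``fragmentation_split > 1`` the ``mappings`` and ``scaffold_lengths``
    reflect the split assembly (fragmentation is modeled at the
    scaffold-partition level, not by editing sequences).
    """

    config: FixtureConfig
    scaffolds: Dict[str, str]
    cds: Dict[str, str]
    hit_rows: List[str]                      # 12-column tab-joined lines
    taxonomy: TaxonomyMap
    mappings: List[MappingRecord]
    scaffold_lengths: Dict[str, int]
    manifest: pd.DataFrame                   # one row per CDS

    def write(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "scaffolds": out / "scaffolds.fasta",
            "cds": out / "cds.fasta",
            "hits": out / "hits.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "mappings": out / "mappings.tsv",
            "manifest": out / "manifest.tsv",
            "scaffold_lengths": out / "scaffold_lengths.tsv",
        }
        write_fasta(self.scaffolds, paths["scaffolds"])
        write_fasta(self.cds, paths["cds"])
        with open(paths["hits"], "w") as fh:
            fh.write("\n".join(self.hit_rows) + ("\n" if self.hit_rows else ""))
        self.taxonomy.to_tsv(paths["taxonomy"])
        write_mappings_tsv(self.mappings, paths["mappings"])
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        with open(paths["scaffold_lengths"], "w") as fh:
            for sid in sorted(self.scaffold_lengths):
                fh.write(f"{sid}\t{self.scaffold_lengths[sid]}\n")
        return paths


def _markov_seq(rng: np.random.Generator, length: int, P: np.ndarray) -> str:
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    state = int(rng.integers(0, 4))
    for i in range(length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 3)
        out[i] = state
    return "".join(_BASES[out])


def _make_taxonomy(species_per_group: int = 6) -> TaxonomyMap:
    pairs = []
    for group in GROUP_NAMES:
        for i in range(1, species_per_group + 1):
            pairs.append((f"{group.upper()}_SP{i}", group))
    return TaxonomyMap.from_pairs(pairs)


def _species_pool(group: str, species_per_group: int = 6) -> List[str]:
    return [f"{group.upper()}_SP{i}" for i in range(1, species_per_group + 1)]


def generate(config: FixtureConfig) -> Fixture:
    """Generate one complete fixture; byte-identical for equal configs."""
    rng = np.random.default_rng(config.seed)
    c = config
    layout_span = c.genes_per_scaffold * (_GENE_LEN_BP + _SPACER_BP) + _SPACER_BP
    if c.genes_per_scaffold > 0 and c.host_scaffold_len_bp < layout_span:
        raise XenocdsError(
            f"host_scaffold_len_bp {c.host_scaffold_len_bp} cannot hold "
            f"{c.genes_per_scaffold} genes (need >= {layout_span})")
    if 2 * c.n_chimeric_host_genes > c.n_host_scaffolds:
        raise XenocdsError("need two host scaffolds per chimeric gene")

    contaminant_P = ((1.0 - c.composition_divergence) * _HOST_TRANSITION
                     + c.composition_divergence * _ALT_TRANSITION)
    taxonomy = _make_taxonomy()

    # ---- slot roles on host scaffolds -------------------------------------
    roles = [["host"] * c.genes_per_scaffold for _ in range(c.n_host_scaffolds)]
    for j in range(c.n_chimeric_host_genes):
        roles[2 * j][0] = f"chim1:{j}"
        roles[2 * j + 1][0] = f"chim2:{j}"
    placed = 0
    slot = c.genes_per_scaffold - 1
    while placed < c.n_hgt_genes:
        if slot < 0:
            raise XenocdsError("too many HGT genes for the host layout")
        for i in range(c.n_host_scaffolds):
            if placed >= c.n_hgt_genes:
                break
            if roles[i][slot] == "host":
                roles[i][slot] = "hgt"
                placed += 1
        slot -= 1
    placed = 0
    for s in range(1, c.genes_per_scaffold):
        for i in range(c.n_host_scaffolds):
            if placed >= c.n_orphan_genes:
                break
            if roles[i][s] == "host":
                roles[i][s] = "orphan"
                placed += 1
        if placed >= c.n_orphan_genes:
            break
    if placed < c.n_orphan_genes:
        raise XenocdsError("too many orphan genes for the host layout")
    for i in range(c.n_host_scaffolds):
        has_hgt = any(r == "hgt" for r in roles[i])
        has_confident = any(r == "host" or r.startswith("chim") for r in roles[i])
        if has_hgt and not has_confident:
            raise XenocdsError(
                f"host scaffold {i}: HGT gene needs a resident gene on the scaffold")

    scaffolds: Dict[str, str] = {}
    cds: Dict[str, str] = {}
    mappings: List[MappingRecord] = []
    manifest_rows: List[dict] = []
    hgt_groups_cycle = list(c.contaminant_groups) or ["eubacteria"]

    def slot_coords(s: int) -> Tuple[int, int]:
        start = _SPACER_BP + s * (_GENE_LEN_BP + _SPACER_BP) + 1
        return start, start + _GENE_LEN_BP - 1

    chimera_parts: Dict[int, List[Tuple[str, str, int, int]]] = {}
    hgt_index = 0
    for i in range(c.n_host_scaffolds):
        sid = f"hostscaf{i:02d}"
        seq = list(_markov_seq(rng, c.host_scaffold_len_bp, _HOST_TRANSITION))
        for s in range(c.genes_per_scaffold):
            role = roles[i][s]
            start, end = slot_coords(s)
            if role == "hgt":
                group = hgt_groups_cycle[hgt_index % len(hgt_groups_cycle)]
                hgt_index += 1
                gene_seq = _markov_seq(rng, _GENE_LEN_BP, contaminant_P)
                seq[start - 1:end] = list(gene_seq)
                cid = f"cds_{sid}_{s:02d}"
                cds[cid] = gene_seq
                mappings.append(MappingRecord(cid, sid, start, end, "+",
                                              _GENE_LEN_BP, _MAP_IDENTITY, 1))
                manifest_rows.append(dict(
                    cds_id=cid, origin="hgt", group=group, scaffold_id=sid,
                    intended_stage1=Stage1.FOREIGN.value,
                    intended_stage2=Stage2.HGT_CANDIDATE.value))
            elif role.startswith("chim"):
                _, j = role.split(":")
                # scaffold order guarantees part 1 (scaffold 2j) lands first
                chimera_parts.setdefault(int(j), []).append(
                    ("".join(seq[start - 1:end]), sid, start, end))
            elif role == "orphan":
                cid = f"cds_{sid}_{s:02d}"
                cds[cid] = "".join(seq[start - 1:end])
                manifest_rows.append(dict(
                    cds_id=cid, origin="host", group="", scaffold_id=sid,
                    intended_stage1=Stage1.ORPHAN.value,
                    intended_stage2=Stage2.NOT_APPLICABLE.value))
            else:
                cid = f"cds_{sid}_{s:02d}"
                cds[cid] = "".join(seq[start - 1:end])
                mappings.append(MappingRecord(cid, sid, start, end, "+",
                                              _GENE_LEN_BP, _MAP_IDENTITY, 1))
                manifest_rows.append(dict(
                    cds_id=cid, origin="host", group="", scaffold_id=sid,
                    intended_stage1=Stage1.CONFIDENT_ARTHROPOD.value,
                    intended_stage2=Stage2.NOT_APPLICABLE.value))
        scaffolds[sid] = "".join(seq)

    for j in sorted(chimera_parts):
        parts = chimera_parts[j]
        if len(parts) != 2:
            raise AssertionError("chimera must have exactly two parts")
        cid = f"cds_chim{j}"
        (seq1, sid1, start1, end1), (seq2, sid2, start2, end2) = parts
        cds[cid] = seq1 + seq2
        mappings.append(MappingRecord(cid, sid1, start1, end1, "+",
                                      len(seq1), _MAP_IDENTITY, 1))
        mappings.append(MappingRecord(cid, sid2, start2, end2, "+",
                                      len(seq2), _MAP_IDENTITY, 2))
        manifest_rows.append(dict(
            cds_id=cid, origin="host", group="",
            scaffold_id=f"{sid1},{sid2}",
            intended_stage1=Stage1.CONFIDENT_ARTHROPOD.value,
            intended_stage2=Stage2.NOT_APPLICABLE.value))

    # ---- contaminant scaffolds --------------------------------------------
    contam_specs: List[Tuple[str, List[str]]] = []
    for i in range(c.n_contaminant_scaffolds):
        group = c.contaminant_groups[i % len(c.contaminant_groups)] \
            if c.contaminant_groups else "eubacteria"
        contam_specs.append((f"contamscaf{i:02d}",
                             [group] * c.contaminant_genes_per_scaffold))
    if c.plant_mixed_scaffold:
        contam_specs.append(("mixedscaf00", ["eubacteria", "fungi", "fungi"]))

    for sid, gene_groups in contam_specs:
        n_genes = len(gene_groups)
        length = n_genes * (_GENE_LEN_BP + _SPACER_BP) + _SPACER_BP
        seq = _markov_seq(rng, length, contaminant_P)
        scaffolds[sid] = seq
        intended2 = (Stage2.CONTAMINANT_CANDIDATE if n_genes >= 2
                     else Stage2.UNCERTAIN)
        for s, group in enumerate(gene_groups):
            start, end = slot_coords(s)
            cid = f"cds_{sid}_{s:02d}"
            cds[cid] = seq[start - 1:end]
            mappings.append(MappingRecord(cid, sid, start, end, "+",
                                          _GENE_LEN_BP, _MAP_IDENTITY, 1))
            manifest_rows.append(dict(
                cds_id=cid, origin="contaminant", group=group, scaffold_id=sid,
                intended_stage1=Stage1.FOREIGN.value,
                intended_stage2=intended2.value))

    # ---- hit table --------------------------------------------------------
    manifest = pd.DataFrame(manifest_rows).sort_values("cds_id").reset_index(drop=True)
    hit_rows: List[str] = []
    all_species = {g: _species_pool(g) for g in GROUP_NAMES}
    for row in manifest.itertuples():
        if row.intended_stage1 == Stage1.ORPHAN.value:
            group_seq = ["arthropoda"]       # one passing hit: below the 2-hit gate
        elif row.intended_stage1 == Stage1.CONFIDENT_ARTHROPOD.value:
            group_seq = ["arthropoda"] * 8 + ["other_metazoa"] * 2
        else:
            group_seq = [row.group] * 8 + ["other_metazoa"] * 2
        for k, group in enumerate(group_seq):
            if c.hit_noise > 0 and rng.random() < c.hit_noise:
                others = [g for g in GROUP_NAMES if g != group]
                group = others[int(rng.integers(len(others)))]
            pool = all_species[group]
            species = pool[k % len(pool)]
            identity = round(float(rng.uniform(60.0, 95.0)), 1)
            aln = int(rng.integers(100, 301))
            evalue = 10.0 ** (-(80 - 3 * k))
            bitscore = 400.0 - 10.0 * k
            mismatch = int(aln * (1 - identity / 100.0))
            hit_rows.append("\t".join(map(str, [
                row.cds_id, f"{species}|prot{k}", identity, aln, mismatch, 0,
                1, aln, 1, aln, f"{evalue:.0e}", bitscore])))

    scaffold_lengths = {sid: len(seq) for sid, seq in scaffolds.items()}
    if c.fragmentation_split > 1:
        mappings, scaffold_lengths = fragment_assembly(
            mappings, scaffold_lengths, c.fragmentation_split)

    return Fixture(config=c, scaffolds=scaffolds, cds=cds, hit_rows=hit_rows,
                   taxonomy=taxonomy, mappings=mappings,
                   scaffold_lengths=scaffold_lengths, manifest=manifest)


@dataclass(frozen=True)
class FragmentedFixture:
    """One point of a fragmentation sweep: shared gene content, re-partitioned
    scaffolds."""

    split_factor: int
    mappings: Tuple[MappingRecord, ...]
    scaffold_lengths: Mapping[str, int]
    base: Fixture


def sweep_fragmentation(
    config: FixtureConfig,
    split_factors: Sequence[int],
) -> List[FragmentedFixture]:
    """One fixture variant per split factor, all sharing the base fixture's
    gene content and hit table."""
    if not split_factors:
        raise XenocdsError("sweep_fragmentation needs at least one factor")
    base = generate(replace(config, fragmentation_split=1))
    base_lengths = {sid: len(s) for sid, s in base.scaffolds.items()}
    out = []
    for f in split_factors:
        mappings, lengths = fragment_assembly(base.mappings, base_lengths, f)
        out.append(FragmentedFixture(split_factor=f, mappings=tuple(mappings),
                                     scaffold_lengths=lengths, base=base))
    return out
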