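"""Stage 1: per-CDS taxonomic assignment from ranked similarity hits.

Each CDS is assigned by majority vote over its best protein-similarity
hits.  Hits first pass three strict filters (identity > 40%, alignment
length > 75 aa, E-value < 1e-10); a CDS with fewer than two passing hits,
or passing hits to fewer than two distinct species, is an orphan.  The
vote is taken over the (at most) ten smallest-E-value retained hits:

* foreign group g        — >= 70% of the top hits in g (one of eubacteria,
                           archaea, fungi, viridiplantae, protists);
* confident resident     — 100% of the top hits metazoan, of which >= 70%
                           arthropod;
* other metazoa          — >= 70% non-arthropod metazoan and zero
                           arthropod hits;
* otherwise unassigned.

Fractions count *hits*, not distinct species; multiple hits to the same
species each vote.  The minimum-two-species gate is evaluated on all
retained hits, not just the top ten.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .io_formats import HitRecord
from .model import (FOREIGN_GROUP_NAMES, Stage1, Stage2, TaxonomyMap,
                    Thresholds, XenocdsError)


@dataclass(frozen=True)
class HitSet:
    """The retained, ranked hit list of one CDS."""

    cds_id: str
    retained: Tuple[HitRecord, ...]      # ascending E-value (ties broken)
    top: Tuple[HitRecord, ...]           # first min(top_n, |retained|)
    distinct_species: int


@dataclass(frozen=True)
class CdsAnnotation:
    """Category of one CDS through both pipeline stages, with evidence."""

    cds_id: str
    stage1: Stage1
    foreign_group: Optional[str] = None
    stage2: Stage2 = Stage2.NOT_APPLICABLE
    scaffolds: Tuple[str, ...] = ()
    n_top: int = 0
    group_counts: Mapping[str, int] = field(default_factory=dict)
    majority_fraction_observed: float = 0.0

    def __post_init__(self) -> None:
        if (self.foreign_group is not None) != (self.stage1 is Stage1.FOREIGN):
            raise XenocdsError(
                f"{self.cds_id}: foreign_group must be set iff stage1 is foreign")
        if (self.stage2 is not Stage2.NOT_APPLICABLE) and self.stage1 is not Stage1.FOREIGN:
            raise XenocdsError(
                f"{self.cds_id}: stage2 applies to foreign candidates only")


def retain_hits(hits: Sequence[HitRecord], thresholds: Thresholds) -> HitSet:
    """Filter and rank the hits of one CDS.

    All hits must share one query id.  Filters are strict; survivors are
    sorted by (E-value asc, bitscore desc, subject id asc) and the top list
    truncated to ``top_n_hits``.
    """
    if not hits:
        raise XenocdsError("retain_hits needs at least the cds context; got no hits")
    cds_ids = {h.query_id for h in hits}
    if len(cds_ids) != 1:
        raise XenocdsError(f"retain_hits: hits span multiple CDS ids {sorted(cds_ids)}")
    t = thresholds
    kept = [h for h in hits
            if h.identity_pct > t.min_hit_identity_pct
            and h.aln_len > t.min_hit_aln_len_aa
            and h.evalue < t.max_hit_evalue]
    kept.sort(key=lambda h: h.rank_key)
    return HitSet(
        cds_id=cds_ids.pop(),
        retained=tuple(kept),
        top=tuple(kept[: t.top_n_hits]),
        distinct_species=len({h.subject_species for h in kept}),
    )


def empty_hitset(cds_id: str) -> HitSet:
    """The hit set of a CDS with no hits at all (always an orphan)."""
    return HitSet(cds_id=cds_id, retained=(), top=(), distinct_species=0)


def assign_category(
    hitset: HitSet,
    taxonomy: TaxonomyMap,
    thresholds: Thresholds,
) -> CdsAnnotation:
    """Assign the stage-1 category of one CDS from its retained hits.

    The decision procedure is applied in a fixed order: orphan gate,
    foreign majority, confident resident, other-metazoa, unassigned.  At
    the default 70% majority at most one foreign group can win (2 x 0.70 >
    1), so the foreign rule is unambiguous; with a configured majority
    below 0.5 ties break by larger fraction then group name.
    """
    t = thresholds
    if (len(hitset.retained) < t.min_hits
            or hitset.distinct_species < t.min_distinct_species):
        return CdsAnnotation(cds_id=hitset.cds_id, stage1=Stage1.ORPHAN,
                             n_top=len(hitset.top))

    groups = [taxonomy.group_of(h.subject_species) for h in hitset.top]
    n = len(groups)
    counts: Dict[str, int] = {}
    for g in groups:
        counts[g.name] = counts.get(g.name, 0) + 1
    frac = {name: c / n for name, c in counts.items()}

    metazoa_frac = sum(c for name, c in counts.items()
                       if _is_metazoa(name)) / n
    arthropod_count = sum(c for name, c in counts.items() if _is_arthropod(name))
    arthropod_frac = arthropod_count / n
    nonarth_metazoa_frac = metazoa_frac - arthropod_frac

    def annotate(stage1: Stage1, group: Optional[str], observed: float) -> CdsAnnotation:
        return CdsAnnotation(cds_id=hitset.cds_id, stage1=stage1,
                             foreign_group=group, n_top=n, group_counts=counts,
                             majority_fraction_observed=observed)

    foreign_winners = sorted(
        ((frac[name], name) for name in FOREIGN_GROUP_NAMES
         if frac.get(name, 0.0) >= t.majority_fraction),
        key=lambda p: (-p[0], p[1]))
    if foreign_winners:
        f, name = foreign_winners[0]
        return annotate(Stage1.FOREIGN, name, f)

    if (metazoa_frac >= t.confident_metazoa_fraction
            and arthropod_frac >= t.majority_fraction):
        return annotate(Stage1.CONFIDENT_ARTHROPOD, None, arthropod_frac)

    if nonarth_metazoa_frac >= t.majority_fraction and arthropod_count == 0:
        return annotate(Stage1.OTHER_METAZOA, None, nonarth_metazoa_frac)

    return annotate(Stage1.UNASSIGNED, None,
                    max(frac.values()) if frac else 0.0)


def _is_metazoa(group_name: str) -> bool:
    from .model import CANONICAL_GROUPS
    return CANONICAL_GROUPS[group_name].is_metazoa


def _is_arthropod(group_name: str) -> bool:
    from .model import CANONICAL_GROUPS
    return CANONICAL_GROUPS[group_name].is_arthropod


def assign_all(
    hits: Sequence[HitRecord],
    cds_ids: Sequence[str],
    taxonomy: TaxonomyMap,
    thresholds: Thresholds,
) -> List[CdsAnnotation]:
    """Assign every CDS in ``cds_ids``; CDS without hits become orphans.

    Hits whose query id is not in ``cds_ids`` are ignored (they belong to
    CDS removed by the input filters).
    """
    wanted = set(cds_ids)
    by_cds: Dict[str, List[HitRecord]] = {}
    for h in hits:
        if h.query_id in wanted:
            by_cds.setdefault(h.query_id, []).append(h)
    out = []
    for cds_id in sorted(wanted):
        hs = (retain_hits(by_cds[cds_id], thresholds)
              if cds_id in by_cds else empty_hitset(cds_id))
        out.append(assign_category(hs, taxonomy, thresholds))
    return out
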