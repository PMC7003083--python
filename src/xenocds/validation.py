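"""Validation computations: tetranucleotide PCA, scaffold taxonomic
consistency, and single-linkage family clustering of HGT candidates.

Tetranucleotide (4-mer) frequencies carry phylogenetic signal, so planted
or real contaminant CDS should separate from resident CDS in the first
principal components — the same rationale as GC/coverage blob plots and
compositional metagenome binning.  Where a published analysis would
eyeball the PCA, :func:`pca_separation` returns a silhouette score so the
check is numeric and testable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import networkx as nx
from sklearn.metrics import silhouette_score

from .model import Stage1, Stage2, Thresholds, XenocdsError
from .synteny_classification import ScaffoldTable
from .taxonomic_assignment import CdsAnnotation

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_order(k: int = 4) -> List[str]:
    """All k-mers over ACGT in lexicographic order (256 entries for k=4)."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


@dataclass(frozen=True)
class KmerProfile:
    """Normalized k-mer frequency vector of one CDS (stranded, no
    reverse-complement collapsing)."""

    cds_id: str
    freqs: np.ndarray            # length 4**k, lexicographic k-mer order
    n_windows: int

    @property
    def flagged_short(self) -> bool:
        """Profiles from fewer than 50 countable windows are noisy."""
        return self.n_windows < 50


def kmer_profile(seq: str, cds_id: str = "", k: int = 4) -> KmerProfile:
    """Sliding-window k-mer frequencies of a nucleotide sequence.

    Windows containing any non-ACGT symbol are skipped and the remaining
    counts renormalized.  A sequence shorter than k yields an all-zero
    profile with ``n_windows = 0``.
    """
    if k < 1:
        raise XenocdsError(f"k must be >= 1, got {k}")
    seq = seq.upper()
    counts = np.zeros(4 ** k)
    n_windows = 0
    codes = [_BASE_INDEX.get(c, -1) for c in seq]
    for i in range(len(seq) - k + 1):
        window = codes[i:i + k]
        if -1 in window:
            continue
        idx = 0
        for c in window:
            idx = idx * 4 + c
        counts[idx] += 1
        n_windows += 1
    freqs = counts / n_windows if n_windows else counts
    return KmerProfile(cds_id=cds_id, freqs=freqs, n_windows=n_windows)


def profiles_matrix(profiles: Sequence[KmerProfile]) -> np.ndarray:
    return np.vstack([p.freqs for p in profiles])


def pca_separation(
    contaminant_profiles: Sequence[KmerProfile],
    resident_profiles: Sequence[KmerProfile],
    n_components: int = 3,
    seed: int = 0,
) -> Tuple[np.ndarray, float]:
    """PCA of pooled k-mer profiles plus a silhouette separation score.

    Profiles are centered (column means removed, no scaling) and
    decomposed by SVD.  Returns the coordinates of all profiles
    (contaminants first) on the first ``n_components`` axes, and the mean
    silhouette of the contaminant/resident labeling computed on those
    coordinates: near 0 for indistinguishable sets, toward 1 for cleanly
    separated ones.  Component signs are canonicalized (largest-magnitude
    loading positive) so results are exactly reproducible; ``seed`` is
    part of the interface but the decomposition is deterministic.
    """
    if len(contaminant_profiles) < 2 or len(resident_profiles) < 2:
        raise XenocdsError("pca_separation needs >= 2 profiles per set")
    X = profiles_matrix(list(contaminant_profiles) + list(resident_profiles))
    if n_components > X.shape[1]:
        raise XenocdsError("n_components exceeds profile dimension")
    if np.unique(X, axis=0).shape[0] < 2:
        raise XenocdsError("pca_separation needs at least 2 distinct profiles")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(S))
    # canonical sign: the largest-|.| loading of each axis is positive
    for j in range(n_components):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    coords = U[:, :n_components] * S[:n_components]
    labels = np.array([0] * len(contaminant_profiles) + [1] * len(resident_profiles))
    score = float(silhouette_score(coords, labels))
    return coords, score


# --------------------------------------------------------------------------
# Contaminant-scaffold consistency
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldConsistency:
    scaffold_id: str
    groups: Tuple[str, ...]      # foreign group of each contaminant CDS, sorted
    consistent: bool


def contaminant_scaffolds(
    table: ScaffoldTable,
    annotations: Sequence[CdsAnnotation],
) -> Dict[str, List[CdsAnnotation]]:
    """Scaffolds holding >= 2 contaminant CDS and no resident CDS."""
    by_id = {a.cds_id: a for a in annotations}
    out: Dict[str, List[CdsAnnotation]] = {}
    for sid, items in table.members.items():
        anns = [by_id[cid] for cid, _ in items if cid in by_id]
        if any(a.stage1 is Stage1.CONFIDENT_ARTHROPOD for a in anns):
            continue
        contams = [a for a in anns if a.stage2 is Stage2.CONTAMINANT_CANDIDATE]
        if len(contams) >= 2:
            out[sid] = contams
    return out


def consistency_check(
    table: ScaffoldTable,
    annotations: Sequence[CdsAnnotation],
) -> List[ScaffoldConsistency]:
    """Taxonomic consistency of each contaminant scaffold.

    All CDS on one contaminant scaffold should derive from the same
    organism, hence share one foreign group; a scaffold mixing groups is
    flagged (it may be a chimera of two contaminant sequences).  Scaffolds
    with fewer than two contaminant CDS are not contaminant scaffolds and
    are excluded.
    """
    results = []
    for sid, contams in sorted(contaminant_scaffolds(table, annotations).items()):
        groups = tuple(sorted(a.foreign_group for a in contams))
        results.append(ScaffoldConsistency(
            scaffold_id=sid, groups=groups, consistent=len(set(groups)) == 1))
    return results


# --------------------------------------------------------------------------
# Family clustering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyPartition:
    """Single-linkage families over the pairwise-identity graph."""

    families: Mapping[str, Tuple[str, ...]]   # family id (smallest member) -> members

    def family_of(self, cds_id: str) -> str:
        for fid, members in self.families.items():
            if cds_id in members:
                return fid
        raise XenocdsError(f"{cds_id} not in any family")

    def __len__(self) -> int:
        return len(self.families)


def cluster_families(
    pairwise: Iterable[Tuple[str, str, float]],
    universe: Set[str],
    thresholds: Thresholds = Thresholds(),
) -> FamilyPartition:
    """Cluster CDS into families by single linkage at the identity floor.

    Edges with identity fraction >= ``family_identity_fraction`` (default
    0.60) are kept; families are the connected components of the resulting
    graph, unconnected CDS are singletons, and each family is named after
    its lexicographically smallest member.
    """
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for a, b, ident in pairwise:
        if a not in universe or b not in universe:
            raise XenocdsError(f"pair ({a}, {b}) references a CDS outside the universe")
        if not 0.0 <= ident <= 1.0:
            raise XenocdsError(f"identity fraction out of [0,1]: {ident}")
        if ident >= thresholds.family_identity_fraction:
            graph.add_edge(a, b)
    families = {}
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        families[members[0]] = members
    return FamilyPartition(families=dict(sorted(families.items())))
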