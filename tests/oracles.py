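"""Independent brute-force oracles and random-instance generators.

These deliberately re-derive every rule from first principles (plain
dicts, literal scans, fixpoint loops) without importing the package's
decision logic, so agreement with the implementation is a real check.
They are shared between the unit/property tests and the acceptance
script.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

GROUPS = ("eubacteria", "archaea", "fungi", "viridiplantae", "protists",
          "arthropoda", "other_metazoa")
FOREIGN = GROUPS[:5]
METAZOA = {"arthropoda", "other_metazoa"}


# --------------------------------------------------------------------------
# Stage 1: literal rule enumeration
# --------------------------------------------------------------------------

def stage1_oracle(
    hits: Sequence[dict],
    group_of: Dict[str, str],
    min_identity: float = 40.0,
    min_aln: int = 75,
    max_evalue: float = 1e-10,
    min_hits: int = 2,
    min_species: int = 2,
    top_n: int = 10,
    majority: float = 0.70,
) -> Tuple[str, Optional[str]]:
    """Return (stage1 label, foreign group or None) by literal enumeration.

    ``hits`` are dicts with keys species, subject_id, identity, aln_len,
    evalue, bitscore.
    """
    passing = []
    for h in hits:
        if h["identity"] > min_identity and h["aln_len"] > min_aln \
                and h["evalue"] < max_evalue:
            passing.append(h)
    if len(passing) < min_hits:
        return ("orphan", None)
    if len({h["species"] for h in passing}) < min_species:
        return ("orphan", None)

    ranked = sorted(passing,
                    key=lambda h: (h["evalue"], -h["bitscore"], h["subject_id"]))
    top = ranked[:top_n]
    n = len(top)

    def frac_of(predicate) -> float:
        return sum(1 for h in top if predicate(group_of[h["species"]])) / n

    winners = []
    for g in FOREIGN:
        f = frac_of(lambda name, g=g: name == g)
        if f >= majority:
            winners.append((f, g))
    if winners:
        winners.sort(key=lambda p: (-p[0], p[1]))
        return ("foreign", winners[0][1])

    metazoa_frac = frac_of(lambda name: name in METAZOA)
    arthropod_frac = frac_of(lambda name: name == "arthropoda")
    if metazoa_frac == 1.0 and arthropod_frac >= majority:
        return ("confident_arthropod", None)

    nonarth_frac = frac_of(lambda name: name == "other_metazoa")
    arthropod_count = sum(1 for h in top if group_of[h["species"]] == "arthropoda")
    if nonarth_frac >= majority and arthropod_count == 0:
        return ("other_metazoa", None)

    return ("unassigned", None)


def random_hitset(rng: np.random.Generator) -> Tuple[List[dict], Dict[str, str]]:
    """A random hit list exercising filter boundaries, ties and small-n cases."""
    group_of = {}
    for g in GROUPS:
        for i in range(1, 4):
            group_of[f"{g}:{i}"] = g
    n = int(rng.integers(0, 16))
    identities = [38.0, 40.0, 40.5, 55.0, 75.0, 92.0]
    aln_lens = [60, 75, 76, 120, 250]
    evalues = [1e-5, 1e-10, 1.1e-10, 1e-11, 1e-30, 1e-60, 1e-80]
    hits = []
    for i in range(n):
        g = GROUPS[int(rng.integers(len(GROUPS)))]
        sp = f"{g}:{int(rng.integers(1, 4))}"
        hits.append(dict(
            species=sp,
            subject_id=f"{sp}|p{int(rng.integers(0, 6))}",
            identity=float(rng.choice(identities)),
            aln_len=int(rng.choice(aln_lens)),
            evalue=float(rng.choice(evalues)),
            bitscore=float(rng.choice([100.0, 200.0, 200.0, 300.0])),
        ))
    return hits, group_of


# --------------------------------------------------------------------------
# Stage 2: literal membership scanning
# --------------------------------------------------------------------------

def stage2_oracle(
    cds_stage1: Dict[str, str],            # cds -> "foreign" | "confident_arthropod"
    placements: Dict[str, List[Tuple[str, int, float]]],  # cds -> [(scaffold, aln_len, identity)]
    min_len: int = 100,
    min_identity: float = 95.0,
) -> Dict[str, str]:
    """Classify every foreign CDS by literally scanning scaffold members."""
    mapped: Dict[str, List[str]] = {}
    for cds, places in placements.items():
        if cds not in cds_stage1:
            continue
        scaffolds = []
        for scaffold, aln, ident in places:
            if aln >= min_len and ident >= min_identity and scaffold not in scaffolds:
                scaffolds.append(scaffold)
        if scaffolds:
            mapped[cds] = scaffolds

    scaffold_members: Dict[str, Set[str]] = {}
    for cds, scaffolds in mapped.items():
        for s in scaffolds:
            scaffold_members.setdefault(s, set()).add(cds)

    tagged = {s for s, members in scaffold_members.items()
              if any(cds_stage1[c] == "confident_arthropod" for c in members)}
    # fixpoint propagation across chimera-linked scaffolds
    changed = True
    while changed:
        changed = False
        for cds, scaffolds in mapped.items():
            if len(scaffolds) >= 2 and any(s in tagged for s in scaffolds):
                for s in scaffolds:
                    if s not in tagged:
                        tagged.add(s)
                        changed = True

    out = {}
    for cds, s1 in cds_stage1.items():
        if s1 != "foreign":
            continue
        scaffolds = mapped.get(cds, [])
        if not scaffolds:
            out[cds] = "uncertain"
        elif any(s in tagged for s in scaffolds):
            out[cds] = "hgt_candidate"
        elif any(other != cds
                 for s in scaffolds for other in scaffold_members[s]
                 if cds_stage1[other] == "foreign"):
            out[cds] = "contaminant_candidate"
        else:
            out[cds] = "uncertain"
    return out


def random_stage2_instance(rng: np.random.Generator):
    """Random small scaffold instance incl. chimeric CDS and filter-failing
    placements."""
    n_scaffolds = int(rng.integers(1, 11))
    scaffolds = [f"s{i}" for i in range(n_scaffolds)]
    n_cds = int(rng.integers(1, 31))
    cds_stage1: Dict[str, str] = {}
    placements: Dict[str, List[Tuple[str, int, float]]] = {}
    for i in range(n_cds):
        cid = f"c{i}"
        cds_stage1[cid] = "confident_arthropod" if rng.random() < 0.35 else "foreign"
        r = rng.random()
        if r < 0.15:
            placements[cid] = []          # unmapped
            continue
        n_parts = 2 if (r > 0.75 and n_scaffolds >= 2) else 1
        chosen = rng.choice(n_scaffolds, size=n_parts, replace=False)
        places = []
        for s_idx in chosen:
            aln = int(rng.choice([80, 99, 100, 101, 500]))
            ident = float(rng.choice([90.0, 94.9, 95.0, 99.0]))
            places.append((scaffolds[int(s_idx)], aln, ident))
        placements[cid] = places
    return cds_stage1, placements


# --------------------------------------------------------------------------
# Numeric primitives
# --------------------------------------------------------------------------

def n50_oracle(lengths: Sequence[int]) -> int:
    """Check every candidate length against the N50 definition directly."""
    total = sum(lengths)
    best = None
    for L in sorted(set(lengths)):
        covered = sum(x for x in lengths if x >= L)
        if 2 * covered >= total:
            best = L   # largest L still covering half; N50 is the max such L
    return best


def kmer_counts_oracle(seq: str, k: int) -> Dict[str, int]:
    """Window-by-window k-mer counting with explicit ACGT checks."""
    counts: Dict[str, int] = {}
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if all(c in "ACGT" for c in w):
            counts[w] = counts.get(w, 0) + 1
    return counts
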