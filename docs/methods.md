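# Methods

## Model and assumptions

`xenocds` annotates every predicted CDS of one assembly with a category
from {confident resident, other metazoa, foreign candidate, orphan,
unassigned} (stage 1) and, for foreign candidates, {HGT candidate,
contaminant candidate, uncertain} (stage 2).  The central assumptions are:

1. **Similarity votes, not best hits.** Taxonomic affinity is decided by a
   70% majority over the (at most) ten lowest-E-value retained hits, which
   buffers against individual mis-annotated reference sequences.  Fractions
   count *hits*, not distinct species: repeated hits to one well-sampled
   species are evidence, not noise.  The minimum-evidence gate (≥ 2 retained
   hits to ≥ 2 species) is evaluated on all retained hits, since a second
   species outside the top ten still corroborates the assignment.
2. **Synteny adjudicates.** Foreign-looking CDS that co-locate with
   confidently resident genes are treated as HGT candidates; foreign CDS on
   scaffolds free of resident genes but carrying other foreign CDS are
   contaminant candidates.  A single foreign CDS alone on a scaffold is
   *uncertain* — deliberately so, as the synteny signal is absent.
3. **The reference taxonomy is user-supplied.** Species-to-group mapping
   comes solely from a two-column table; an unresolvable species is an
   error, never a silent default.

## Thresholds

All constants live in `Thresholds` and serialize to a `key = value` config
file.  Defaults:

| parameter | default | unit | note |
|---|---|---|---|
| `min_hit_identity_pct` | 40 | % | strict: hits kept iff identity **>** 40 |
| `min_hit_aln_len_aa` | 75 | aa | strict **>** |
| `max_hit_evalue` | 1e-10 | — | strict **<** |
| `min_hits` / `min_distinct_species` | 2 / 2 | count | orphan gate, on retained hits |
| `top_n_hits` | 10 | count | voting window |
| `majority_fraction` | 0.70 | — | group majority over top hits |
| `confident_metazoa_fraction` | 1.00 | — | enclosing-clade purity for residents |
| `min_map_len_bp` / `min_map_identity_pct` | 100 / 95 | bp / % | inclusive **≥** ("minimum" = attainable bound) |
| `min_scaffold_len_bp` / `min_cds_len_bp` | 200 / 150 | bp | input pre-filters (≥ kept) |
| `family_identity_fraction` | 0.60 | — | single-linkage family edges, inclusive |
| `logit_adjustment` | 0.025 | — | squeeze for proportions of 0/1 |

Hit filters are strict and mapping/clustering filters inclusive because the
former are phrased as strict inequalities and the latter as attainable
minima; at equality the difference matters only for synthetic data, but the
convention is fixed and documented here.  The logit squeeze of 0.025 is the
common remedy-of-zeroes convention for logit-transformed proportions.

## Decision-rule details

Stage-1 rules apply in a fixed order: orphan gate; foreign majority;
confident resident; other-metazoa; unassigned.  At the default 70%
majority at most one foreign group can win (2 × 0.70 > 1); if a user lowers
the majority below 0.5, ties break by larger fraction then group name.
E-value ties at the top-ten boundary break by bitscore (descending) then
subject id — an arbitrary but deterministic convention.

Stage 2: the resident tag is seeded on every scaffold holding a mapped
confident-resident CDS and closed over connected components of the
chimera-link graph (a chimeric alignment is one CDS whose 5′ and 3′ ends
map to different scaffolds).  For the contaminant rule, "another foreign
CDS" may belong to any of the five source groups — a scaffold mixing groups
still counts, and is then surfaced by the consistency test rather than
silently reclassified — but it must be a *different* CDS: a chimeric CDS's
second part never corroborates its first.  Best placements are chosen by
identity, then aligned length, then lexicographic scaffold id.

An optional contig-scale mode breaks scaffolds at runs of ≥ 10 ambiguous
bases before classification, for assemblies whose scaffolding is in doubt;
it can only move candidates toward *uncertain*.

## Validation computations

* **4-mer PCA.** Stranded tetranucleotide frequencies (no
  reverse-complement collapsing — CDS are oriented), windows containing
  non-ACGT symbols skipped, frequencies normalized by counted windows.
  Profiles are centered but not scaled before SVD; component signs are
  canonicalized (largest-magnitude loading positive) for exact
  reproducibility.  Separation between contaminant and resident sets is
  the mean silhouette on the first three components — a numeric stand-in
  for the by-eye inspection of PCA plots, chosen so the validation is
  testable.  Profiles from < 50 windows are flagged as noisy.  k is
  configurable, so the module doubles as a general compositional profiler.
* **Consistency test.** A contaminant scaffold (≥ 2 contaminant CDS, no
  resident CDS) is consistent iff all its contaminant CDS share one source
  group; mixed scaffolds are reported, as they may be chimeras of two
  contaminants.
* **Family clustering.** Single linkage over a user-supplied pairwise
  identity table at ≥ 0.60; families are connected components, named after
  their lexicographically smallest member.  Alignments themselves are out
  of scope.

## Reporting

`AssemblyReport` fixes the denominators explicitly: `pct_contaminant_of_all`
is over all CDS; the `*_of_assigned` percentages are over CDS whose stage-1
category is neither orphan nor unassigned (the CDS for which a taxonomic
assignment was possible — the more meaningful prevalence measure);
`pct_uncertain_of_foreign` is over foreign candidates.  N50 is the length
of the scaffold at which the descending cumulative sum first reaches half
the assembly span.  The fragmentation regression fits
logit(uncertain fraction) on log₁₀(N50) by OLS (base-10 logs chosen for
readability of the slope; the sign and fit are invariant to the base).

## Synthetic data generator

The generator emulates the data regimes the pipeline must handle: a host
assembly (default 12 scaffolds × 8 genes of 900 bp, 200 bp spacers) plus
planted contaminant scaffolds (default 4 × 3 genes — the
"scattered small scaffolds" regime; one long scaffold with many genes
models the opposite regime), HGT genes on host scaffolds (default 5),
chimeric host genes spanning scaffold pairs (default 2), and 2 orphan
genes.  Host sequences come from an AT-rich order-1 Markov model (~38% GC,
typical of insect hosts); contaminant/HGT sequences from a GC-rich model
(~68% GC, as for many bacterial genomes) mixed toward the host model by
`1 − composition_divergence`.  Order-1 chains are the simplest model that
makes the classes separable in 4-mer space; they do not reproduce codon
structure, repeats, or within-genome compositional heterogeneity, so a
high PCA separation on fixtures shows the statistic works, not that real
host/contaminant pairs are always this separable.

Hits are synthesized, not computed by an aligner: each CDS receives ten
hits whose species reflect its true origin (eight in the true group, two
to other metazoans), with E-values descending and identities in 60–95%;
`hit_noise` reassigns each hit to a random wrong group with the given
probability.  This keeps the generator self-contained while honouring the
exact hit-table contract, and a real search output can be substituted
file-for-file.  Mappings mirror the true placements at 99% identity.

Fragmentation is modeled at the scaffold-partition level: each scaffold's
mapped CDS, in coordinate order, are split into `f` contiguous chunks with
boundaries at `i·n/f`, making partitions nested across factors that divide
each other (so refining a split can never re-merge CDS).  Scaffold
sequences are not edited; no read or assembly simulation is performed.

## Determinism and numerical choices

Every output file is sorted deterministically and rewritten byte-identically
on identical inputs; run records carry checksums and counts but no
timestamps (timing goes to the log stream).  PCA is exact SVD, so the only
randomness anywhere is the generator's seeded RNG.  K-mer frequencies sum
to 1 within 1e-9 by construction; degenerate inputs (sequence shorter than
k, empty hit tables, assemblies with zero foreign candidates) return
well-defined flagged results rather than errors.

## Problem sizes

The bundled analyses use assemblies of ~100 CDS across ~16 scaffolds
(~160 kb), 10⁴ random instances for each brute-force cross-check, 10³
random lists for the N50 oracle, and a five-point fragmentation sweep —
sizes at which every property of interest is already expressed and the
whole suite runs in seconds on one CPU.

## Known limitations

* Power depends on the completeness and balance of the user's reference
  proteome set; taxonomic gaps (e.g. archaea) depress the corresponding
  foreign counts.
* Stage 2 cannot adjudicate foreign CDS alone on their scaffolds; the
  uncertain fraction grows as assemblies fragment, so contamination
  prevalence in fragmented assemblies is a lower bound.
* A scaffold whose only occupants are foreign CDS of *different* groups is
  still called contaminant (and flagged by the consistency test) rather
  than uncertain; this is a deliberate, documented choice.
* HGT candidates are similarity+synteny candidates only; confirming a
  transfer requires phylogenetic follow-up outside this package's scope.
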