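"""Consistency test of contaminant scaffolds and HGT family clustering.

All CDS on a genuine contaminant scaffold derive from one organism, so
mixed taxonomic groups on one scaffold indicate a problem (for instance a
chimeric scaffold joining two contaminants).  HGT candidates are
clustered into families by single linkage at >= 60% identity before any
per-family follow-up.
"""

import xenocds as x
from xenocds.synthetic_fixtures import FixtureConfig, generate

# one scaffold deliberately mixes 1 eubacterial with 2 fungal CDS
fx = generate(FixtureConfig(seed=5, plant_mixed_scaffold=True))
hits = [x.HitRecord(c[0], c[1], c[1].split("|", 1)[0], float(c[2]), int(c[3]),
                    float(c[10]), float(c[11]))
        for c in (line.split("\t") for line in fx.hit_rows)]
result = x.run_all(fx.scaffolds, fx.cds, hits, fx.taxonomy, fx.mappings)

print("contaminant scaffold consistency:")
for r in x.consistency_check(result.table, result.annotations):
    status = "ok" if r.consistent else "MIXED ORIGIN"
    print(f"  {r.scaffold_id}: {','.join(r.groups)}  -> {status}")

# family clustering of the HGT candidates from a pairwise identity table
hgt_ids = {a.cds_id for a in result.annotations
           if a.stage2 is x.Stage2.HGT_CANDIDATE}
ids = sorted(hgt_ids)
pairs = [(ids[0], ids[1], 0.82), (ids[1], ids[2], 0.71), (ids[2], ids[0], 0.55),
         (ids[3], ids[4], 0.30)]
partition = x.cluster_families(pairs, hgt_ids)
print(f"\n{len(hgt_ids)} HGT candidates -> {len(partition)} families "
      "(single linkage, >= 60% identity):")
for fid, members in partition.families.items():
    print(f"  family {fid}: {', '.join(members)}")
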