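"""QC a plasmid pool from simulated long reads.

Simulates a skewed nanopore-style run over the 56-construct toy library
(one construct at 10x weight, 2% substitution errors), assigns reads by
diagnostic k-mer tags and reports depth, coverage rate and abundance.
"""

from promoswap import assign_reads, build_tag_index, coverage_report, golden_gate
from promoswap.fixtures import (
    ReadSimConfig, ToyGenomeSpec, build_toy_genome, make_basic_plasmid,
    make_promoter_parts, make_vector, simulate_reads,
)
from promoswap.pipeline import design_library

genome, anns = build_toy_genome(ToyGenomeSpec(n_genes=8, seed=7))
designs, _ = design_library(genome, anns)
vector = make_vector()
basics = [make_basic_plasmid(d.element, d.arms, vector) for d in designs.values()]
pool = golden_gate(basics, make_promoter_parts(6, seed=11))

ids = [p.id for p in pool.products]
weights = {cid: (10.0 if cid == ids[0] else 1.0) for cid in ids}
cfg = ReadSimConfig(abundance=weights, n_reads=2000, substitution_rate=0.02, seed=3)
reads = simulate_reads(pool, cfg)

index = build_tag_index(pool, k=31)
table = assign_reads(reads, index)
report = coverage_report(table, pool, reads)

n_assigned = int(table["promoter_state"].notna().sum())
print(f"reads assigned    : {n_assigned}/{len(table)} "
      f"({table['reason'].value_counts().to_dict()})")
print(f"overall mean depth: {report.overall_mean_depth:.2f}x")
print(f"coverage rate     : {report.overall_coverage_rate:.2f}%")
print(f"abundance CV      : {report.abundance_cv:.3f}")
top = report.per_construct.nlargest(3, "abundance")
print(top[["construct_id", "read_count", "mean_depth", "abundance"]].to_string(index=False))
# the 10x-weighted construct tops the abundance table; unassigned reads are
# those whose spacer or promoter tags were destroyed by substitutions —
# errors lower the assignment rate but never cross-assign.
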