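"""Design one scarless promoter-replacement construct for a toy gene.

Builds a seeded toy genome, picks the first gene, selects an sgRNA in the
promoter window, extracts SapI-free homology arms, and assembles the
500-bp synthetic gene block.
"""

from promoswap.fixtures import ToyGenomeSpec, build_toy_genome
from promoswap.pipeline import design_construct

genome, anns = build_toy_genome(ToyGenomeSpec(n_genes=1, seed=19))
d = design_construct(genome, anns[0], arm_len=162)

g = d.guide
print(f"target           : {anns[0].gene_id} ({anns[0].strand} strand)")
print(f"guide spacer+PAM : {g.spacer}+{g.pam} ({len(g.spacer + g.pam)} nt)")
print(f"cut position     : {g.cut_pos} (gene-relative; 0 = A of ATG)")
print(f"score / hits     : {g.score} / {g.hits}")
print(f"up arm           : [{d.arms.up_arm.start}, {d.arms.up_arm.end}]")
print(f"down arm         : [{d.arms.down_arm.start}, {d.arms.down_arm.end}]")
print(f"deleted promoter : {d.arms.deleted_interval}")
print(f"element length   : {len(d.element.sequence)} bp")
print("element layout   :", ", ".join(f"{n}[{a}:{b}]" for n, a, b in d.element.features))

# The cut sits inside the deleted native promoter, so the edited allele
# (native promoter gone) can no longer be cut; the element is 2*162+176 bp.
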