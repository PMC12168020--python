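# promoswap

Design automation and in-silico QC for **scarless CRISPR promoter-replacement
libraries** in yeast (built around *Yarrowia lipolytica*-style promoter
tuning of transcription factors, but genome-agnostic).

Tuning a gene's expression without touching its coding sequence means
swapping its native promoter for a stronger or weaker one — or deleting it
outright — at its exact start codon. `promoswap` automates the whole desk
side of that workflow:

1. **Guide design** — enumerate 20-nt spacer + NGG PAM candidates (23 bp
   total) in the promoter window, count genome-wide off-targets (Hamming
   ≤ 2, PAM-adjacent), score them with a transparent rule-based efficiency
   score, and select one guide per target whose blunt cut (3 bp 5′ of the
   PAM) falls within −200 bp of the start codon *and inside the interval
   that will be deleted*, so edited alleles cannot be re-cut.
2. **Construct design** — extract SapI-free homology arms (62 or 162 bp;
   the down arm fixed at the CDS start, the up arm at the distal end of the
   −500..0 window) and assemble the synthetic gene block:
   `gibson(20) · spacer(20) · linker(80) · up_arm · SapI-cassette(36) ·
   down_arm · gibson(20)` — 300 bp with 62-bp arms, 500 bp with 162-bp arms.
3. **Assembly simulation** — SapI (GCTCTTC, 1/4 geometry, 3-nt 5′
   overhangs) digestion, promoter-part flanking, and single-pot Golden Gate
   enumeration of the pooled library. The cassette's two outward-reading
   sites excise a stuffer and leave a programmable scar overhang upstream
   and the CDS's own **ATG** downstream — so the promoter junction at the
   CDS boundary is scarless and correct products, having lost every
   recognition site, are irreversible. Library diversity =
   targets × (promoters + deletion).
4. **Library QC** — assign simulated (or real, toy-scale) long reads to
   constructs by diagnostic k-mer tags (spacer 20-mers, promoter 31-mers,
   deletion-junction tags; both orientations) and report per-construct mean
   depth, coverage rate, and abundance.
5. **Screen statistics** — normalized betanin absorbance
   nAb = A535/OD600, percent change vs. control with hit ranking, and
   maximum specific growth rate µmax as the largest sliding-window OLS
   slope of ln(OD) versus time.

A deterministic fixtures module generates toy genomes, promoter parts,
plasmids, reads and plate data, so everything above is testable end to end
with no downloads.

## Worked example

```python
from promoswap.fixtures import ToyGenomeSpec, build_toy_genome
from promoswap.pipeline import design_construct

genome, anns = build_toy_genome(ToyGenomeSpec(n_genes=1, seed=19))
d = design_construct(genome, anns[0], arm_len=162)
```

Running `python examples/01_design_construct.py` prints:

```
target           : TF01 (+ strand)
guide spacer+PAM : AACCAACTCCTTCCATGACC+AGG (23 nt)
cut position     : -1 (gene-relative; 0 = A of ATG)
score / hits     : 100.0 / {0: 1, 1: 0, 2: 0}
up arm           : [-500, -339]
down arm         : [0, 161]
deleted promoter : (-338, -1)
element length   : 500 bp
```

The guide is unique in the genome (one perfect hit, the target itself),
its cut lies inside the native promoter that the 162-bp arms will delete,
and the finished gene block is exactly 2·162 + 176 = 500 bp. The other
examples build an 8-target × 7-state library (diversity 56), QC it from
2 000 simulated error-prone reads (100% coverage rate, the 10×-weighted
construct recovered at the top of the abundance table), and rank betanin
screen hits. Each `examples/*.py` script is a narrative walk through one
capability.

A thin CLI wraps the same functions:

```sh
promoswap fixtures genome --n-genes 4 --seed 7 --out-dir demo
promoswap design guides --genome demo/toy_genome.fa --gff demo/toy_genome.gff3 --out guides.tsv
promoswap assemble --genome demo/toy_genome.fa --gff demo/toy_genome.gff3 \
    --promoters promoters.fa --out pool.tsv
promoswap qc --genome ... --reads reads.fastq --out qc.tsv
promoswap screen nab --plate plate.tsv --control ctrl --out nab.tsv
```

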