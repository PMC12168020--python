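# Methods

This note documents the models and conventions behind `promoswap`: what is
simulated, which parameters matter, and where genuinely open design choices
were settled.

## Coordinates and sequence views

Genomic coordinates are 0-based half-open internally; GFF3 input (1-based
inclusive) is converted on load, and `GeneAnnotation` keeps the 1-based
values as parsed for direct comparison with the source file. All design
logic runs in **gene-relative coordinates**: position 0 is the first base
of the annotated start codon, upstream positions are negative (−1 is the
base immediately 5′ of the ATG). Minus-strand genes are viewed through a
reverse-complemented window (`OrientedLocus`) so "upstream" is always 5′
of the CDS; a plus-strand gene and its reverse-complemented twin produce
identical windows (tested). Windows containing `N` are rejected outright:
a synthetic design must be fully specified, and failing at locus creation
gives one clear error instead of several downstream ones.

## Guide model

Candidates are 20-nt spacers with an NGG PAM; the Cas9 cut is modeled as
blunt between spacer positions 17 and 18 (3 bp 5′ of the PAM) — standard
SpCas9 geometry. `cut_pos` is the gene-relative index of the first base 3′
of the cut on the top strand; minus-strand candidates are found by
scanning for CCN on the given strand and reported with spacer/PAM on their
own strand.

**Selection window.** The cut must fall in `[-200, -1]` by default. With
the default flag `require_cut_in_deletion`, the cut must additionally lie
inside the deleted promoter interval and the full 23-nt protospacer+PAM
must overlap it — after homologous recombination the target site is gone
and the edited allele cannot be re-cut.

**Efficiency score.** Web-tool on-target scores are not reproducible from
a rule description, so the score here is a deliberately transparent
stand-in that keeps the conventional "usable above 60" semantics: start at
100; −30 if spacer GC ∉ [0.40, 0.80]; −40 if the spacer contains `TTTT`
(Pol III terminator-like run); −20 per perfect genomic match beyond the
on-target site; floored at 0. The threshold is strict (`score > 60`).

**Off-targets** are counted exactly: both strands, PAM-adjacent NGG,
Hamming distance ≤ 2 (≤ 3 supported), including the on-target site in the
0-mismatch bin. The implementation is vectorized (numpy sliding windows);
tests compare it against an independent naive scan. Ranking is fully
deterministic: fewest extra perfect hits, fewest 1-mismatch hits, highest
score, smallest distance to the ATG, lexicographic spacer.

## Homology arms and the synthetic element

The down arm is fixed at gene-relative `[0, arm_len)` and must start with
ATG; a SapI site there is a hard "design-failed" error because that arm
cannot move. The up arm starts at the distal end of the upstream window
(`[-500, -500+arm_len)` by default) and slides 1 bp toward the ATG while
it contains a SapI site on either strand, as long as the deleted interval
stays non-empty. Fixing the down arm at the CDS and pushing the up arm
distal maximizes the deleted native-promoter span, which is what makes the
"cut inside the deletion" guarantee easy to satisfy.

The element layout is
`gibson_left(20) · spacer(20) · linker(80) · up_arm · cassette(36) ·
down_arm · gibson_right(20)`; the fixed regions total 176 bp by
construction, so element length is exactly `2·arm_len + 176` (300/500 bp
for 62/162-bp arms — a property tested for arbitrary arm lengths). The
internal composition of the fixed 136 bp between the Gibson arms is not
dictated by the chemistry, only its budget; the shipped linker stands in
for the sgRNA scaffold region and is a fixed SapI-free sequence, as are
the Gibson arms. All fixed sequences are configurable.

**The 36-bp cassette** carries two outward-reading SapI sites:
`o_up(3) · N · GAAGAGC · stuffer(17) · GCTCTTC · N`. With SapI's
GCTCTTC(1/4) geometry the forward site's cut lands exactly at the down-arm
boundary, making the CDS's own ATG the 3-nt overhang, and the reverse
site's cut lands at the cassette's first base, making `o_up` the upstream
overhang. The upstream scar defaults to `AAT`: non-palindromic (no
self-ligation), ≠ ATG (unambiguous insert orientation), configurable. The
finished element must contain exactly two recognition sites over both
strands; any variable part or junction that introduces another is an error
naming the offending feature.

## Digestion and ligation model

Every SapI cut is a bond pair (T, B = T+3); fragments are stored in
top-strand representation, spanning top-cut to top-cut, with each sticky
end recorded as the junction duplex 3-mer read on the top strand. Two ends
ligate when those 3-mers are equal — which is precisely reverse-complement
annealing of the physically protruding 5′ single strands; one convention,
used everywhere. Circular molecules with k sites give k fragments, linear
k+1 (terminal ends blunt); overlapping recognition footprints are
rejected. Ligation fidelity is ideal (exact pairs only), and any ligation
product retaining a recognition site is treated as re-digested by the
continued one-pot reaction — so stuffer re-ligations never appear and
correct products are irreversible (re-digestion returns them unchanged,
tested). Thermocycling parameters are protocol metadata, never simulated.

Products are linearized starting at the up arm so the diagnostic junction
`up_arm · o_up · core · ATG · down_arm[3:]` reads contiguously.
Library diversity is the count of distinct (target, promoter-state) pairs:
`T·(P+d)` with d = 1 when the deletion part (an explicit empty-core insert
joining `o_up` directly to ATG) is enabled. A basic plasmid that does not
digest into exactly one (ATG, o_up) backbone is reported "assembly-failed"
and excluded from diversity; a part whose overhangs match no backbone
raises a warning.

Gibson validation checks that the element's terminal 20-mers equal the
backbone junction 20-mers; overlap lengths are measured from the junction
inward, so a single mismatched outermost base reports 19/20 and fails.

## Library QC model

Alignment is replaced by exact k-mer tags, which is deterministic and
sufficient at toy scale: the guide spacer (20-mer, both orientations)
identifies the target; promoter identity is a majority vote over core
31-mers (k-mers shared between two promoter cores are dropped from both
sets at index time, no rescue); deletion variants are recognized by a
27-nt junction tag (12 bp of arm context on each side of the 3-nt scar)
that is contiguous only when no core intervenes. A read is assigned iff
exactly one spacer tag matches and the promoter vote has a strict winner
(or, with zero promoter evidence, the target's deletion tag is present);
everything else is unassigned with a reason code. Substitution errors
therefore lower the assignment rate but cannot cross-assign on pools with
pairwise-distinct tags (tested at 2% error).

Depth model: an assigned read covers `min(read length, construct length)`
consecutive positions of the circular construct starting at the position
inferred from its first spacer-tag match — full-length reads cover the
whole plasmid. Reported metrics: per-construct mean depth (covered bases /
length), coverage rate (% positions ≥ 1×), read count, and **abundance
defined as the assigned-read fraction** (the source protocol does not pin
down its abundance definition; ours is stated in the TSV header).
Pool-level: length-weighted overall depth and coverage rate, and the CV of
per-construct abundances.

## Screen statistics

`nAb = A535 / OD600` (scale-invariant in culture density; OD must be
positive, negative absorbances warn but pass through — blank correction is
the caller's responsibility and is recorded as a flag). Percent change is
`100·(sample − control)/control`; hits are ranked descending with
lexicographic strain-id tie-breaks and an `improved` flag.

µmax is estimated as the maximum over sliding windows (default 5 points)
of the OLS slope of ln(OD) versus time, using only points above an OD
floor (default 0; for real plates ~3× the blank SD is sensible — the
floor is a parameter because blank replicates are not part of the curve
container). On a noiseless exponential the estimator is exact; on 2%
multiplicative noise with hourly sampling it recovers the true rate within
10% (tested). Taking a max over windows biases the estimate slightly
upward under noise; denser sampling with the same window count per hour
amplifies this, which is why the generator defaults matter (below).

## Synthetic data generators

All generators are pure functions of (spec, seed) using one named
`numpy.random.default_rng` stream each; outputs are byte-identical across
calls (tested).

* **Toy genome** — genes on alternating strands in 900-bp blocks (560 bp
  upstream, 300-bp CDS, 40-bp gap), every CDS starting ATG, all design
  windows scrubbed of SapI sites, and (by default) one implanted unique
  guide site per gene whose cut falls at −100. `implant_sapi` writes
  recognition sites at chosen gene-relative positions for negative-path
  tests. This genome has no repeats, no N runs and near-uniform base
  composition — passing tests show the machinery is correct, not that real
  genomes always contain a usable guide or a SapI-free arm placement
  (which is exactly why those failure paths exist and are tested).
* **Promoter parts** — 6 SapI-free cores, 60–140 bp, pairwise sharing no
  31-mer. Real promoters are longer and can share motifs; shared k-mers
  are handled by the index-time drop rule.
* **Reads** — full-length (default) or truncated-uniform reads, 50/50
  orientation, i.i.d. substitutions at a configurable rate, constant Q20.
  No indels or homopolymer artifacts: sufficient to exercise tag voting,
  not a nanopore error model.
* **Plate data** — pure exponential growth curves (no lag or stationary
  phase) and proportional A535, with multiplicative Gaussian noise; at
  zero noise the generating (nAb, µmax) are recovered exactly.

## Problem sizes

The shipped tests and the acceptance script run the full chain at the
scale the method targets: a 60-target design round (the library pools 56
basic plasmids after 4 simulated cloning failures, × 7 promoter states =
392 constructs), an 8-target × 7-state pool (56 constructs) for QC
exercises, reads in the 10³–10⁴ range for abundance recovery, and 10-kb
genomes for brute-force oracle comparison. All are pure-Python/numpy desk
computations that complete in seconds.

## Known limitations

* The efficiency score is a stand-in; it preserves threshold semantics,
  not any trained model's rankings.
* Off-target search is exact Hamming ≤ 3 with a mandatory NGG — no bulges,
  no NAG PAMs, no genome-scale index.
* Ligation is ideal; overhang mismatch ligation and kinetics are out of
  scope, so simulated diversity is an upper bound on a real pool.
* Tag-based QC assumes pairwise-distinct spacers and promoter cores; it
  replaces, and does not approximate, read alignment at scale.
* Growth curves without a clear exponential phase above the floor give a
  µmax dominated by noise; the window/floor parameters are the lever.
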