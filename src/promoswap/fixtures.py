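"""Deterministic toy-data generators.

Everything downstream of the genome is testable without downloads: a toy
genome with annotated genes (each with a clean 500-bp upstream window, an
ATG-initiated CDS and, optionally, a guaranteed usable guide site),
SapI-free promoter parts of varying length, basic plasmids, simulated
long reads with a substitution-only error model, and plate-reader tables
with known ground truth.  Every generator is a pure function of its
(spec, seed) arguments; seeds are recorded in output headers where a file
format allows comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly_sim import LibraryPool, Plasmid, PromoterPart, make_part
from .construct_design import (
    ArmPair,
    ElementLayout,
    SyntheticElement,
    has_sapi_site,
)
from .errors import DesignError, QCError
from .sequence_model import GeneAnnotation, GenomeRef, revcomp

_BASES = np.array(list("ACGT"))

#: per-gene block geometry: 560 bp upstream + 300 bp CDS + 40 bp spacer gap
UPSTREAM_LEN = 560
CDS_LEN = 300
GAP_LEN = 40
BLOCK_LEN = UPSTREAM_LEN + CDS_LEN + GAP_LEN
#: implanted guide geometry: spacer at [-117, -98], TGG PAM at [-97, -95],
#: cut at gene-relative -100 (inside the default -200..-1 window)
_GUIDE_SPACER_POS = -117


@dataclass
class ToyGenomeSpec:
    """Parameters of the toy genome.

    ``implant_sapi`` lists (gene_index, gene_relative_pos) pairs at which a
    GCTCTTC site is written, for negative-path tests.  ``contig_length``
    defaults to exactly what ``n_genes`` blocks need.
    """

    n_genes: int = 56
    contig_length: int | None = None
    seed: int = 7
    guaranteed_pam: bool = True
    implant_sapi: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        needed = self.n_genes * BLOCK_LEN
        if self.contig_length is None:
            self.contig_length = needed
        if self.contig_length < needed:
            raise DesignError(
                f"contig too short for {self.n_genes} genes: need >= {needed} bp"
            )


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _scrub_sapi(arr: np.ndarray) -> None:
    """Destroy every SapI site in-place by rotating its middle base."""
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    s = "".join(arr)
    while has_sapi_site(s):
        for motif in ("GCTCTTC", "GAAGAGC"):
            i = s.find(motif)
            while i >= 0:
                arr[i + 3] = rot[arr[i + 3]]
                i = s.find(motif, i + 1)
        s = "".join(arr)


def _random_spacer(rng: np.random.Generator) -> str:
    """A 20-nt spacer with GC in [0.40, 0.80], no TTTT, SapI-free."""
    for _ in range(1000):
        sp = "".join(_random_dna(rng, 20))
        gc = (sp.count("G") + sp.count("C")) / 20
        if 0.40 <= gc <= 0.80 and "TTTT" not in sp and not has_sapi_site(sp):
            return sp
    raise RuntimeError("unreachable: spacer rejection loop exhausted")


def build_toy_genome(spec: ToyGenomeSpec) -> tuple[GenomeRef, list[GeneAnnotation]]:
    """In-memory toy genome: alternating-strand genes, ATG-initiated CDSs,
    SapI-free design windows, optional guaranteed guide sites."""
    rng = np.random.default_rng(spec.seed)
    implants = {}
    for gene_idx, pos in spec.implant_sapi:
        implants.setdefault(gene_idx, []).append(pos)

    contig_parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    offset = 0
    for i in range(spec.n_genes):
        gene_id = f"TF{i + 1:02d}"
        local = _random_dna(rng, UPSTREAM_LEN + CDS_LEN)  # gene-relative -560..299
        _scrub_sapi(local)
        local[UPSTREAM_LEN:UPSTREAM_LEN + 3] = list("ATG")
        if spec.guaranteed_pam:
            for _ in range(100):
                motif = _random_spacer(rng) + "TGG"
                lo = _GUIDE_SPACER_POS + UPSTREAM_LEN
                local[lo:lo + 23] = list(motif)
                around = "".join(local[lo - 7:lo + 30])
                if not has_sapi_site(around):
                    break
            else:
                raise RuntimeError("could not implant a SapI-free guide site")
        for pos in implants.get(i, []):
            lo = pos + UPSTREAM_LEN
            if lo < 0 or lo + 7 > len(local):
                raise DesignError(
                    f"implant_sapi position {pos} outside gene block of {gene_id}"
                )
            local[lo:lo + 7] = list("GCTCTTC")
        block = "".join(local)
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            contig_parts.append(block)
            a_pos = offset + UPSTREAM_LEN  # 0-based A of ATG
            ann = GeneAnnotation(gene_id, "chrT", "+", a_pos + 1, a_pos + CDS_LEN)
        else:
            contig_parts.append(revcomp(block))
            a_pos = offset + CDS_LEN - 1
            ann = GeneAnnotation(gene_id, "chrT", "-", a_pos + 1, offset + 1)
        annotations.append(ann)
        gap = _random_dna(rng, GAP_LEN)
        _scrub_sapi(gap)
        contig_parts.append("".join(gap))
        offset += BLOCK_LEN
    contig = "".join(contig_parts)
    pad = spec.contig_length - len(contig)
    if pad > 0:
        tail = _random_dna(rng, pad)
        _scrub_sapi(tail)
        contig += "".join(tail)
    return GenomeRef({"chrT": contig}), annotations


def make_toy_genome(spec: ToyGenomeSpec, out_dir) -> tuple[Path, Path]:
    """Write the toy genome as FASTA + GFF3; deterministic for a fixed spec."""
    genome, annotations = build_toy_genome(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "toy_genome.fa"
    gff = out_dir / "toy_genome.gff3"
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description=f"toy contig seed={spec.seed}")
         for name, seq in genome.contigs.items()],
        str(fasta), "fasta",
    )
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"# toy genome, seed={spec.seed}, n_genes={spec.n_genes}\n")
        for ann in annotations:
            lo, hi = sorted((ann.cds_start, ann.cds_end))
            fh.write(
                f"{ann.contig}\tpromoswap\tgene\t{lo}\t{hi}\t.\t{ann.strand}\t."
                f"\tID={ann.gene_id}\n"
            )
            fh.write(
                f"{ann.contig}\tpromoswap\tCDS\t{lo}\t{hi}\t.\t{ann.strand}\t0"
                f"\tID={ann.gene_id}.cds;Parent={ann.gene_id}\n"
            )
    return fasta, gff


def make_promoter_parts(
    n: int = 6,
    seed: int = 11,
    o_up: str = "AAT",
    min_len: int = 60,
    max_len: int = 140,
    k_distinct: int = 31,
) -> list[PromoterPart]:
    """SapI-free promoter cores of varying length, pairwise sharing no
    ``k_distinct``-mer (so tag-based QC can tell them apart)."""
    rng = np.random.default_rng(seed)
    lengths = np.linspace(min_len, max_len, n).astype(int)
    parts: list[PromoterPart] = []
    seen_kmers: set[str] = set()
    for i, length in enumerate(lengths):
        for _ in range(100):
            arr = _random_dna(rng, int(length))
            _scrub_sapi(arr)
            core = "".join(arr)
            kmers = {core[j:j + k_distinct] for j in range(len(core) - k_distinct + 1)}
            kmers |= {revcomp(km) for km in kmers}
            if not (kmers & seen_kmers):
                seen_kmers |= kmers
                parts.append(make_part(f"PR{i + 1:02d}", core, o_up))
                break
        else:
            raise RuntimeError("could not draw pairwise-distinct promoter cores")
    return parts


def make_vector(seed: int = 23, core_len: int = 360, layout: ElementLayout | None = None) -> str:
    """A linearized SapI-free plasmid backbone whose termini are the Gibson
    overlaps: it starts with the element's terminal 20-mer and ends with the
    element's leading 20-mer."""
    layout = layout or ElementLayout()
    rng = np.random.default_rng(seed)
    arr = _random_dna(rng, core_len)
    _scrub_sapi(arr)
    vector = layout.gibson_right_seq + "".join(arr) + layout.gibson_left_seq
    if has_sapi_site(vector):
        raise DesignError("vector backbone contains a SapI site")
    return vector


def make_basic_plasmid(
    element: SyntheticElement, arms: ArmPair, vector: str, o_up: str = "AAT"
) -> Plasmid:
    """Gibson-join an element with the backbone into a circular basic plasmid.

    The shared 20-mers merge, so the plasmid is element + vector-core; the
    construct metadata needed by downstream QC and locus reconstruction
    (spacer, arms, scar) travels in ``meta``.
    """
    if element.sequence[:20] != vector[-20:] or element.sequence[-20:] != vector[:20]:
        raise DesignError(
            f"{element.target_id}: element termini do not overlap the vector ends"
        )
    sequence = element.sequence + vector[20:-20]
    meta = {
        "target_id": element.target_id,
        "spacer": element.feature_seq("spacer"),
        "up_arm": arms.up_arm.seq,
        "up_arm_start": arms.up_arm.start,
        "down_arm": arms.down_arm.seq,
        "o_up": o_up,
    }
    return Plasmid(f"pBasic-{element.target_id}", sequence, circular=True, meta=meta)


@dataclass
class ReadSimConfig:
    """Simulated long-read run over a construct pool.

    ``abundance`` maps construct id ("target::promoter") to a sampling
    weight; ``read_length`` is "full" (whole-plasmid reads) or
    "truncated-uniform" (a uniform fraction of the circular plasmid from a
    random start).  Errors are i.i.d. substitutions; qualities constant Q20.
    """

    abundance: dict[str, float]
    n_reads: int
    read_length: str = "full"
    substitution_rate: float = 0.0
    min_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise QCError("n_reads must be positive")
        if not self.abundance:
            raise QCError("abundance map is empty")
        w = np.array(list(self.abundance.values()), dtype=float)
        if np.any(w < 0) or w.sum() == 0:
            raise QCError("abundance weights must be >= 0 and not all zero")
        if self.read_length not in ("full", "truncated-uniform"):
            raise QCError(f"unknown read_length model {self.read_length!r}")


def simulate_reads(
    pool: LibraryPool, cfg: ReadSimConfig, out_path=None
) -> list[SeqRecord]:
    """Draw reads from pool constructs proportionally to their weights.

    Orientations are emitted 50/50; substitution errors are i.i.d. at the
    configured rate.  Deterministic for a fixed config; optionally writes
    Phred+33 FASTQ.
    """
    products = {pr.id: pr for pr in pool.products}
    ids = list(cfg.abundance)
    missing = [i for i in ids if i not in products]
    if missing:
        raise QCError(f"abundance refers to unknown constructs: {missing[:3]}")
    weights = np.array([cfg.abundance[i] for i in ids], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(cfg.seed)
    choices = rng.choice(len(ids), size=cfg.n_reads, p=weights)

    records = []
    for ridx, cidx in enumerate(choices):
        cid = ids[cidx]
        seq = products[cid].sequence
        L = len(seq)
        if cfg.read_length == "truncated-uniform":
            span = max(50, int(rng.uniform(cfg.min_frac, 1.0) * L))
            start = int(rng.integers(L))
            seq = (seq + seq)[start:start + min(span, L)]
        arr = np.array(list(seq))
        if cfg.substitution_rate > 0:
            mask = rng.random(arr.size) < cfg.substitution_rate
            n_err = int(mask.sum())
            if n_err:
                cur = arr[mask]
                shift = rng.integers(1, 4, size=n_err)
                idx = np.searchsorted(_BASES, cur)
                arr[mask] = _BASES[(idx + shift) % 4]
        read_seq = "".join(arr)
        if rng.random() < 0.5:
            read_seq = revcomp(read_seq)
            orient = "-"
        else:
            orient = "+"
        rec = SeqRecord(
            Seq(read_seq),
            id=f"read{ridx:06d}",
            description=f"truth={cid} orient={orient}",
        )
        rec.letter_annotations["phred_quality"] = [20] * len(read_seq)
        records.append(rec)
    if out_path is not None:
        SeqIO.write(records, str(out_path), "fastq")
    return records


def simulate_plate(
    truth: dict[str, tuple[float, float]],
    noise: float = 0.0,
    seed: int = 0,
    t_max: float = 10.0,
    dt: float = 0.5,
    od0: float = 0.05,
    base_od: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plate tables consistent with known (nAb, µmax) per strain plus noise.

    Returns (plate_df with well/strain/od600/a535, growth_df with
    strain/time_h/od600).  Growth curves are pure exponentials
    od0 * exp(µ t) with multiplicative noise; at zero noise the generating
    values are recovered exactly.
    """
    rng = np.random.default_rng(seed)
    plate_rows, growth_rows = [], []
    times = np.arange(0.0, t_max + 1e-9, dt)
    for w, (strain, (nab, mu)) in enumerate(sorted(truth.items())):
        well = f"{chr(ord('A') + w // 12)}{w % 12 + 1}"
        od = base_od * (1.0 + noise * rng.standard_normal())
        a535 = nab * od * (1.0 + noise * rng.standard_normal())
        plate_rows.append((well, strain, od, a535))
        curve = od0 * np.exp(mu * times)
        curve = curve * (1.0 + noise * rng.standard_normal(times.size))
        for t, o in zip(times, curve):
            growth_rows.append((strain, t, max(o, 1e-9)))
    plate_df = pd.DataFrame(plate_rows, columns=["well", "strain", "od600", "a535"])
    growth_df = pd.DataFrame(growth_rows, columns=["strain", "time_h", "od600"])
    return plate_df, growth_df
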