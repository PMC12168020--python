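"""sgRNA enumeration, scoring, off-target counting and selection.

A candidate is a 20-nt spacer plus its 3-nt NGG PAM (23 nt total) whose
SpCas9 blunt cut — between spacer positions 17 and 18, i.e. 3 bp 5' of the
PAM — falls inside the configured promoter window upstream of the start
codon.  The efficiency score is a transparent rule-based stand-in for
web-tool scores (start at 100; -30 for spacer GC outside [0.40, 0.80];
-40 for a TTTT run; -20 per perfect genomic match beyond the on-target
site; floored at 0) keeping the conventional ">60" usable-guide threshold.

Coordinates are gene-relative (0 = A of the start codon).  ``cut_pos`` is
the gene-relative position of the first base 3' of the blunt cut on the
gene (top) strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DesignError
from .sequence_model import GenomeRef, OrientedLocus, revcomp

#: distance (nt) from the spacer 5' end to the blunt cut: cut between
#: spacer positions 17 and 18, i.e. 3 bp 5' of the PAM.
CUT_OFFSET = 17
#: flank (nt) the locus must cover beyond the scan window so that spacers
#: and PAMs of boundary cuts are fully inside the window.
SCAN_FLANK = 25


@dataclass
class GuideConfig:
    """Guide selection parameters.

    window_start/window_end bound the allowed cut position (gene-relative,
    inclusive); score_threshold is strict (score must exceed it); max_mm is
    the off-target Hamming radius; require_cut_in_deletion additionally
    demands that the cut lies inside the replaced promoter interval and the
    full protospacer+PAM overlaps it, so edited alleles cannot be re-cut.
    """

    window_start: int = -200
    window_end: int = -1
    score_threshold: float = 60.0
    max_mm: int = 2
    require_cut_in_deletion: bool = True

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end <= 0:
            raise DesignError(
                f"invalid guide window [{self.window_start}, {self.window_end}]"
            )


@dataclass
class GuideCandidate:
    target_id: str
    spacer: str
    pam: str
    strand_rel_gene: str
    protospacer_start: int  # gene-relative position of the spacer 5' end
    cut_pos: int
    distance_to_atg: int
    score: float | None = None
    hits: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise DesignError(f"spacer must be 20 nt, got {len(self.spacer)}")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise DesignError(f"PAM must be NGG, got {self.pam!r}")

    @property
    def protospacer_span(self) -> tuple[int, int]:
        """Inclusive gene-relative span of protospacer+PAM (23 nt)."""
        if self.strand_rel_gene == "+":
            return (self.protospacer_start, self.protospacer_start + 22)
        return (self.protospacer_start - 22, self.protospacer_start)


def scan_pams(locus: OrientedLocus, cfg: GuideConfig | None = None) -> list[GuideCandidate]:
    """Enumerate every NGG protospacer on either strand whose cut falls in
    the configured window.

    Minus-strand candidates are reported with spacer and PAM on that strand
    (the scan looks for CCN on the given strand).
    """
    cfg = cfg or GuideConfig()
    lo_needed = cfg.window_start - SCAN_FLANK
    hi_needed = cfg.window_end + SCAN_FLANK
    if -locus.u > lo_needed or locus.d - 1 < hi_needed:
        raise DesignError(
            f"locus {locus.gene_id}: window [-{locus.u}, {locus.d}) does not "
            f"cover scan range [{lo_needed}, {hi_needed}]"
        )
    seq, u = locus.window_seq, locus.u
    scan_lo = max(0, lo_needed + u)
    scan_hi = min(len(seq), hi_needed + u + 1)
    if "N" in seq[scan_lo:scan_hi]:
        raise DesignError(f"locus {locus.gene_id}: scan window contains N")

    out: list[GuideCandidate] = []
    for i in range(len(seq) - 22):
        # plus strand: spacer [i, i+20), PAM [i+20, i+23)
        if seq[i + 21] == "G" and seq[i + 22] == "G":
            cut = i + CUT_OFFSET - u
            if cfg.window_start <= cut <= cfg.window_end:
                out.append(GuideCandidate(
                    locus.gene_id, seq[i:i + 20], seq[i + 20:i + 23], "+",
                    protospacer_start=i - u, cut_pos=cut,
                    distance_to_atg=abs(cut),
                ))
        # minus strand: CCN at [i, i+3) then 20-nt protospacer complement
        if seq[i] == "C" and seq[i + 1] == "C":
            cut = i + 6 - u
            if cfg.window_start <= cut <= cfg.window_end:
                out.append(GuideCandidate(
                    locus.gene_id, revcomp(seq[i + 3:i + 23]),
                    revcomp(seq[i:i + 3]), "-",
                    protospacer_start=i + 22 - u, cut_pos=cut,
                    distance_to_atg=abs(cut),
                ))
    return out


def score_guide(c: GuideCandidate) -> float:
    """Deterministic rule-based efficiency score in [0, 100].

    Penalties: -30 if spacer GC fraction outside [0.40, 0.80]; -40 if the
    spacer contains TTTT; -20 per perfect-match genomic hit beyond the
    on-target site (requires ``c.hits``; absent hits count as unique).
    """
    score = 100.0
    gc = (c.spacer.count("G") + c.spacer.count("C")) / 20.0
    if not 0.40 <= gc <= 0.80:
        score -= 30
    if "TTTT" in c.spacer:
        score -= 40
    perfect = (c.hits or {}).get(0, 1)
    score -= 20 * max(0, perfect - 1)
    return max(score, 0.0)


_BASE_CODES = {b: np.uint8(ord(b)) for b in "ACGTN"}


def _hits_one_strand(seq: str, spacer: str, max_mm: int, counts: np.ndarray) -> None:
    if len(seq) < 23:
        return
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = sliding_window_view(arr, 23)
    g = _BASE_CODES["G"]
    pam_ok = (win[:, 21] == g) & (win[:, 22] == g)
    if not pam_ok.any():
        return
    sp = np.frombuffer(spacer.encode(), dtype=np.uint8)
    mm = (win[pam_ok, :20] != sp).sum(axis=1)
    for m in range(max_mm + 1):
        counts[m] += int((mm == m).sum())


def count_offtargets(spacer: str, genome: GenomeRef, max_mm: int = 2) -> dict[int, int]:
    """Genome-wide NGG-adjacent occurrence counts per Hamming distance.

    Both strands are scanned; the on-target site itself is included in the
    0-mismatch count.  N never matches any spacer base and voids the PAM.
    """
    if len(spacer) != 20:
        raise DesignError(f"spacer must be 20 nt, got {len(spacer)}")
    if max_mm > 3:
        raise DesignError("max_mm > 3 not supported at desk scale")
    counts = np.zeros(max_mm + 1, dtype=np.int64)
    for seq in genome.contigs.values():
        _hits_one_strand(seq, spacer, max_mm, counts)
        _hits_one_strand(revcomp(seq), spacer, max_mm, counts)
    return {m: int(counts[m]) for m in range(max_mm + 1)}


def select_guide(
    cands: list[GuideCandidate],
    cfg: GuideConfig | None = None,
    deleted_interval: tuple[int, int] | None = None,
) -> GuideCandidate:
    """Filter and rank candidates; return the single best guide.

    Filters: score strictly above threshold, cut inside the window, and —
    when require_cut_in_deletion is set and a deleted interval is supplied —
    cut inside the deleted interval with the full protospacer+PAM
    overlapping it.  Ranking: fewest extra perfect-match hits, then fewest
    1-mismatch hits, highest score, smallest distance to the ATG,
    lexicographic spacer.  Fully deterministic.
    """
    cfg = cfg or GuideConfig()
    if not cands:
        raise DesignError("no guide: empty candidate list")
    target_id = cands[0].target_id
    surviving = []
    for c in cands:
        score = c.score if c.score is not None else score_guide(c)
        if score <= cfg.score_threshold:
            continue
        if not cfg.window_start <= c.cut_pos <= cfg.window_end:
            continue
        if cfg.require_cut_in_deletion and deleted_interval is not None:
            lo, hi = deleted_interval
            if not lo <= c.cut_pos <= hi:
                continue
            span_lo, span_hi = c.protospacer_span
            if span_hi < lo or span_lo > hi:
                continue
        surviving.append((c, score))
    if not surviving:
        raise DesignError(f"no guide for target {target_id}: no candidate passes filters")

    def key(item):
        c, score = item
        hits = c.hits or {0: 1}
        return (
            max(0, hits.get(0, 1) - 1),
            hits.get(1, 0),
            -score,
            c.distance_to_atg,
            c.spacer,
        )

    best, best_score = min(surviving, key=key)
    best.score = best_score
    return best


def design_guide(
    locus: OrientedLocus,
    genome: GenomeRef,
    cfg: GuideConfig | None = None,
    deleted_interval: tuple[int, int] | None = None,
) -> GuideCandidate:
    """Scan, off-target-count, score and select one guide for a locus."""
    cfg = cfg or GuideConfig()
    cands = scan_pams(locus, cfg)
    if not cands:
        raise DesignError(f"no guide for target {locus.gene_id}: no PAM in window")
    for c in cands:
        c.hits = count_offtargets(c.spacer, genome, cfg.max_mm)
        c.score = score_guide(c)
    return select_guide(cands, cfg, deleted_interval)
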