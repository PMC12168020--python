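"""Homology-arm extraction and synthetic gene-block (element) assembly.

The element that gets synthesised and Gibson-cloned into the basic plasmid
has a fixed layout::

    gibson_left(20) | spacer(20) | linker(80) | up_arm | SapI cassette(36)
                    | down_arm | gibson_right(20)

The fixed regions total 176 bp, so the whole element is ``2*arm_len + 176``
bp: 300 bp with 62-bp arms, 500 bp with 162-bp arms.  The down arm starts
at the CDS (gene-relative 0, beginning with ATG); the up arm sits at the
distal end of the upstream window, and the native promoter between them is
the interval deleted and replaced by the inserted promoter.

The 36-bp cassette carries a double, outward-reading SapI site pair so that
digestion excises the internal stuffer and leaves two 3-nt 5' overhangs:
the configurable upstream scar ``o_up`` (default AAT) and the ATG of the
CDS — which is why promoter insertion is scarless at the CDS boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DesignError
from .guide_design import GuideCandidate
from .sequence_model import OrientedLocus, revcomp

SAPI_SITE = "GCTCTTC"
SAPI_SITE_RC = "GAAGAGC"

#: shipped default fixed sequences (SapI-free, no TTTT runs)
DEFAULT_GIBSON_LEFT = "TGTGTCTCAACAGATCGAGT"
DEFAULT_GIBSON_RIGHT = "TGTTCAACAGTGAGGGGACA"
DEFAULT_LINKER = (
    "TCAGCTTAAATCCTGATGGGGGCGATCTTCCTATGCCAAGC"
    "CAGGGTGAGGTCCATAGTACTAGTGATCGCCAAATATCC"
)
DEFAULT_STUFFER = "GGGTAAGTTGTTGCCGG"
DEFAULT_O_UP = "AAT"


def count_sapi_sites(seq: str, circular: bool = False) -> int:
    """Number of SapI recognition sites over both strands."""
    s = seq + seq[:6] if circular else seq
    return sum(
        1 for i in range(len(s) - 6)
        if s[i:i + 7] in (SAPI_SITE, SAPI_SITE_RC)
    )


def has_sapi_site(seq: str) -> bool:
    return SAPI_SITE in seq or SAPI_SITE_RC in seq


@dataclass
class Arm:
    """One homology arm: sequence plus its inclusive gene-relative interval."""

    seq: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start + 1:
            raise DesignError("arm sequence length disagrees with its interval")


@dataclass
class ArmPair:
    up_arm: Arm
    down_arm: Arm
    arm_len: int
    deleted_interval: tuple[int, int]  # inclusive gene-relative


def extract_arms(locus: OrientedLocus, arm_len: int = 162, window: int = 500) -> ArmPair:
    """Extract SapI-free up/down homology arms around the start codon.

    The down arm is fixed at gene-relative [0, arm_len) and must begin with
    ATG.  The up arm starts at the distal end of the upstream window
    (gene-relative -window) and slides 1 bp toward the ATG while it contains
    a SapI site, keeping the deleted promoter interval non-empty.
    """
    if locus.u < window or locus.d < arm_len:
        raise DesignError(
            f"{locus.gene_id}: locus window [-{locus.u}, {locus.d}) does not "
            f"cover [-{window}, {arm_len})"
        )
    down_seq = locus.slice(0, arm_len)
    if not down_seq.startswith("ATG"):
        raise DesignError(f"{locus.gene_id}: design-failed, down arm does not start with ATG")
    if "N" in down_seq:
        raise DesignError(f"{locus.gene_id}: design-failed, down arm contains N")
    if has_sapi_site(down_seq):
        raise DesignError(
            f"{locus.gene_id}: design-failed, SapI site in the fixed down arm"
        )
    start = -window
    while start + arm_len <= -1:
        up_seq = locus.slice(start, start + arm_len)
        if "N" in up_seq:
            raise DesignError(f"{locus.gene_id}: design-failed, up arm window contains N")
        if not has_sapi_site(up_seq):
            up = Arm(up_seq, start, start + arm_len - 1)
            deleted = (start + arm_len, -1)
            return ArmPair(up, Arm(down_seq, 0, arm_len - 1), arm_len, deleted)
        start += 1
    raise DesignError(
        f"{locus.gene_id}: design-failed, no SapI-free up-arm placement keeps "
        "a non-empty deleted interval"
    )


def build_cassette(o_up: str = DEFAULT_O_UP, stuffer: str = DEFAULT_STUFFER) -> str:
    """The 36-bp double-SapI cassette.

    Layout (top strand): ``o_up(3) N(1) GAAGAGC stuffer(17) GCTCTTC N(1)``.
    The reverse-orientation site cuts leftward leaving the o_up overhang at
    the up-arm junction; the forward site cuts rightward leaving the ATG of
    the down arm as the 3-nt overhang.
    """
    if len(o_up) != 3:
        raise DesignError("o_up overhang must be 3 nt")
    if o_up == "ATG":
        raise DesignError("o_up must differ from the ATG overhang")
    if len(stuffer) != 17:
        raise DesignError("cassette stuffer must be 17 nt")
    cassette = o_up + "A" + SAPI_SITE_RC + stuffer + SAPI_SITE + "A"
    if count_sapi_sites(cassette) != 2:
        raise DesignError("cassette must contain exactly two SapI sites")
    return cassette


@dataclass
class ElementLayout:
    """Fixed-region composition of the synthetic element.

    The fixed budget 2*gibson_len + spacer_len + linker_len + cassette_len
    must equal 176 bp so that element length is 2*arm_len + 176 (300 bp for
    62-bp arms, 500 bp for 162-bp arms).
    """

    gibson_len: int = 20
    spacer_len: int = 20
    linker_len: int = 80
    cassette_len: int = 36
    arm_len: int = 162
    gibson_left_seq: str = DEFAULT_GIBSON_LEFT
    gibson_right_seq: str = DEFAULT_GIBSON_RIGHT
    linker_seq: str = DEFAULT_LINKER
    o_up: str = DEFAULT_O_UP
    stuffer_seq: str = DEFAULT_STUFFER

    def __post_init__(self) -> None:
        if 2 * self.gibson_len + self.spacer_len + self.linker_len + self.cassette_len != 176:
            raise DesignError("fixed-region budget must total 176 bp")
        for name, seq, n in [
            ("gibson_left", self.gibson_left_seq, self.gibson_len),
            ("gibson_right", self.gibson_right_seq, self.gibson_len),
            ("linker", self.linker_seq, self.linker_len),
        ]:
            if len(seq) != n:
                raise DesignError(f"{name} must be {n} nt, got {len(seq)}")
            if has_sapi_site(seq):
                raise DesignError(f"{name} contains a SapI site")
        self.cassette_template = build_cassette(self.o_up, self.stuffer_seq)
        if len(self.cassette_template) != self.cassette_len:
            raise DesignError("cassette length disagrees with layout")

    @property
    def total_len(self) -> int:
        return 2 * self.arm_len + 176


@dataclass
class SyntheticElement:
    """The full gene-block: sequence plus an ordered feature layout.

    Feature intervals are 0-based half-open over the element sequence and
    tile it without gaps or overlaps.
    """

    target_id: str
    sequence: str
    features: list[tuple[str, int, int]]

    def feature_seq(self, name: str) -> str:
        for fname, start, end in self.features:
            if fname == name:
                return self.sequence[start:end]
        raise KeyError(name)


def build_element(
    guide: GuideCandidate,
    arms: ArmPair,
    layout: ElementLayout | None = None,
) -> SyntheticElement:
    """Concatenate the element and verify its invariants.

    Raises if any variable part (arms, spacer) introduces a SapI site or if
    a junction accidentally creates one: the finished element must carry
    exactly the cassette's two sites.
    """
    layout = layout or ElementLayout()
    if layout.arm_len != arms.arm_len:
        raise DesignError(
            f"layout arm_len {layout.arm_len} != extracted arm_len {arms.arm_len}"
        )
    if len(guide.spacer) != layout.spacer_len:
        raise DesignError("guide spacer length disagrees with layout")
    for name, seq in [
        ("spacer", guide.spacer), ("up_arm", arms.up_arm.seq),
        ("down_arm", arms.down_arm.seq),
    ]:
        if has_sapi_site(seq):
            raise DesignError(f"{guide.target_id}: feature {name} contains a SapI site")
    parts = [
        ("gibson_left", layout.gibson_left_seq),
        ("spacer", guide.spacer),
        ("linker", layout.linker_seq),
        ("up_arm", arms.up_arm.seq),
        ("sapi_cassette", layout.cassette_template),
        ("down_arm", arms.down_arm.seq),
        ("gibson_right", layout.gibson_right_seq),
    ]
    features, pos, chunks = [], 0, []
    for name, seq in parts:
        features.append((name, pos, pos + len(seq)))
        chunks.append(seq)
        pos += len(seq)
    sequence = "".join(chunks)
    if len(sequence) != layout.total_len:
        raise DesignError(
            f"{guide.target_id}: element length {len(sequence)} != {layout.total_len}"
        )
    n_sites = count_sapi_sites(sequence)
    if n_sites != 2:
        raise DesignError(
            f"{guide.target_id}: element carries {n_sites} SapI sites (expected 2); "
            "a junction or variable part introduced an extra site"
        )
    return SyntheticElement(guide.target_id, sequence, features)


def write_elements(elements: list[SyntheticElement], fasta_path, features_path) -> None:
    """Write elements as FASTA plus a sidecar feature TSV."""
    seen = set()
    for el in elements:
        if el.target_id in seen:
            raise DesignError(f"duplicate target_id {el.target_id!r}")
        seen.add(el.target_id)
    records = [
        SeqRecord(Seq(el.sequence), id=el.target_id, description="")
        for el in elements
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(features_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["target_id", "feature", "start", "end"])
        for el in elements:
            for name, start, end in el.features:
                w.writerow([el.target_id, name, start, end])


def read_elements(fasta_path, features_path) -> list[SyntheticElement]:
    """Read back elements written by :func:`write_elements`."""
    feats: dict[str, list[tuple[str, int, int]]] = {}
    with open(features_path) as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != ["target_id", "feature", "start", "end"]:
            raise DesignError(f"unexpected feature table header {header}")
        for tid, name, start, end in r:
            feats.setdefault(tid, []).append((name, int(start), int(end)))
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(SyntheticElement(rec.id, str(rec.seq).upper(), feats.get(rec.id, [])))
    return out
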