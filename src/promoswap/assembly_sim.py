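"""In-silico SapI digestion, Golden Gate ligation and Gibson validation.

SapI is a type-IIS enzyme: recognition GCTCTTC with (1/4) geometry — top
strand cut 1 nt 3' of the site, bottom strand 4 nt — leaving 3-nt 5'
overhangs.  Every cut is therefore a pair of bond coordinates (T, B=T+3)
and the junction duplex is the top-strand 3-mer ``seq[T:T+3]``.

Sticky ends are stored in *top-strand convention*: both the right end of
the upstream fragment and the left end of the downstream fragment carry
the same junction 3-mer.  Two ends ligate when their top-strand 3-mers are
equal, which is exactly reverse-complement annealing of the physically
protruding 5' single strands.  Ligation fidelity is ideal (exact pairs
only); products that retain a SapI site are treated as re-digested and
never survive the one-pot reaction, which is what makes correct assemblies
irreversible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .construct_design import (
    SAPI_SITE,
    SAPI_SITE_RC,
    SyntheticElement,
    count_sapi_sites,
)
from .errors import AssemblyError
from .sequence_model import OrientedLocus, revcomp


@dataclass
class Plasmid:
    id: str
    sequence: str
    circular: bool = True
    meta: dict | None = None


@dataclass
class Fragment:
    """A digestion fragment in top-strand representation.

    ``sequence`` spans from the top-strand cut on the left to the
    top-strand cut on the right; overhangs are junction 3-mers in
    top-strand convention ("" = blunt / molecule terminus).
    """

    sequence: str
    left_overhang: str = ""
    right_overhang: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        for ov in (self.left_overhang, self.right_overhang):
            if len(ov) not in (0, 3):
                raise AssemblyError(f"overhang must be 0 or 3 nt, got {ov!r}")


@dataclass
class PromoterPart:
    """A promoter insert flanked by outward-reading SapI sites.

    Digestion of ``flanked_seq`` releases one insert fragment with left
    overhang ``o_up`` and right overhang ATG; an empty ``core_seq`` is the
    promoter-deletion part, joining o_up directly to the ATG.
    """

    id: str
    core_seq: str
    flanked_seq: str
    o_up: str


@dataclass
class AssemblyProduct:
    target_id: str
    promoter_id: str  # promoter part id, or "DELETION"
    sequence: str  # circular product, top strand
    meta: dict | None = None

    @property
    def id(self) -> str:
        return f"{self.target_id}::{self.promoter_id}"


@dataclass
class LibraryPool:
    products: list[AssemblyProduct]
    diversity: int
    failures: list[tuple[str, str]] = field(default_factory=list)


def _find_sites(seq: str, circular: bool) -> list[tuple[int, int, int]]:
    """All SapI cuts as (rec_start, T, B) bond coordinates (mod L if circular)."""
    L = len(seq)
    scan = seq + seq[:10] if circular else seq
    sites = []
    for i in range(len(scan) - 6):
        if i >= L:  # origin-spanning copies only once
            break
        heptamer = scan[i:i + 7]
        if heptamer == SAPI_SITE:
            t, b = i + 8, i + 11
        elif heptamer == SAPI_SITE_RC:
            t, b = i - 4, i - 1
        else:
            continue
        if circular:
            sites.append((i, t % L, b % L if b % L else L))
        else:
            if t < 0 or b > L:
                warnings.warn(f"SapI site at {i} cuts beyond the molecule end; skipped")
                continue
            sites.append((i, t, b))
    # overlapping recognition sites cannot both be cut
    spans = sorted(s[0] for s in sites)
    for a, b in zip(spans, spans[1:]):
        if b - a < 7:
            raise AssemblyError(f"overlapping SapI recognition sites at {a} and {b}")
    return sites


def sapi_digest(p: Plasmid) -> list[Fragment]:
    """Digest a plasmid at every SapI site.

    Circular molecules with k sites yield k fragments; linear molecules
    yield k+1 (terminal ends blunt).  A molecule without sites is returned
    unchanged as a single fragment.
    """
    seq = p.sequence.upper()
    sites = _find_sites(seq, p.circular)
    L = len(seq)
    if not sites:
        return [Fragment(seq, circular=p.circular)]
    cuts = sorted(t for _, t, _ in sites)

    def junction(t: int) -> str:
        return (seq + seq[:3])[t:t + 3] if p.circular else seq[t:t + 3]

    frags = []
    if p.circular:
        for i, t in enumerate(cuts):
            t_next = cuts[(i + 1) % len(cuts)]
            top = seq[t:t_next] if t_next > t else seq[t:] + seq[:t_next]
            frags.append(Fragment(top, junction(t), junction(t_next)))
    else:
        bounds = [0] + cuts + [L]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            left = junction(a) if i > 0 else ""
            right = junction(b) if i < len(bounds) - 2 else ""
            frags.append(Fragment(seq[a:b], left, right))
    return frags


def make_part(part_id: str, core_seq: str, o_up: str = "AAT") -> PromoterPart:
    """Flank a SapI-free promoter core with outward-reading SapI sites.

    The flanked sequence digests into exactly one insert with overhangs
    (o_up, ATG).  An empty core builds the deletion part.
    """
    core_seq = core_seq.upper()
    if SAPI_SITE in core_seq or SAPI_SITE_RC in core_seq:
        raise AssemblyError(f"part {part_id}: core contains a SapI site")
    if len(o_up) != 3 or set(o_up) - set("ACGT"):
        raise AssemblyError(f"part {part_id}: o_up must be a 3-nt DNA string")
    if o_up == "ATG":
        raise AssemblyError(
            f"part {part_id}: o_up may not equal ATG (ambiguous insert orientation)"
        )
    flanked = "TT" + SAPI_SITE + "A" + o_up + core_seq + "ATG" + "A" + SAPI_SITE_RC + "TT"
    if count_sapi_sites(flanked) != 2:
        raise AssemblyError(
            f"part {part_id}: flanking created a stray SapI site at a junction"
        )
    part = PromoterPart(part_id, core_seq, flanked, o_up)
    insert = part_insert(part)  # validates digestion geometry
    if insert.left_overhang != o_up or insert.right_overhang != "ATG":
        raise AssemblyError(f"part {part_id}: digestion does not yield ({o_up}, ATG)")
    return part


def part_insert(part: PromoterPart) -> Fragment:
    """The single insert fragment released by digesting the flanked part."""
    frags = sapi_digest(Plasmid(part.id, part.flanked_seq, circular=False))
    inner = [f for f in frags if f.left_overhang and f.right_overhang]
    if len(inner) != 1:
        raise AssemblyError(
            f"part {part.id}: expected exactly one internal fragment, got {len(inner)}"
        )
    return inner[0]


def ligate_circular(a: Fragment, b: Fragment) -> str:
    """Circularize two fragments joined at both junctions.

    Requires a.right == b.left and b.right == a.left in top-strand
    convention (i.e. both pairs of protruding strands are reverse
    complements).
    """
    if not (a.right_overhang and a.right_overhang == b.left_overhang
            and b.right_overhang and b.right_overhang == a.left_overhang):
        raise AssemblyError(
            f"overhangs do not pair: ({a.left_overhang},{a.right_overhang}) x "
            f"({b.left_overhang},{b.right_overhang})"
        )
    return a.sequence + b.sequence


def golden_gate(
    basic: list[Plasmid],
    parts: list[PromoterPart],
    include_deletion: bool = True,
    o_up: str = "AAT",
) -> LibraryPool:
    """Enumerate the single-pot Golden Gate library.

    Each basic plasmid must digest into exactly one backbone fragment with
    overhangs (ATG, o_up) — ATG on its left (the CDS-side junction), o_up on
    its right (the up-arm-side junction).  Every part insert with matching
    overhangs ligates into every compatible backbone; products are verified
    SapI-free (re-ligations of the stuffer regenerate sites and are removed
    by continued digestion, so they never appear).  Diversity is the number
    of distinct (target, promoter-state) products.
    """
    all_parts = list(parts)
    if include_deletion:
        all_parts.append(make_part("DELETION", "", o_up))

    backbones: list[tuple[Plasmid, Fragment]] = []
    failures: list[tuple[str, str]] = []
    for p in basic:
        target_id = (p.meta or {}).get("target_id", p.id)
        frags = sapi_digest(p)
        cands = [
            f for f in frags
            if f.left_overhang == "ATG" and f.right_overhang == o_up
        ]
        if len(cands) != 1:
            failures.append((target_id, "assembly-failed: no unique (ATG, %s) backbone" % o_up))
            continue
        backbones.append((p, cands[0]))

    products: list[AssemblyProduct] = []
    for part in all_parts:
        insert = part_insert(part)
        n_before = len(products)
        for p, bb in backbones:
            if bb.right_overhang != insert.left_overhang or \
               insert.right_overhang != bb.left_overhang:
                continue
            seq = ligate_circular(bb, insert)
            if count_sapi_sites(seq, circular=True) != 0:
                raise AssemblyError(
                    f"product {p.id} x {part.id} retains a SapI site"
                )
            target_id = (p.meta or {}).get("target_id", p.id)
            meta = dict(p.meta or {})
            meta["core"] = part.core_seq
            # linearize the circular product at the up-arm start so the
            # promoter junction up_arm.o_up.core.ATG reads contiguously
            up_arm = meta.get("up_arm")
            if up_arm:
                idx = seq.find(up_arm)
                if idx >= 0:
                    seq = seq[idx:] + seq[:idx]
            products.append(AssemblyProduct(target_id, part.id, seq, meta))
        if len(products) == n_before:
            warnings.warn(f"part {part.id} is incompatible with every backbone")

    diversity = len({(pr.target_id, pr.promoter_id) for pr in products})
    return LibraryPool(products, diversity, failures)


@dataclass
class GibsonReport:
    passed: bool
    left_overlap: int
    right_overlap: int
    reason: str = ""


def _common_suffix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def gibson_check(
    element: SyntheticElement,
    backbone_left: str,
    backbone_right: str,
) -> GibsonReport:
    """Validate the element's 20-bp terminal Gibson overlaps.

    The element's first 20-mer must equal the last 20 bases of the left
    backbone junction and its last 20-mer the first 20 of the right one.
    Overlap lengths are measured from the junction inward, so a mismatched
    outermost terminal base reports 19.
    """
    seq = element.sequence
    if len(seq) < 40:
        return GibsonReport(False, 0, 0, "too short: element under 40 nt")
    left = _common_suffix(seq[:20], backbone_left[-20:])
    right = _common_prefix(seq[-20:], backbone_right[:20])
    passed = left == 20 and right == 20
    reason = "" if passed else "terminal 20-mers do not match the backbone junctions"
    return GibsonReport(passed, left, right, reason)


def reconstruct_edited_locus(product: AssemblyProduct, locus: OrientedLocus) -> str:
    """Predicted post-HR genomic sequence at the target locus.

    Reads upstream context, the up arm, the 3-nt scar, the inserted core
    (empty for deletions), then the CDS from its original ATG onward: the
    CDS boundary is scarless by construction.  Requires the product to
    carry arm metadata (up_arm sequence and gene-relative interval, o_up).
    """
    meta = product.meta or {}
    for key in ("up_arm", "up_arm_start", "o_up"):
        if key not in meta:
            raise AssemblyError(f"product {product.id}: missing meta[{key!r}]")
    up_arm, o_up, core = meta["up_arm"], meta["o_up"], meta.get("core", "")
    junction = up_arm + o_up + core + "ATG"
    doubled = product.sequence + product.sequence
    if junction not in doubled:
        raise AssemblyError(
            f"product {product.id}: junction mismatch, expected "
            "up_arm + o_up + core + ATG in the circular product"
        )
    idx = meta["up_arm_start"] + locus.u
    if idx < 0:
        raise AssemblyError(f"product {product.id}: up arm outside the locus window")
    edited = locus.window_seq[:idx] + up_arm + o_up + core + locus.window_seq[locus.u:]
    cds_at = idx + len(up_arm) + 3 + len(core)
    if edited[cds_at:cds_at + 3] != "ATG":
        raise AssemblyError(f"product {product.id}: CDS start not intact after edit")
    return edited
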