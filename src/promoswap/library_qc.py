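"""Long-read library QC: tag-based read assignment and coverage metrics.

Reads are assigned to (target, promoter-state) constructs by exact k-mer
tags instead of alignment: the target-specific 20-nt guide spacer
identifies the target, a majority vote over promoter-specific 31-mers
identifies the inserted promoter, and a junction tag spanning
up_arm·o_up·ATG identifies promoter deletions.  Both read orientations
are searched (reverse-complement tags are indexed).

Reported metrics follow the usual per-reference definitions: mean depth =
assigned bases / construct length, coverage rate = percent of positions
covered at least once, and abundance = assigned-read fraction (the
abundance definition is also stated in the TSV header).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .assembly_sim import LibraryPool
from .errors import QCError
from .sequence_model import revcomp

SPACER_LEN = 20
JUNCTION_FLANK = 12  # bases of arm context on each side of the deletion scar


@dataclass
class TagIndex:
    k: int
    spacer_tags: dict[str, str]  # 20-mer (both orientations) -> target_id
    promoter_kmers: dict[str, str]  # k-mer (both orientations) -> promoter_id
    deletion_tags: dict[str, str]  # junction tag (both orientations) -> target_id
    deletion_tag_len: int
    pool_pairs: set[tuple[str, str]]


def build_tag_index(pool: LibraryPool, k: int = 31) -> TagIndex:
    """Derive diagnostic tags from an enumerated library pool.

    Promoter k-mers shared between two promoters are dropped from both tag
    sets (with a warning); a 20-mer spacer shared by two targets or two
    constructs with identical sequence are hard errors.
    """
    if not pool.products:
        raise QCError("empty pool: no constructs to index")
    seqs = {}
    for pr in pool.products:
        if pr.sequence in seqs:
            raise QCError(
                f"constructs {seqs[pr.sequence]} and {pr.id} are identical in sequence"
            )
        seqs[pr.sequence] = pr.id

    spacer_tags: dict[str, str] = {}
    for pr in pool.products:
        spacer = (pr.meta or {}).get("spacer")
        if not spacer or len(spacer) != SPACER_LEN:
            raise QCError(f"construct {pr.id}: missing or malformed spacer metadata")
        for tag in (spacer, revcomp(spacer)):
            prev = spacer_tags.get(tag)
            if prev is not None and prev != pr.target_id:
                raise QCError(
                    f"spacer tag shared by targets {prev} and {pr.target_id}"
                )
            spacer_tags[tag] = pr.target_id

    # promoter k-mer sets from insert cores, collisions dropped
    cores: dict[str, str] = {}
    for pr in pool.products:
        if pr.promoter_id != "DELETION":
            cores.setdefault(pr.promoter_id, (pr.meta or {}).get("core", ""))
    kmer_owner: dict[str, set[str]] = {}
    for pid, core in cores.items():
        for strand_seq in (core, revcomp(core)):
            for i in range(max(0, len(strand_seq) - k + 1)):
                kmer_owner.setdefault(strand_seq[i:i + k], set()).add(pid)
    promoter_kmers = {}
    n_dropped = 0
    for kmer, owners in kmer_owner.items():
        if len(owners) == 1:
            promoter_kmers[kmer] = next(iter(owners))
        else:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"{n_dropped} promoter k-mers shared between promoters were dropped"
        )

    deletion_tags: dict[str, str] = {}
    tag_len = 2 * JUNCTION_FLANK + 3
    for pr in pool.products:
        if pr.promoter_id != "DELETION":
            continue
        meta = pr.meta or {}
        up, o_up, down = meta.get("up_arm"), meta.get("o_up"), meta.get("down_arm")
        if not (up and o_up and down):
            raise QCError(f"construct {pr.id}: missing arm metadata for deletion tag")
        tag = up[-JUNCTION_FLANK:] + o_up + down[:JUNCTION_FLANK]
        for t in (tag, revcomp(tag)):
            prev = deletion_tags.get(t)
            if prev is not None and prev != pr.target_id:
                raise QCError(f"deletion junction tag shared by {prev} and {pr.target_id}")
            deletion_tags[t] = pr.target_id

    pairs = {(pr.target_id, pr.promoter_id) for pr in pool.products}
    return TagIndex(k, spacer_tags, promoter_kmers, deletion_tags, tag_len, pairs)


def _parse_fastq(reads):
    """Yield (read_id, sequence) from a FASTQ path or SeqRecord iterable."""
    if isinstance(reads, (str, Path)):
        n = 0
        try:
            for rec in SeqIO.parse(str(reads), "fastq"):
                n += 1
                yield rec.id, str(rec.seq).upper()
        except ValueError as exc:
            from .errors import ParseError

            raise ParseError(f"malformed FASTQ near record {n + 1}: {exc}") from exc
    else:
        for rec in reads:
            yield rec.id, str(rec.seq).upper()


def assign_reads(reads, index: TagIndex) -> pd.DataFrame:
    """Assign each read to at most one (target, promoter-state).

    A read is assigned iff exactly one spacer tag matches and the promoter
    k-mer vote has a strict winner (or, with zero promoter evidence, the
    target's deletion junction tag is present).  Anything else is
    unassigned with a reason code.  Columns: read_id, target_id,
    promoter_state, spacer_tag_hits, promoter_tag_hits, reason.
    """
    rows = []
    k, jlen = index.k, index.deletion_tag_len
    for read_id, seq in _parse_fastq(reads):
        targets = set()
        n_spacer_hits = 0
        for i in range(len(seq) - SPACER_LEN + 1):
            t = index.spacer_tags.get(seq[i:i + SPACER_LEN])
            if t is not None:
                targets.add(t)
                n_spacer_hits += 1
        votes: Counter = Counter()
        for i in range(len(seq) - k + 1):
            p = index.promoter_kmers.get(seq[i:i + k])
            if p is not None:
                votes[p] += 1
        n_prom_hits = sum(votes.values())

        target = promoter = None
        reason = ""
        if len(targets) == 0:
            reason = "no-target"
        elif len(targets) > 1:
            reason = "ambiguous-target"
        else:
            target = next(iter(targets))
            ranked = votes.most_common(2)
            if ranked and (len(ranked) == 1 or ranked[0][1] > ranked[1][1]):
                promoter = ranked[0][0]
            elif ranked:
                reason = "ambiguous-promoter"
            else:
                has_junction = any(
                    index.deletion_tags.get(seq[i:i + jlen]) == target
                    for i in range(len(seq) - jlen + 1)
                )
                if has_junction:
                    promoter = "DELETION"
                else:
                    reason = "no-promoter-evidence"
            if promoter is not None and (target, promoter) not in index.pool_pairs:
                promoter = None
                reason = "not-in-pool"
        if promoter is None:
            target_out = None
        else:
            target_out = target
        rows.append((read_id, target_out, promoter, n_spacer_hits, n_prom_hits, reason))
    return pd.DataFrame(
        rows,
        columns=["read_id", "target_id", "promoter_state",
                 "spacer_tag_hits", "promoter_tag_hits", "reason"],
    )


@dataclass
class CoverageReport:
    """Per-construct and pool-level coverage/abundance metrics."""

    per_construct: pd.DataFrame
    overall_mean_depth: float
    overall_coverage_rate: float
    abundance_cv: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# abundance = fraction of assigned reads per construct\n")
            fh.write("# depth model: each assigned read covers min(read, construct) "
                     "bases from its inferred start (circular)\n")
            self.per_construct.to_csv(fh, sep="\t", index=False)


def coverage_report(
    assignments: pd.DataFrame, pool: LibraryPool, reads
) -> CoverageReport:
    """Compute mean depth, positional coverage rate and abundance.

    Depth model: an assigned read covers ``min(read length, construct
    length)`` consecutive positions of the circular construct, starting at
    the position inferred from its first spacer-tag match.
    """
    products = {pr.id: pr for pr in pool.products}
    read_seqs = {rid: seq for rid, seq in _parse_fastq(reads)}
    depth = {pid: np.zeros(len(pr.sequence), dtype=np.int64)
             for pid, pr in products.items()}
    counts: Counter = Counter()

    assigned = assignments.dropna(subset=["target_id", "promoter_state"])
    for row in assigned.itertuples(index=False):
        pid = f"{row.target_id}::{row.promoter_state}"
        pr = products.get(pid)
        if pr is None:
            raise QCError(f"assignment to unknown construct {pid}")
        seq = read_seqs[row.read_id]
        L = len(pr.sequence)
        spacer = (pr.meta or {}).get("spacer", "")
        c_pos = pr.sequence.find(spacer) if spacer else -1
        start = 0
        for oriented in (seq, revcomp(seq)):
            r_pos = oriented.find(spacer) if spacer else -1
            if r_pos >= 0 and c_pos >= 0:
                start = (c_pos - r_pos) % L
                break
        span = min(len(seq), L)
        arr = depth[pid]
        end = start + span
        if end <= L:
            arr[start:end] += 1
        else:
            arr[start:] += 1
            arr[:end - L] += 1
        counts[pid] += 1

    total_assigned = sum(counts.values())
    rows = []
    for pid, pr in sorted(products.items()):
        arr = depth[pid]
        n = counts.get(pid, 0)
        rows.append({
            "construct_id": pid,
            "target_id": pr.target_id,
            "promoter_state": pr.promoter_id,
            "length": len(pr.sequence),
            "read_count": n,
            "mean_depth": float(arr.mean()),
            "coverage_rate_pct": float(100.0 * (arr >= 1).mean()),
            "abundance": (n / total_assigned) if total_assigned else 0.0,
            "flag": "" if n else "no-reads",
        })
    df = pd.DataFrame(rows)
    total_len = int(df["length"].sum())
    covered = sum(int((depth[pid] >= 1).sum()) for pid in products)
    total_bases = sum(int(depth[pid].sum()) for pid in products)
    ab = df["abundance"].to_numpy()
    cv = float(ab.std() / ab.mean()) if total_assigned and ab.mean() > 0 else float("nan")
    return CoverageReport(
        per_construct=df,
        overall_mean_depth=total_bases / total_len if total_len else 0.0,
        overall_coverage_rate=100.0 * covered / total_len if total_len else 0.0,
        abundance_cv=cv,
    )
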