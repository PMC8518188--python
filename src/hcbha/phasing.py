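"""Alignment-free read phasing: assigning reads to candidate bins.

Each bin's contigs are indexed by canonical window minimizers; a read is
assigned to the bin sharing the most distinct minimizers with it, provided
the best score clears a minimum and the runner-up is not too close (tie
ratio). Short-read mates are scored jointly so pairs never split across
bins. Unassigned reads carry forward as the remaining dataset of the next
iteration; read subtraction removes the reads consumed by accepted
genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._seq import minimizer_hash_set, minimizers
from .binning import CandidateBin, LEFTOVER_BIN
from .io_core import ContigSeq, ReadSet

logger = logging.getLogger("hcbha")

UNASSIGNED = "UNASSIGNED"


@dataclass
class MinimizerIndex:
    """Map from canonical minimizer hash to the bins containing it."""

    k: int = 15
    w: int = 10
    entries: dict[int, list[tuple[str, str, int]]] = field(
        default_factory=dict)  # hash -> [(bin id, contig id, position)]
    bin_sets: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.k % 2 == 0:
            raise ValueError("k must be odd (strand-symmetric canonical "
                             "k-mers)")


@dataclass
class ReadAssignment:
    """Per read (or pair): winning bin, score and runner-up score."""

    assignments: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def bin_of(self, read_id: str) -> str:
        return self.assignments.get(read_id, (UNASSIGNED, 0, 0))[0]

    def reads_of_bin(self, bin_id: str) -> set[str]:
        return {r for r, (b, _, _) in self.assignments.items() if b == bin_id}


def build_minimizer_index(bins: list[CandidateBin],
                          contigs: dict[str, ContigSeq],
                          k: int = 15, w: int = 10,
                          include_leftover: bool = False) -> MinimizerIndex:
    """Index the canonical minimizers of every bin's contigs."""
    if not bins:
        raise ValueError("no bins to index")
    idx = MinimizerIndex(k=k, w=w)
    indexed = 0
    for b in bins:
        if b.id == LEFTOVER_BIN and not include_leftover:
            continue
        bset = idx.bin_sets.setdefault(b.id, set())
        for cid in b.contig_ids:
            seq = contigs[cid].bases
            if len(seq) < k:
                continue
            for pos, h in minimizers(seq, k, w):
                idx.entries.setdefault(h, []).append((b.id, cid, pos))
                bset.add(h)
                indexed += 1
    if indexed == 0:
        raise ValueError("no contig long enough to index (all < k)")
    return idx


def _pair_key(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def _score_bins(seq: str, idx: MinimizerIndex, counts: dict[str, int]) -> None:
    for h in minimizer_hash_set(seq, idx.k, idx.w):
        entry = idx.entries.get(h)
        if entry is None:
            continue
        seen = set()
        for bid, _, _ in entry:
            if bid not in seen:
                seen.add(bid)
                counts[bid] = counts.get(bid, 0) + 1


def assign_reads(rs: ReadSet, idx: MinimizerIndex, *,
                 min_score: int = 3,
                 tie_ratio: float = 0.8) -> ReadAssignment:
    """Assign each read (mate pairs jointly) to its best-matching bin.

    The score is the number of distinct canonical minimizers shared with
    the bin (summed over mates for pairs). A read is assigned iff
    score >= min_score and runner_up <= tie_ratio * score; exact ties and
    weak hits stay UNASSIGNED.
    """
    # group mate pairs
    groups: dict[str, list] = {}
    for r in rs:
        groups.setdefault(_pair_key(r.id) if r.mate else r.id, []).append(r)
    out = ReadAssignment()
    for key, members in groups.items():
        counts: dict[str, int] = {}
        for r in members:
            _score_bins(r.bases, idx, counts)
        if not counts:
            best_bin, score, runner = UNASSIGNED, 0, 0
        else:
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            best_bin, score = ranked[0]
            runner = ranked[1][1] if len(ranked) > 1 else 0
            if score < min_score or runner > tie_ratio * score:
                best_bin = UNASSIGNED
        for r in members:
            out.assignments[r.id] = (best_bin, score, runner)
    return out


def assignments_from_paf(path, contig_to_bin: dict[str, str], *,
                         min_match: int = 100,
                         tie_ratio: float = 0.8) -> ReadAssignment:
    """External-aligner backend: derive bin assignments from a PAF file.

    Reads standard minimap2 PAF columns 1-12; per read the matching-base
    counts (column 10) are summed per bin, and the same argmax/tie rule
    as the minimizer path decides the assignment.
    """
    scores: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            read_id, target, matches = f[0], f[5], int(f[9])
            bin_id = contig_to_bin.get(target)
            if bin_id is None:
                continue
            d = scores.setdefault(read_id, {})
            d[bin_id] = d.get(bin_id, 0) + matches
    out = ReadAssignment()
    for read_id, counts in scores.items():
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        best, score = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0
        if score < min_match or runner > tie_ratio * score:
            best = UNASSIGNED
        out.assignments[read_id] = (best, score, runner)
    return out


def subtract_reads(rs: ReadSet, consumed_ids: set[str]) -> ReadSet:
    """Remove consumed reads from a read set (order preserved).

    IDs not present in the set are logged and ignored.
    """
    present = rs.ids()
    missing = consumed_ids - present
    if missing:
        logger.debug("subtract_reads: %d consumed ids not in read set",
                     len(missing))
    return ReadSet([r for r in rs if r.id not in consumed_ids])
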