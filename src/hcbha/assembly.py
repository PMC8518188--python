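"""Per-bin hybrid assembly: mini OLC backend, polishing, contiguity, promotion.

The built-in backend is a deliberately desk-scale overlap-layout-consensus
assembler for error-prone long reads: all-vs-all candidate overlaps are
found by shared-minimizer diagonal chaining, contained reads removed,
greedy best-overlap non-branching paths laid out with edit-distance
junction refinement, and a per-column plurality pileup consensus called
over all reads mapped back to the backbone. Circularity is detected when
the layout wraps onto its own start. Around the backend sit the
short-read pileup polisher, a long-read bridging contiguity enhancer, and
a coverage/composition outlier filter that promotes bin accuracy.
Real-scale runs plug in external assemblers through the backend contract.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Protocol

import edlib
import numpy as np

from ._seq import cigar_stats, minimizers_with_strand, parse_cigar, revcomp
from .io_core import ContigSeq, ReadSet

logger = logging.getLogger("hcbha")

OLC_K = 13   # k-mer size for error-prone overlap detection
OLC_W = 8    # minimizer window

_B2C = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _B2C[_b] = _i


class BinCollapseError(RuntimeError):
    """All contigs of a bin were rejected by the accuracy promoter."""


# ---------------------------------------------------------------------------
# anchors and chaining


def _cluster_anchors(pairs: list[tuple[int, int]],
                     band_base: float = 200.0, band_frac: float = 0.12):
    """Dominant colinear band of (qpos, tpos) anchors.

    Returns (offset, score, q_span, q_lo, q_hi, t_lo, t_hi) of the densest
    diagonal band, or None. Offset is the median t - q of kept anchors.
    """
    if not pairs:
        return None
    diags = sorted(t - q for q, t in pairs)
    med = diags[len(diags) // 2]
    span_guess = max(q for q, _ in pairs) - min(q for q, _ in pairs) + 1
    band = band_base + band_frac * span_guess
    kept = [(q, t) for q, t in pairs if abs((t - q) - med) <= band]
    if not kept:
        return None
    # re-center once on the kept anchors
    diags = sorted(t - q for q, t in kept)
    med = diags[len(diags) // 2]
    kept = [(q, t) for q, t in pairs if abs((t - q) - med) <= band]
    qs = [q for q, _ in kept]
    ts = [t for _, t in kept]
    return (med, len(kept), max(qs) - min(qs) + OLC_K,
            min(qs), max(qs) + OLC_K, min(ts), max(ts) + OLC_K)


def _cluster_anchors_multi(pairs: list[tuple[int, int]],
                           min_count: int = 5,
                           split_gap: float = 800.0):
    """All colinear bands of (qpos, tpos) anchors with >= min_count members.

    Unlike the single-band variant this keeps every diagonal band — a read
    crossing a circular origin or bridging two contigs produces several.
    """
    if not pairs:
        return []
    by_diag = sorted(pairs, key=lambda p: p[1] - p[0])
    groups: list[list[tuple[int, int]]] = [[by_diag[0]]]
    for p in by_diag[1:]:
        if (p[1] - p[0]) - (groups[-1][-1][1] - groups[-1][-1][0]) > split_gap:
            groups.append([p])
        else:
            groups[-1].append(p)
    out = []
    for g in groups:
        if len(g) < min_count:
            continue
        cl = _cluster_anchors(g)
        if cl is not None and cl[1] >= min_count:
            out.append(cl)
    return out


# ---------------------------------------------------------------------------
# overlap detection


@dataclass
class OverlapGraph:
    """All-vs-all read overlaps: adjacency in each read's forward frame.

    adj[a] holds (b, orient_b, offset, score, span): oriented read b starts
    at ``offset`` in a's forward coordinates.
    """

    n_reads: int
    lengths: list[int]
    adj: dict[int, list[tuple[int, str, int, int, int]]] = field(
        default_factory=dict)
    contained: set[int] = field(default_factory=set)

    def neighbors(self, idx: int, orient: str):
        """Neighbors of oriented read (idx, orient) in its own frame."""
        raw = self.adj.get(idx, [])
        if orient == "+":
            return raw
        L = self.lengths[idx]
        return [(b, "-" if o == "+" else "+",
                 L - off - self.lengths[b], sc, sp)
                for b, o, off, sc, sp in raw]


def build_overlap_graph(reads: list, min_overlap: int = 500,
                        min_chain_score: int = 10,
                        max_hits: int = 60) -> OverlapGraph:
    """Find candidate dovetail overlaps by shared-minimizer chaining."""
    n = len(reads)
    lens = [len(r.bases) for r in reads]
    graph = OverlapGraph(n_reads=n, lengths=lens)
    mins = [minimizers_with_strand(r.bases, OLC_K, OLC_W) for r in reads]
    index: dict[int, list[tuple[int, int, bool]]] = {}
    for i, mm in enumerate(mins):
        for pos, h, fwd in mm:
            index.setdefault(h, []).append((i, pos, fwd))
    # collect anchors per ordered pair (i < j) and relative strand
    anchors: dict[tuple[int, int, bool], list[tuple[int, int]]] = {}
    for i, mm in enumerate(mins):
        li = lens[i]
        for pos_i, h, fwd_i in mm:
            entry = index.get(h)
            if entry is None or len(entry) > max_hits:
                continue
            for j, pos_j, fwd_j in entry:
                if j <= i:
                    continue
                ss = fwd_i == fwd_j
                pj = pos_j if ss else lens[j] - OLC_K - pos_j
                anchors.setdefault((i, j, ss), []).append((pj, pos_i))
    for (i, j, ss), pairs in anchors.items():
        if len(pairs) < min_chain_score:
            continue
        # cluster with q = position on j (oriented), t = position on i
        cl = _cluster_anchors(pairs)
        if cl is None:
            continue
        off, score, span, _, _, t_lo, t_hi = cl
        if score < min_chain_score or span < min_overlap:
            continue
        li, lj = lens[i], lens[j]
        # containment: the candidate extends neither end of the other by
        # more than the offset-estimation noise
        tol = 100 + 0.01 * min(li, lj)
        if -off < tol and off + lj - li < tol:
            graph.contained.add(j)
            continue
        if off < tol and li - (off + lj) < tol:
            graph.contained.add(i)
            continue
        orient_j = "+" if ss else "-"
        graph.adj.setdefault(i, []).append((j, orient_j, off, score, span))
        # inverse edge, in j's forward frame
        if ss:
            inv = (i, "+", -off, score, span)
        else:
            inv = (i, "-", lj - li + off, score, span)
        graph.adj.setdefault(j, []).append(inv)
    return graph


# ---------------------------------------------------------------------------
# greedy layout


def _greedy_paths(graph: OverlapGraph):
    """Non-branching greedy best-overlap paths over non-contained reads.

    Each path is a list of (read idx, orient, overlap_with_previous).
    """
    order = sorted(range(graph.n_reads),
                   key=lambda i: -graph.lengths[i])
    used: set[int] = set(graph.contained)
    paths = []
    for seed in order:
        if seed in used:
            continue
        used.add(seed)
        path = [(seed, "+", 0)]
        for _pass in range(2):
            # extend to the right; second pass extends the original left
            # end after flipping the whole path
            while True:
                idx, orient, _ = path[-1]
                L = graph.lengths[idx]
                best = None
                for b, o, off, sc, sp in graph.neighbors(idx, orient):
                    if b in used or off <= 0 or off + graph.lengths[b] <= L:
                        continue
                    key = (sp, sc, -b)
                    if best is None or key > best[0]:
                        best = (key, b, o, L - off)
                if best is None:
                    break
                _, b, o, ovl = best
                used.add(b)
                path.append((b, o, ovl))
            if _pass == 0:
                flipped = [(i, "-" if o == "+" else "+", 0)
                           for i, o, _ in reversed(path)]
                for t in range(1, len(flipped)):
                    flipped[t] = (flipped[t][0], flipped[t][1],
                                  path[len(path) - t][2])
                path = flipped
        paths.append(path)
    return paths


def _oriented(seq: str, orient: str) -> str:
    return seq if orient == "+" else revcomp(seq)


def _layout_backbone(path, reads) -> str | None:
    """Concatenate a greedy path into a raw backbone.

    Each junction is refined by an infix edit-distance alignment of the
    backbone tail inside the next read; a junction whose identity falls
    below 55% breaks the layout (remainder dropped from this backbone).
    """
    idx0, o0, _ = path[0]
    bb = _oriented(reads[idx0].bases, o0)
    for idx, orient, ovl in path[1:]:
        nxt = _oriented(reads[idx].bases, orient)
        qlen = max(100, int(0.7 * ovl))
        qlen = min(qlen, len(bb), int(0.95 * len(nxt)))
        res = edlib.align(bb[-qlen:], nxt, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > 0.45 * qlen:
            logger.debug("layout junction rejected (read %s)", reads[idx].id)
            break
        end = res["locations"][0][1]  # inclusive end of tail within nxt
        if end + 1 >= len(nxt):
            continue
        bb += nxt[end + 1:]
    return bb


# ---------------------------------------------------------------------------
# read-to-backbone mapping and pileup consensus


def _map_read(seq: str, index, k: int, w: int, min_score: int = 5):
    """Best (backbone, strand, offset, score) placement of a read."""
    anchors: dict[tuple[int, bool], list[tuple[int, int]]] = {}
    for pos, h, fwd in minimizers_with_strand(seq, k, w):
        entry = index.get(h)
        if entry is None:
            continue
        for t, tpos, tfwd in entry:
            ss = fwd == tfwd
            q = pos if ss else len(seq) - k - pos
            anchors.setdefault((t, ss), []).append((q, tpos))
    best = None
    for (t, ss), pairs in anchors.items():
        if len(pairs) < min_score:
            continue
        cl = _cluster_anchors(pairs)
        if cl is None or cl[1] < min_score:
            continue
        key = (cl[1], -t)
        if best is None or key > best[0]:
            best = (key, t, ss, cl[0])
    if best is None:
        return None
    _, t, ss, off = best
    return t, ("+" if ss else "-"), off, best[0][0]


class _Pileup:
    """Per-column vote accumulator over one backbone."""

    def __init__(self, backbone: str):
        self.backbone = backbone
        n = len(backbone)
        self.votes = np.zeros((n, 5), dtype=np.int32)  # A C G T del
        self.ins: dict[int, dict[str, int]] = {}

    def add_alignment(self, qseq: str, tstart: int, cigar: str):
        codes = _B2C[np.frombuffer(qseq.encode(), dtype=np.uint8)]
        votes = self.votes
        n_bb = len(self.backbone)
        t = tstart
        q = 0
        for n, op in parse_cigar(cigar):
            if op in "=XM":
                lo, hi = max(t, 0), min(t + n, n_bb)
                if hi > lo:
                    cc = codes[q + (lo - t):q + (hi - t)]
                    ok = cc < 4
                    if ok.all():
                        np.add.at(votes, (np.arange(lo, hi), cc), 1)
                    else:
                        idx = np.arange(lo, hi)[ok]
                        np.add.at(votes, (idx, cc[ok]), 1)
                t += n
                q += n
            elif op == "D":
                lo, hi = max(t, 0), min(t + n, n_bb)
                if hi > lo:
                    votes[lo:hi, 4] += 1
                t += n
            elif op == "I":
                if 0 <= t <= n_bb:
                    d = self.ins.setdefault(t, {})
                    s = qseq[q:q + n]
                    d[s] = d.get(s, 0) + 1
                q += n

    def mean_coverage(self) -> float:
        cov = self.votes.sum(axis=1)
        return float(cov.mean()) if cov.size else 0.0

    def call(self, mode: str = "plurality", min_reads: int = 3,
             min_frac: float = 0.7) -> str:
        """Consensus sequence.

        plurality: per-column argmax (backbone base kept at zero
        coverage); insertions applied when supported by > 50% of the
        column coverage. threshold: a change from the backbone base
        (including indels) needs >= min_reads votes and >= min_frac of
        the column coverage — used by the short-read polisher.
        """
        votes = self.votes
        colcov = votes.sum(axis=1)
        winners = votes.argmax(axis=1)
        wcounts = votes[np.arange(len(winners)), winners]
        out: list[str] = []
        bases = "ACGT-"
        bb = self.backbone
        ins = self.ins
        for i in range(len(bb)):
            iv = ins.get(i)
            if iv:
                # vote on having *an* insertion by pooled count, then pick
                # the plurality sequence (gap placement jitters between
                # reads, so per-sequence counts alone undercount)
                s, _ = max(iv.items(), key=lambda kv: (kv[1], kv[0]))
                c = sum(iv.values())
                cov_here = max(colcov[i], 1)
                if mode == "plurality":
                    if c > 0.5 * cov_here:
                        out.append(s)
                elif c >= min_reads and c >= min_frac * cov_here:
                    out.append(s)
            if colcov[i] == 0:
                out.append(bb[i])
                continue
            w = int(winners[i])
            if mode == "plurality":
                if w != 4:
                    out.append(bases[w])
            else:
                ref_code = int(_B2C[ord(bb[i])])
                if (w != ref_code and wcounts[i] >= min_reads
                        and wcounts[i] >= min_frac * colcov[i]):
                    if w != 4:
                        out.append(bases[w])
                else:
                    out.append(bb[i])
        iv = ins.get(len(bb))
        if iv:
            s, _ = max(iv.items(), key=lambda kv: (kv[1], kv[0]))
            c = sum(iv.values())
            cov_here = max(colcov[-1], 1) if len(bb) else 1
            if (mode == "plurality" and c > 0.5 * cov_here) or (
                    mode != "plurality" and c >= min_reads
                    and c >= min_frac * cov_here):
                out.append(s)
        return "".join(out)


def _consensus_round(backbones: list[str], reads, k: int, w: int,
                     min_map_score: int = 5,
                     pad_frac: float = 0.1) -> list[_Pileup]:
    """Map every read to its best backbone (one shared minimizer index)
    and accumulate pileups per backbone."""
    index: dict[int, list[tuple[int, int, bool]]] = {}
    for t, bb in enumerate(backbones):
        for pos, h, fwd in minimizers_with_strand(bb, k, w):
            index.setdefault(h, []).append((t, pos, fwd))
    piles = [_Pileup(bb) for bb in backbones]
    for r in reads:
        hit = _map_read(r.bases, index, k, w, min_map_score)
        if hit is None:
            continue
        t, strand, off, _ = hit
        backbone = backbones[t]
        nbb = len(backbone)
        qseq = _oriented(r.bases, strand)
        # clip the read to the backbone span, window pads absorb drift
        start_clip = max(0, -off)
        end_clip = max(0, off + len(qseq) - nbb)
        if start_clip + end_clip >= len(qseq):
            continue
        qs = qseq[start_clip:len(qseq) - end_clip]
        off2 = off + start_clip
        pad = int(150 + pad_frac * len(qs))
        ws = max(0, off2 - pad)
        we = min(nbb, off2 + len(qs) + pad)
        res = edlib.align(qs, backbone[ws:we], mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        tstart = ws + res["locations"][0][0]
        piles[t].add_alignment(qs, tstart, res["cigar"])
    return piles


# ---------------------------------------------------------------------------
# the mini OLC backend


def _detect_circular(cons: str, max_err: float = 0.15,
                     min_period: int = 3000) -> tuple[str, bool]:
    """Trim a wrapped layout to one genome period.

    A layout of a circular genome runs past its own start (possibly for
    several laps when coverage is deep). The first re-occurrence of the
    head marks the period; everything beyond it is duplicate sequence.
    Scanned left to right so the smallest period wins.
    """
    n = len(cons)
    qlen = min(2000, n // 4)
    if n < min_period + qlen + 200:
        return cons, False
    head = cons[:qlen]
    step = 4000
    for ws in range(min_period, n - qlen // 2, step):
        window = cons[ws:ws + qlen + step]
        res = edlib.align(head, window, mode="HW", task="locations",
                          k=int(max_err * qlen))
        if res["editDistance"] < 0:
            continue
        s_abs = ws + res["locations"][0][0]
        if s_abs < min_period:
            continue
        return cons[:s_abs], True
    return cons, False


def mini_olc_assemble(long_rs: ReadSet, *, min_overlap: int = 500,
                      min_chain_score: int = 10) -> list[ContigSeq]:
    """Desk-scale OLC assembly of long reads into consensus contigs.

    Overlap -> greedy layout -> plurality pileup consensus -> circularity
    detection. Reads without overlaps are emitted as singleton contigs;
    contained reads contribute to the consensus only.
    """
    reads = list(long_rs.reads)
    if not reads:
        raise ValueError("no long reads to assemble")
    if len(reads) == 1:
        r = reads[0]
        return [ContigSeq(id="ctg1", bases=r.bases, coverage=1.0)]
    graph = build_overlap_graph(reads, min_overlap, min_chain_score)
    paths = _greedy_paths(graph)
    backbones: list[str] = []
    circulars: list[bool] = []
    singletons: list[str] = []
    for path in paths:
        bb = _layout_backbone(path, reads)
        if bb is None or len(bb) < OLC_K + OLC_W:
            continue
        if len(path) == 1 and not graph.adj.get(path[0][0]):
            singletons.append(bb)  # isolated read: emit as-is
            continue
        # trim multi-lap layouts of circular genomes before consensus so
        # the pileup concentrates on a single period (raw backbone is
        # error-prone, hence the loose threshold)
        bb, circ = _detect_circular(bb, max_err=0.35)
        backbones.append(bb)
        circulars.append(circ)
    covs = [1.0] * len(backbones)
    for _round in range(2):  # second pass resolves gap ambiguity
        piles = _consensus_round(backbones, reads, OLC_K, OLC_W)
        new = [p.call(mode="plurality") for p in piles]
        covs = [p.mean_coverage() for p in piles]
        changed = new != backbones
        backbones = new
        if not changed:
            break
    contigs: list[ContigSeq] = []
    for cons, circ, cov in zip(backbones, circulars, covs):
        if not circ:
            cons, circ = _detect_circular(cons, max_err=0.15)
        contigs.append(ContigSeq(id=f"ctg{len(contigs) + 1}", bases=cons,
                                 coverage=cov, circular=circ))
    for s in singletons:
        contigs.append(ContigSeq(id=f"ctg{len(contigs) + 1}", bases=s,
                                 coverage=1.0))
    contigs.sort(key=lambda c: -len(c))
    for i, c in enumerate(contigs):
        c.id = f"ctg{i + 1}"
    return contigs


# ---------------------------------------------------------------------------
# short-read polishing


def polish_with_short_reads(draft: ContigSeq, short: ReadSet, *,
                            rounds: int = 2, k_anchor: int = 21,
                            min_reads: int = 3,
                            min_frac: float = 0.7) -> ContigSeq:
    """Pileup-vote polishing of a draft contig with accurate short reads.

    Reads are anchored by unique k_anchor-mers of the draft, locally
    aligned in a padded band, and per-column plurality changes are applied
    when supported by >= min_reads reads and >= min_frac agreement.
    Regions without anchorable coverage are left unchanged; the operation
    is idempotent on a clean draft.
    """
    seq = draft.bases
    for _ in range(rounds):
        uniq: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(seq) - k_anchor + 1):
            km = seq[i:i + k_anchor]
            if km in dup:
                continue
            if km in uniq:
                del uniq[km]
                dup.add(km)
            else:
                uniq[km] = i
        pile = _Pileup(seq)
        n_anchored = 0
        for r in short:
            placed = _anchor_short_read(r.bases, seq, uniq, k_anchor)
            if placed is None:
                continue
            qseq, off = placed
            start_clip = max(0, -off)
            end_clip = max(0, off + len(qseq) - len(seq))
            if start_clip + end_clip >= len(qseq):
                continue
            qs = qseq[start_clip:len(qseq) - end_clip]
            off2 = off + start_clip
            ws = max(0, off2 - 25)
            we = min(len(seq), off2 + len(qs) + 25)
            res = edlib.align(qs, seq[ws:we], mode="HW", task="path")
            if res["editDistance"] < 0 or res["editDistance"] > 0.3 * len(qs):
                continue
            pile.add_alignment(qs, ws + res["locations"][0][0], res["cigar"])
            n_anchored += 1
        if n_anchored == 0:
            logger.warning("polish: no anchorable short reads for %s",
                           draft.id)
            return ContigSeq(id=draft.id, bases=seq, coverage=draft.coverage,
                             circular=draft.circular)
        new = pile.call(mode="threshold", min_reads=min_reads,
                        min_frac=min_frac)
        if new == seq:
            break
        seq = new
    return ContigSeq(id=draft.id, bases=seq, coverage=draft.coverage,
                     circular=draft.circular)


def _anchor_short_read(bases: str, draft: str, uniq: dict[str, int],
                       k: int):
    """Place a short read on the draft via unique k-mer anchors; returns
    (oriented sequence, draft offset) or None."""
    if len(bases) < k:
        return None
    step = max(1, (len(bases) - k) // 16)
    best = None
    for qseq in (bases, revcomp(bases)):
        deltas = []
        for i in range(0, len(qseq) - k + 1, step):
            p = uniq.get(qseq[i:i + k])
            if p is not None:
                deltas.append(p - i)
        if len(deltas) >= 2:
            deltas.sort()
            off = deltas[len(deltas) // 2]
            n_consistent = sum(1 for d in deltas if abs(d - off) <= 10)
            if best is None or n_consistent > best[2]:
                best = (qseq, off, n_consistent)
    if best is None or best[2] < 2:
        return None
    return best[0], best[1]


# ---------------------------------------------------------------------------
# contiguity enhancement


def improve_contiguity(contigs: list[ContigSeq], long_rs: ReadSet, *,
                       min_bridges: int = 3, anchor_len: int = 500,
                       end_tol: int = 300) -> list[ContigSeq]:
    """Merge contigs whose ends are bridged by >= min_bridges long reads.

    A bridging read must anchor >= anchor_len on both contigs with
    consistent orientation and ordering; the gap is filled with the
    best-scoring bridging read's subsequence. A read bridging one
    contig's two ends circularizes it. Conflicting junctions for the same
    contig end are skipped. N50 never decreases.
    """
    if not contigs:
        return contigs
    index: dict[int, list[tuple[int, int, bool]]] = {}
    for ci, c in enumerate(contigs):
        for pos, h, fwd in minimizers_with_strand(c.bases, OLC_K, OLC_W):
            index.setdefault(h, []).append((ci, pos, fwd))
    # junction key -> list of (total score, gap sequence, exit position in
    # the first contig's oriented frame, entry position in the second's)
    junctions: dict[tuple, list[tuple]] = {}
    for r in long_rs:
        anchors: dict[tuple[int, bool], list[tuple[int, int]]] = {}
        for pos, h, fwd in minimizers_with_strand(r.bases, OLC_K, OLC_W):
            for ci, tpos, tfwd in index.get(h, ()):
                ss = fwd == tfwd
                q = pos if ss else len(r.bases) - OLC_K - pos
                anchors.setdefault((ci, ss), []).append((q, tpos))
        clusters = []
        for (ci, ss), pairs in anchors.items():
            for cl in _cluster_anchors_multi(pairs):
                _, score, span, qlo, qhi, tlo, thi = cl
                if span < anchor_len:
                    continue
                # q was computed in the frame where the read matches the
                # contig forward; convert to read-forward coordinates
                if ss:
                    rlo, rhi = qlo, qhi
                else:
                    rlo, rhi = len(r.bases) - qhi, len(r.bases) - qlo
                clusters.append((rlo, rhi, ci, "+" if ss else "-",
                                 tlo, thi, score))
        if len(clusters) < 2:
            continue
        clusters.sort()
        for a, b in zip(clusters, clusters[1:]):
            rlo_a, rhi_a, ca, sa, tlo_a, thi_a, sc_a = a
            rlo_b, rhi_b, cb, sb, tlo_b, thi_b, sc_b = b
            la, lb = len(contigs[ca]), len(contigs[cb])
            # positions in each contig's oriented (read-direction) frame
            exit_hi = thi_a if sa == "+" else la - tlo_a
            entry_lo = tlo_b if sb == "+" else lb - thi_b
            if la - exit_hi > end_tol or entry_lo > end_tol:
                continue
            gap = r.bases[rhi_a:rlo_b] if rlo_b > rhi_a else ""
            if rlo_b < rhi_a:  # anchors overlap on the read: trim entry
                entry_lo += rhi_a - rlo_b
            if ca == cb:
                if sa == sb:
                    junctions.setdefault(("self", ca, sa), []).append(
                        (sc_a + sc_b, gap, exit_hi, entry_lo))
                continue
            fwdk = (ca, sa, cb, sb)
            revk = (cb, "-" if sb == "+" else "+",
                    ca, "-" if sa == "+" else "+")
            if fwdk <= revk:
                junctions.setdefault(fwdk, []).append(
                    (sc_a + sc_b, gap, exit_hi, entry_lo))
            else:
                # mirrored representation: traverse the junction backwards
                junctions.setdefault(revk, []).append(
                    (sc_a + sc_b, revcomp(gap),
                     lb - entry_lo, la - exit_hi))
    strong = {k: v for k, v in junctions.items() if len(v) >= min_bridges}
    # conflict detection: one contig end in two strong junctions
    end_use: dict[tuple[int, str], list] = {}
    for key in strong:
        if key[0] == "self":
            _, ca, sa = key
            ends = [(ca, "right" if sa == "+" else "left"),
                    (ca, "left" if sa == "+" else "right")]
        else:
            ca, sa, cb, sb = key
            ends = [(ca, "right" if sa == "+" else "left"),
                    (cb, "left" if sb == "+" else "right")]
        for e in ends:
            end_use.setdefault(e, []).append(key)
    conflicted = {k for ks in end_use.values() if len(ks) > 1 for k in ks}
    for k in conflicted:
        logger.debug("improve_contiguity: conflicting junction %s skipped", k)
    merged_away: set[int] = set()
    new_contigs: list[ContigSeq] = []
    for key, votes in sorted(strong.items(),
                             key=lambda kv: (-len(kv[1]), str(kv[0]))):
        if key in conflicted:
            continue
        _, gap, exit_hi, entry_lo = max(votes)
        if key[0] == "self":
            _, ca, sa = key
            if ca in merged_away or contigs[ca].circular:
                continue
            merged_away.add(ca)
            a_o = _oriented(contigs[ca].bases, sa)
            seq = a_o[entry_lo:exit_hi] + gap
            if len(seq) < 100:
                merged_away.discard(ca)
                continue
            new_contigs.append(ContigSeq(
                id=contigs[ca].id, bases=seq,
                coverage=contigs[ca].coverage, circular=True))
        else:
            ca, sa, cb, sb = key
            if ca in merged_away or cb in merged_away:
                continue
            merged_away.update((ca, cb))
            a_o = _oriented(contigs[ca].bases, sa)
            b_o = _oriented(contigs[cb].bases, sb)
            cov = (contigs[ca].coverage * len(a_o)
                   + contigs[cb].coverage * len(b_o)) / (len(a_o) + len(b_o))
            new_contigs.append(ContigSeq(
                id=f"{contigs[ca].id}+{contigs[cb].id}",
                bases=a_o[:exit_hi] + gap + b_o[entry_lo:],
                coverage=cov, circular=False))
    out = [c for ci, c in enumerate(contigs) if ci not in merged_away]
    out.extend(new_contigs)
    return out


# ---------------------------------------------------------------------------
# bin accuracy promotion


def promote_bin(contigs: list[ContigSeq], *, cov_mad_limit: float = 3.5,
                tnf_dist_limit: float = 0.25
                ) -> tuple[list[ContigSeq], list[ContigSeq]]:
    """Drop coverage/composition outlier contigs from an assembled bin.

    A contig is rejected when its coverage deviates from the bin median by
    more than cov_mad_limit robust MADs, or its TNF distance to the
    length-weighted bin centroid exceeds tnf_dist_limit. Returns
    (kept, dropped); dropped contigs rejoin the leftover pool. Raises
    BinCollapseError if nothing survives.
    """
    from .binning import tnf_profile
    if not contigs:
        raise BinCollapseError("empty bin")
    if len(contigs) == 1:
        return list(contigs), []
    covs = [c.coverage for c in contigs]
    med = statistics.median(covs)
    mad = statistics.median(abs(c - med) for c in covs)
    profs = [tnf_profile(c).tnf for c in contigs]
    wts = np.array([len(c) for c in contigs], float)
    centroid = np.average(np.vstack(profs), axis=0, weights=wts)
    kept, dropped = [], []
    for c, prof in zip(contigs, profs):
        z = abs(c.coverage - med) / (1.4826 * mad) if mad > 0 else 0.0
        d = float(np.linalg.norm(prof - centroid))
        if z > cov_mad_limit or d > tnf_dist_limit:
            dropped.append(c)
        else:
            kept.append(c)
    if not kept:
        raise BinCollapseError("all contigs rejected by promote_bin")
    return kept, dropped


# ---------------------------------------------------------------------------
# backend contract and per-bin orchestration


class AssemblyBackend(Protocol):
    """Contract for assembler backends.

    A backend turns a bin's phased reads into draft contigs, setting
    coverage and circular flags, without side effects outside workdir.
    """

    name: str
    capabilities: set[str]

    def __call__(self, long_rs: ReadSet, short_rs: ReadSet,
                 workdir=None) -> list[ContigSeq]: ...


@dataclass
class MiniOLCBackend:
    """Built-in long-read OLC backend (desk scale)."""

    name: str = "mini_olc"
    capabilities: set[str] = field(default_factory=lambda: {"long_only"})
    min_overlap: int = 500
    min_chain_score: int = 10

    def __call__(self, long_rs: ReadSet, short_rs: ReadSet,
                 workdir=None) -> list[ContigSeq]:
        return mini_olc_assemble(long_rs, min_overlap=self.min_overlap,
                                 min_chain_score=self.min_chain_score)


@dataclass
class ExternalBackend:
    """Adapter running an external assembler via a command template.

    The template receives {long}, {short1}, {short2} and {out} (an output
    FASTA path); coverage and circularity of the produced contigs default
    to 0 / False unless the tool reports them in headers as
    ``cov=<x> circular=<bool>`` tokens.
    """

    cmd_template: str
    name: str = "external"
    capabilities: set[str] = field(default_factory=lambda: {"hybrid"})

    def __call__(self, long_rs: ReadSet, short_rs: ReadSet,
                 workdir=None) -> list[ContigSeq]:
        import subprocess
        import tempfile
        from pathlib import Path
        from .io_core import parse_fasta, write_fastq
        wd = Path(workdir or tempfile.mkdtemp(prefix="hcbha_ext_"))
        wd.mkdir(parents=True, exist_ok=True)
        lpath, out = wd / "long.fastq", wd / "contigs.fasta"
        write_fastq(lpath, long_rs)
        r1 = ReadSet([r for r in short_rs if r.mate != "R2"])
        r2 = ReadSet([r for r in short_rs if r.mate == "R2"])
        p1, p2 = wd / "short_R1.fastq", wd / "short_R2.fastq"
        write_fastq(p1, r1)
        write_fastq(p2, r2)
        cmd = self.cmd_template.format(long=lpath, short1=p1, short2=p2,
                                       out=out)
        subprocess.run(cmd, shell=True, check=True, cwd=wd)
        return [ContigSeq(id=rid, bases=seq)
                for rid, seq in parse_fasta(out)]


@dataclass
class BinAssemblyResult:
    bin_id: str
    status: str  # "ok" | "failed" | "collapsed"
    contigs: list[ContigSeq] = field(default_factory=list)
    dropped: list[ContigSeq] = field(default_factory=list)
    message: str = ""


def assemble_bin(bin_id: str, long_rs: ReadSet, short_rs: ReadSet, *,
                 backend: AssemblyBackend | None = None,
                 min_long_reads: int = 50,
                 polish_rounds: int = 2,
                 min_bridges: int = 3) -> BinAssemblyResult:
    """Hybrid-assemble one candidate bin.

    backend -> short-read polish -> long-read contiguity enhancement ->
    final polish round -> accuracy promotion. Backend failures mark the
    bin failed without stopping the pipeline.
    """
    if len(long_rs) < min_long_reads:
        return BinAssemblyResult(bin_id=bin_id, status="failed",
                                 message=f"only {len(long_rs)} long reads")
    backend = backend or MiniOLCBackend()
    try:
        contigs = backend(long_rs, short_rs)
        if not contigs:
            return BinAssemblyResult(bin_id=bin_id, status="failed",
                                     message="backend produced no contigs")
        if len(short_rs):
            contigs = [polish_with_short_reads(c, short_rs,
                                               rounds=polish_rounds)
                       for c in contigs]
        if len(contigs) > 1:
            contigs = improve_contiguity(contigs, long_rs,
                                         min_bridges=min_bridges)
        if len(short_rs):
            contigs = [polish_with_short_reads(c, short_rs, rounds=1)
                       for c in contigs]
        kept, dropped = promote_bin(contigs)
    except BinCollapseError as exc:
        return BinAssemblyResult(bin_id=bin_id, status="collapsed",
                                 message=str(exc))
    except Exception as exc:  # backend contract: isolate failures
        logger.exception("bin %s assembly failed", bin_id)
        return BinAssemblyResult(bin_id=bin_id, status="failed",
                                 message=str(exc))
    for i, c in enumerate(kept):
        c.id = f"{bin_id}_c{i + 1}"
    return BinAssemblyResult(bin_id=bin_id, status="ok", contigs=kept,
                             dropped=dropped)
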