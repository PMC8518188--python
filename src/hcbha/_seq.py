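"""Low-level sequence primitives shared across the pipeline.

Canonical k-mer hashing, window minimizers, reverse complement, and thin
wrappers around edlib alignments (extended-CIGAR parsing). These are the
alignment-free building blocks used by phasing, the mini OLC assembler and
the reference-based evaluator.
"""

from __future__ import annotations

import edlib
import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 2-bit code; anything else (N etc.) is invalid
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE_LUT[_b] = _c
_MIX1 = np.uint64(0xFF51AFD7ED558CCD)
_MIX2 = np.uint64(0xC4CEB9FE1A85EC53)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N."""
    return seq.translate(_COMP)[::-1]


def _mix(x: int, mask: int) -> int:
    # invertible avalanche hash (murmur-style finalizer) so minimizer
    # selection is not biased toward poly-A k-mers
    x = ((x ^ (x >> 33)) * 0xFF51AFD7ED558CCD) & mask
    x = ((x ^ (x >> 33)) * 0xC4CEB9FE1A85EC53) & mask
    return x ^ (x >> 33)


def canonical_kmer_hashes(seq: str, k: int,
                          with_strand: bool = False):
    """Hash of the canonical (strand-symmetric) k-mer at every position.

    Returns a list of length ``len(seq) - k + 1``; positions whose window
    contains a non-ACGT base are ``None``. With ``with_strand`` each entry
    is ``(hash, is_forward)`` where is_forward says whether the forward
    k-mer is the canonical one.
    """
    n = len(seq)
    if n < k:
        return []
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    out: list = [None] * (n - k + 1)
    code = _CODE
    fwd = rc = 0
    valid = 0  # number of consecutive valid bases ending here
    for i, ch in enumerate(seq):
        c = code.get(ch)
        if c is None:
            valid = 0
            fwd = rc = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rc = (rc >> 2) | ((3 - c) << shift)
        valid += 1
        if valid >= k:
            pos = i - k + 1
            is_fwd = fwd <= rc
            h = _mix(fwd if is_fwd else rc, mask)
            out[pos] = (h, is_fwd) if with_strand else h
    return out


def minimizers(seq: str, k: int, w: int) -> list[tuple[int, int]]:
    """Window minimizers of ``seq``: list of (position, canonical hash).

    Standard (w, k)-minimizer scheme: the smallest canonical k-mer hash in
    every window of w consecutive k-mers is selected; consecutive duplicate
    selections are collapsed. Windows overlapping N's contribute nothing.
    """
    return [(p, h) for p, h, _ in minimizers_with_strand(seq, k, w)]


def minimizer_set(seq: str, k: int, w: int) -> set[int]:
    """Distinct canonical minimizer hashes of a sequence."""
    return {h for _, h in minimizers(seq, k, w)}


def _kmer_arrays(seq: str, k: int):
    """Vectorized canonical k-mer hashes: (hash uint64, is_forward bool).

    Positions whose window contains a non-ACGT base carry the sentinel
    2**64 - 1. Valid for k <= 16 (2k-bit k-mer codes).
    """
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    m = len(codes) - k + 1
    if m <= 0:
        return None, None
    c64 = codes.astype(np.int64)
    pw_fwd = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    pw_rev = 4 ** np.arange(k, dtype=np.int64)
    fwd = np.correlate(c64, pw_fwd, mode="valid")
    rc = int(3 * pw_rev.sum()) - np.correlate(c64, pw_rev, mode="valid")
    is_fwd = fwd <= rc
    canon = np.where(is_fwd, fwd, rc).astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    canon = (canon * _MIX1) & mask
    canon = (canon * _MIX2) & mask
    invalid = np.correlate((codes > 3).astype(np.int64), np.ones(k, np.int64),
                           mode="valid") > 0
    canon[invalid] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return canon, is_fwd


def minimizers_with_strand(seq: str, k: int, w: int) -> list[tuple[int, int, bool]]:
    """Window minimizers as (position, hash, is_forward) triples.

    The smallest canonical hash of every w-k-mer window is selected
    (leftmost on ties), consecutive duplicates collapsed; windows made
    entirely of N-containing k-mers select nothing.
    """
    canon, is_fwd = _kmer_arrays(seq, k)
    if canon is None:
        return []
    sentinel = np.uint64(0xFFFFFFFFFFFFFFFF)
    m = len(canon)
    if m <= w:
        p = int(np.argmin(canon))
        if canon[p] == sentinel:
            return []
        return [(p, int(canon[p]), bool(is_fwd[p]))]
    sw = np.lib.stride_tricks.sliding_window_view(canon, w)
    arg = sw.argmin(axis=1) + np.arange(m - w + 1)
    vals = canon[arg]
    keep = np.ones(len(arg), dtype=bool)
    keep[1:] = arg[1:] != arg[:-1]
    keep &= vals != sentinel
    return [(int(p), int(canon[p]), bool(is_fwd[p])) for p in arg[keep]]


def minimizer_hash_set(seq: str, k: int, w: int) -> set[int]:
    """Distinct minimizer hashes only — the cheap path for read scoring."""
    canon, _ = _kmer_arrays(seq, k)
    if canon is None:
        return set()
    sentinel = 0xFFFFFFFFFFFFFFFF
    m = len(canon)
    if m <= w:
        v = int(canon.min())
        return set() if v == sentinel else {v}
    sw = np.lib.stride_tricks.sliding_window_view(canon, w)
    vals = np.unique(sw.min(axis=1))
    out = set(int(v) for v in vals)
    out.discard(sentinel)
    return out


# ---------------------------------------------------------------------------
# edlib helpers


def edit_align(query: str, target: str, mode: str = "NW", task: str = "distance",
               max_dist: int = -1):
    """edlib alignment with sane defaults; returns the raw result dict."""
    return edlib.align(query, target, mode=mode, task=task, k=max_dist)


def parse_cigar(cigar: str):
    """Yield (length, op) pairs from an extended CIGAR (=, X, I, D)."""
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            yield n, ch
            n = 0


def cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, insertions, deletions) base counts of a CIGAR.

    Insertions are bases present in the query but not the target; deletions
    the converse (edlib convention with query-vs-target).
    """
    m = x = ins = dele = 0
    for n, op in parse_cigar(cigar):
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
        elif op == "M":  # plain cigar fallback; count as match
            m += n
    return m, x, ins, dele


def alignment_identity(query: str, target: str, mode: str = "NW") -> float:
    """Gap-compressed-free identity: 1 - edits / alignment_length."""
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return 0.0
    m, x, i, d = cigar_stats(res["cigar"])
    alen = m + x + i + d
    return (m / alen) if alen else 0.0
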