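"""Contig binning by tetranucleotide composition and coverage.

Draft contigs are profiled by canonical tetranucleotide frequency (136
strand-symmetric 4-mer classes) plus log-coverage, z-scored, and clustered
agglomeratively; the dendrogram is cut (largest merge-height gap by
default) into candidate haplotype bins. Undersized clusters are pooled
into a reserved leftover bin that is excluded from assembly but retained
for the next iteration. An amendment pass reassigns contigs to the nearest
bin centroid until a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from ._seq import revcomp
from .io_core import ContigSeq

LEFTOVER_BIN = "leftover"

# any 4-mer -> canonical class index, 136 classes (120 reverse-complement
# pairs + 16 palindromes), built once at import
_CANON4: dict[str, int] = {}
_K4_INDEX: dict[str, int] = {}
for _kmer in ("".join(p) for p in product("ACGT", repeat=4)):
    _canon = min(_kmer, revcomp(_kmer))
    if _canon not in _CANON4:
        _CANON4[_canon] = len(_CANON4)
    _K4_INDEX[_kmer] = _CANON4[_canon]
N_TNF = len(_CANON4)  # 136


@dataclass
class CompositionProfile:
    """Canonical TNF vector plus log-coverage for one contig."""

    contig_id: str
    tnf: np.ndarray  # length 136, frequencies
    log_cov: float


@dataclass
class CandidateBin:
    """A candidate haplotype bin: contigs plus the reads phased to it."""

    id: str
    contig_ids: list[str]
    centroid: np.ndarray | None = None
    long_read_ids: set[str] = field(default_factory=set)
    short_read_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.contig_ids:
            raise ValueError(f"bin {self.id!r} is empty")


def tnf_profile(contig: ContigSeq) -> CompositionProfile:
    """Canonical tetranucleotide frequency profile of a contig.

    Windows containing N are skipped; frequencies sum to 1 when at least
    one valid 4-mer exists.
    """
    seq = contig.bases
    if len(seq) < 4:
        raise ValueError(f"contig {contig.id!r} shorter than 4 bp")
    counts = np.zeros(N_TNF)
    index = _K4_INDEX
    for i in range(len(seq) - 3):
        idx = index.get(seq[i:i + 4])
        if idx is None:  # window contains N
            continue
        counts[idx] += 1
    total = counts.sum()
    if total > 0:
        counts /= total
    return CompositionProfile(contig_id=contig.id, tnf=counts,
                              log_cov=float(np.log(contig.coverage + 1.0)))


def build_feature_matrix(profiles: list[CompositionProfile],
                         cov_weight: float = 3.0) -> np.ndarray:
    """Z-scored TNF columns plus a cov_weight-scaled z-scored log-coverage
    column; rows follow input order. Zero-variance columns stay at 0."""
    if not profiles:
        raise ValueError("no profiles")
    tnf = np.vstack([p.tnf for p in profiles])
    cov = np.array([p.log_cov for p in profiles])[:, None]
    feats = np.hstack([tnf, cov])
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = np.inf  # zero-variance columns -> 0 after scaling
    z = (feats - mu) / sd
    z[:, -1] *= cov_weight
    return z


def hierarchical_cluster(features: np.ndarray, method: str = "average",
                         metric: str = "euclidean") -> np.ndarray:
    """Agglomerative dendrogram (scipy linkage matrix) of the feature rows."""
    features = np.asarray(features, float)
    if features.ndim == 1:
        features = features[:, None]
    if not np.isfinite(features).all():
        raise ValueError("non-finite features")
    if features.shape[0] == 1:
        return np.empty((0, 4))
    return linkage(features, method=method, metric=metric)


def noise_cut_height(profiles: list[CompositionProfile],
                     lengths: list[int], alpha: float = 1.25) -> float:
    """Merge-height threshold calibrated to TNF sampling noise.

    Two contigs of the *same* genome differ only by multinomial sampling
    noise of their TNF vectors; in the z-scored feature space the
    expected squared distance of such a pair is the summed per-column
    noise variance over the column variances. The cut sits alpha times
    above the largest same-genome pair distance the data could produce,
    so composition signal — not noise — decides the partition.
    """
    tnf = np.vstack([p.tnf for p in profiles])
    fbar = tnf.mean(axis=0)
    sd = tnf.std(axis=0)
    sd[sd == 0] = np.inf
    var_cols = fbar * (1 - fbar) / sd ** 2
    noise = np.array([var_cols.sum() / max(n - 3, 1) for n in lengths])
    # the threshold is set by the noisiest plausible same-genome pair;
    # tiny fragments would blow it up, so prefer contigs >= 10 kb
    big = noise[np.asarray(lengths) >= 10_000]
    pool = big if len(big) >= 2 else noise
    top2 = np.sort(pool)[-2:]
    return alpha * float(np.sqrt(top2.sum()))


def _labels_from_cut(Z: np.ndarray, n: int, mode: str,
                     height: float | None, k: int | None,
                     profiles, lengths) -> np.ndarray:
    if n == 1:
        return np.array([1])
    if mode == "k":
        if k is None or k > n:
            raise ValueError(f"k={k} exceeds number of contigs {n}")
        return fcluster(Z, t=k, criterion="maxclust")
    if mode == "height":
        return fcluster(Z, t=height, criterion="distance")
    if mode == "noise":
        if profiles is None:
            raise ValueError("noise cut requires the composition profiles")
        t = noise_cut_height(profiles, lengths)
        return fcluster(Z, t=t, criterion="distance")
    raise ValueError(f"unknown cut mode {mode!r}")


def cut_to_bins(Z: np.ndarray, contigs: list[ContigSeq], *,
                profiles: list[CompositionProfile] | None = None,
                mode: str = "noise", height: float | None = None,
                k: int | None = None,
                min_bin_bases: int = 50_000) -> list[CandidateBin]:
    """Cut the dendrogram into candidate bins.

    mode "noise" (default) cuts at a height calibrated to the TNF
    sampling noise of the contigs (requires profiles); "height" and "k"
    are explicit. Clusters totalling < min_bin_bases are pooled into the
    reserved leftover bin (excluded from assembly, retained for the next
    iteration). The result is a partition of all input contigs.
    """
    labels = _labels_from_cut(Z, len(contigs), mode, height, k,
                              profiles, [len(c) for c in contigs])
    by_label: dict[int, list[ContigSeq]] = {}
    for c, lab in zip(contigs, labels):
        by_label.setdefault(int(lab), []).append(c)
    bins: list[CandidateBin] = []
    leftover: list[str] = []
    for lab in sorted(by_label):
        members = by_label[lab]
        if sum(len(c) for c in members) < min_bin_bases:
            leftover.extend(c.id for c in members)
        else:
            bins.append(CandidateBin(id=f"bin{len(bins) + 1}",
                                     contig_ids=[c.id for c in members]))
    if leftover:
        bins.append(CandidateBin(id=LEFTOVER_BIN, contig_ids=leftover))
    return bins


def amend_bins(bins: list[CandidateBin], profiles: list[CompositionProfile],
               features: np.ndarray, margin: float = 0.1,
               max_rounds: int = 10) -> list[CandidateBin]:
    """Reassign contigs to clearly nearer bin centroids (fixpoint pass).

    A contig moves only when the distance to the nearest other centroid is
    < (1 - margin) x the distance to its current centroid. The leftover
    bin is left untouched; the global contig set is conserved.
    """
    row_of = {p.contig_id: i for i, p in enumerate(profiles)}
    real = [b for b in bins if b.id != LEFTOVER_BIN]
    rest = [b for b in bins if b.id == LEFTOVER_BIN]
    if len(real) < 2:
        return bins
    assign = {cid: bi for bi, b in enumerate(real) for cid in b.contig_ids}
    for _ in range(max_rounds):
        cents = np.vstack([
            features[[row_of[cid] for cid in b.contig_ids]].mean(axis=0)
            for b in real])
        moved = False
        for cid, bi in list(assign.items()):
            d = cdist(features[row_of[cid]][None, :], cents)[0]
            best = int(np.argmin(d))
            if best != bi and d[best] < (1 - margin) * d[bi]:
                if len([c for c, b2 in assign.items() if b2 == bi]) > 1:
                    assign[cid] = best
                    moved = True
        if not moved:
            break
        real = [CandidateBin(id=b.id,
                             contig_ids=[c for c, bi2 in assign.items()
                                         if bi2 == i])
                for i, b in enumerate(real)]
    out = []
    for i, b in enumerate(real):
        cents = np.vstack([
            features[[row_of[cid] for cid in b.contig_ids]].mean(axis=0)])
        out.append(CandidateBin(id=b.id, contig_ids=b.contig_ids,
                                centroid=cents[0]))
    return out + rest
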