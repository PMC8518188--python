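"""Iteration controller: quality gating, read subtraction, stop rule.

Each iteration runs the full workflow (draft assembly of the remaining
long reads, contig binning, read phasing, per-bin hybrid assembly), gates
the resulting genomes, subtracts the reads consumed by qualified genomes,
and repeats until the per-iteration qualified relative abundance falls
below 2% (or a maximum of 11 iterations). Retained genomes from all
iterations are dereplicated (dRep-style primary/secondary ANI clustering
at 0.90 / 0.97 with 0.65 alignment-coverage) into the final MAG set.

Gate inequalities are deliberately strict: a MAG is *qualified*
(triggers read subtraction) iff completeness > 90, contamination < 10 and
contig count < 30 (all strict); *retained* iff completeness > 50 and
contamination < 10; MIMAG tiers use >=/<= (HQ: completeness >= 90,
contamination <= 5, full-length rRNA; MQ: >= 50 / <= 10); a genome whose
contigs are all closed circles is *complete* regardless of estimated
completeness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import edlib
import numpy as np

from ._seq import canonical_kmer_hashes
from . import binning as _binning
from . import evaluate as _evaluate
from .assembly import MiniOLCBackend, assemble_bin, mini_olc_assemble
from .binning import LEFTOVER_BIN, CandidateBin
from .io_core import ContigSeq, ReadSet, subsample_to_bases
from .phasing import UNASSIGNED, assign_reads, build_minimizer_index, \
    subtract_reads

logger = logging.getLogger("hcbha")

TIER_COMPLETE = "complete"
TIER_HQ = "HQ"
TIER_MQ = "MQ"
TIER_FAILED = "failed"


@dataclass
class QualityRecord:
    completeness: float      # percent
    contamination: float     # percent
    n_contigs: int
    n50: int
    total_bp: int
    circular_all: bool = False
    rrna_full: bool = False
    trna_count: int | None = None

    def __post_init__(self):
        if not (0 <= self.completeness <= 100):
            raise ValueError("completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError("contamination must be >= 0")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")


@dataclass
class MAGRecord:
    mag_id: str
    contigs: list[ContigSeq]
    quality: QualityRecord
    tier: str
    iteration: int
    consumed_read_ids: set[str] = field(default_factory=set)
    relative_abundance: float = 0.0

    @property
    def sequence(self) -> str:
        return "".join(c.bases for c in self.contigs)


@dataclass
class IterationState:
    iteration: int
    remaining_long: ReadSet
    remaining_short: ReadSet
    accepted: list[MAGRecord] = field(default_factory=list)
    leftover_contigs: list[ContigSeq] = field(default_factory=list)
    qualified_abundance_this_iter: float = 0.0
    total_long_bases: int = 0   # of the original full dataset
    total_short_bases: int = 0


# ---------------------------------------------------------------------------
# quality gates


def is_qualified(q: QualityRecord) -> bool:
    """Subtraction trigger: completeness > 90, contamination < 10, and
    fewer than 30 contigs — all strict."""
    return q.completeness > 90 and q.contamination < 10 and q.n_contigs < 30


def retain_filter(q: QualityRecord) -> bool:
    """Per-iteration retention: completeness > 50 and contamination < 10."""
    return q.completeness > 50 and q.contamination < 10


def classify_tier(q: QualityRecord) -> str:
    """MIMAG-style tier; closed circular genomes count complete even below
    90% estimated completeness."""
    if q.circular_all:
        return TIER_COMPLETE
    if q.completeness >= 90 and q.contamination <= 5 and q.rrna_full:
        return TIER_HQ
    if q.completeness >= 50 and q.contamination <= 10:
        return TIER_MQ
    return TIER_FAILED


def should_stop(state: IterationState, threshold: float = 0.02,
                max_iter: int = 11) -> bool:
    """Stop when the qualified relative abundance of the last iteration is
    below threshold (strict <) or max_iter iterations have run."""
    return (state.qualified_abundance_this_iter < threshold
            or state.iteration >= max_iter)


# ---------------------------------------------------------------------------
# quality estimation (reference-based, synthetic mode)

QualityEstimator = Callable[[list[ContigSeq]], QualityRecord]


@dataclass
class ReferenceQualityEstimator:
    """Truth-based quality: completeness is the AGF of the best-matching
    reference, contamination the fraction of aligned bases hitting other
    references; the rRNA flag is the recovery of the planted marker locus
    at >= 99% identity over >= 95% of its length.

    Stands in for marker-gene estimators (CheckM-class tools) in synthetic
    mode; real-data runs plug an external estimator into the same
    contract.
    """

    references: dict[str, str]
    markers: dict[str, str] = field(default_factory=dict)

    def __call__(self, contigs: list[ContigSeq]) -> QualityRecord:
        if not contigs:
            raise ValueError("empty contig set")
        if not self.references:
            raise ValueError("reference mode requires truth genomes")
        blocks = _evaluate.align_to_reference(contigs, self.references)
        lengths = [len(c) for c in contigs]
        total_bp = sum(lengths)
        if not blocks:
            return QualityRecord(
                completeness=0.0, contamination=0.0,
                n_contigs=len(contigs), n50=_evaluate.n50(lengths),
                total_bp=total_bp,
                circular_all=all(c.circular for c in contigs))
        per_ref: dict[str, int] = {}
        for b in blocks:
            per_ref[b.ref_id] = per_ref.get(b.ref_id, 0) + b.aligned_ref_bases
        best = sorted(per_ref.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        best_blocks = [b for b in blocks if b.ref_id == best]
        completeness = _evaluate.aligned_genome_fraction(
            best_blocks, len(self.references[best]))
        aligned_total = sum(b.q_end - b.q_start for b in blocks)
        aligned_other = sum(b.q_end - b.q_start for b in blocks
                            if b.ref_id != best)
        contamination = (100.0 * aligned_other / aligned_total
                         if aligned_total else 0.0)
        rrna = self._marker_recovered(contigs, best)
        return QualityRecord(
            completeness=completeness, contamination=contamination,
            n_contigs=len(contigs), n50=_evaluate.n50(lengths),
            total_bp=total_bp,
            circular_all=all(c.circular for c in contigs),
            rrna_full=rrna)

    def _marker_recovered(self, contigs, ref_id) -> bool:
        marker = self.markers.get(ref_id)
        if marker is None:
            return False
        from ._seq import revcomp
        need = int(0.95 * len(marker))
        for c in contigs:
            target = c.bases
            if c.circular:  # the rotation origin may split the locus
                target = c.bases + c.bases[:len(marker) + 100]
            for probe in (marker, marker[:need],
                          revcomp(marker), revcomp(marker[:need])):
                if len(target) < len(probe):
                    continue
                res = edlib.align(probe, target, mode="HW",
                                  task="distance",
                                  k=int(0.01 * len(probe)) + 1)
                if 0 <= res["editDistance"] <= 0.01 * len(probe):
                    return True
        return False


def assess_quality(contigs: list[ContigSeq],
                   estimator: QualityEstimator) -> QualityRecord:
    """Run the configured quality estimator on a MAG's contigs."""
    return estimator(contigs)


def gate_candidates(mag_id: str, contigs: list[ContigSeq],
                    estimator: QualityEstimator
                    ) -> list[tuple[str, list[ContigSeq], QualityRecord]]:
    """Quality-gate an assembled bin, rescuing chimeric bins.

    Normally the whole bin is one MAG candidate. A multi-contig bin that
    fails retention on contamination (>= 10%) holds organisms that were
    clustered together yet assembled into separate contigs — those are
    gated individually (ids suffixed s1, s2, ...) so a mis-merged bin
    costs neither genome.
    """
    q = assess_quality(contigs, estimator)
    if retain_filter(q) or q.contamination < 10 or len(contigs) < 2:
        return [(mag_id, contigs, q)]
    return [(f"{mag_id}s{i + 1}", [c], assess_quality([c], estimator))
            for i, c in enumerate(contigs)]


# ---------------------------------------------------------------------------
# abundance and dereplication


def relative_abundance(mags: list[MAGRecord],
                       total_reads: ReadSet) -> dict[str, float]:
    """Per-MAG fraction: consumed read bases over the full dataset's
    bases (read-mapping abundance convention)."""
    total = total_reads.total_bases
    len_by_id = {r.id: len(r) for r in total_reads}
    out = {}
    for m in mags:
        consumed = sum(len_by_id.get(i, 0) for i in m.consumed_read_ids)
        out[m.mag_id] = consumed / total if total else 0.0
    return out


def _consumed_bases(rs: ReadSet, ids: set[str]) -> int:
    return sum(len(r) for r in rs if r.id in ids)


def estimate_ani(a: str, b: str, k: int = 21, sketch: int = 5000,
                 chunk: int = 1000) -> tuple[float, float]:
    """Mash-style ANI from a bottom-sketch Jaccard of canonical k-mers.

    Returns (ani, coverage). Coverage approximates alignment coverage:
    the fraction of a's chunk-kb windows sharing at least 3 k-mers with
    b — a window homologous at any ANI the primary clustering cares
    about shares many k-mers, an unrelated one essentially none.
    """
    if len(a) < 10_000 or len(b) < 10_000:
        raise ValueError("genomes must be >= 10 kb for ANI sketching")
    ha = canonical_kmer_hashes(a, k)
    ka = set(h for h in ha if h is not None)
    kb = set(h for h in canonical_kmer_hashes(b, k) if h is not None)
    sa = sorted(ka)[:sketch]
    sb = sorted(kb)[:sketch]
    merged = sorted(set(sa) | set(sb))[:sketch]
    inter = sum(1 for h in merged if h in ka and h in kb)
    j = inter / len(merged) if merged else 0.0
    covered = total = 0
    for s in range(0, len(ha) - chunk + 1, chunk):
        total += 1
        shared = 0
        for h in ha[s:s + chunk]:
            if h is not None and h in kb:
                shared += 1
                if shared >= 3:
                    covered += 1
                    break
    coverage = covered / total if total else 0.0
    if j <= 0:
        return 0.0, 0.0
    ani = 1.0 + (1.0 / k) * math.log(2.0 * j / (1.0 + j))
    return max(0.0, min(1.0, ani)), coverage


def _drep_score(m: MAGRecord) -> float:
    # dRep-like ranking: completeness - 5 x contamination + 0.5 log10 N50
    q = m.quality
    return (q.completeness - 5.0 * q.contamination
            + 0.5 * math.log10(max(q.n50, 1)))


def dereplicate(mags: list[MAGRecord], *, primary_ani: float = 0.90,
                secondary_ani: float = 0.97,
                min_cov: float = 0.65) -> list[MAGRecord]:
    """dRep-style two-level dereplication to one representative per
    secondary ANI cluster (single linkage at both levels)."""
    if not mags:
        return []
    n = len(mags)
    seqs = [m.sequence for m in mags]
    ani = np.zeros((n, n))
    cov = np.zeros((n, n))
    for i in range(n):
        ani[i, i] = cov[i, i] = 1.0
        for j in range(i + 1, n):
            if min(len(seqs[i]), len(seqs[j])) < 10_000:
                continue  # tiny fragments never cluster together
            a1, c1 = estimate_ani(seqs[i], seqs[j])
            a2, c2 = estimate_ani(seqs[j], seqs[i])
            ani[i, j] = ani[j, i] = max(a1, a2)
            cov[i, j] = cov[j, i] = max(c1, c2)

    def components(edge_ok) -> list[list[int]]:
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if edge_ok(i, j):
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        return list(groups.values())

    reps: list[MAGRecord] = []
    for prim in components(lambda i, j: ani[i, j] >= primary_ani
                           and cov[i, j] >= min_cov):
        sub = set(prim)
        for sec in components(lambda i, j: i in sub and j in sub
                              and ani[i, j] >= secondary_ani
                              and cov[i, j] >= min_cov):
            members = [m for m in sec if m in sub]
            if not members:
                continue
            best = max(members, key=lambda i: (_drep_score(mags[i]),
                                               mags[i].mag_id))
            reps.append(mags[best])
    reps.sort(key=lambda m: m.mag_id)
    return reps


# ---------------------------------------------------------------------------
# the iteration itself


@dataclass
class PipelineOptions:
    """Tunables of one workflow iteration (desk-scale defaults)."""

    min_bin_bases: int = 50_000
    cov_weight: float = 3.0
    linkage: str = "average"
    metric: str = "euclidean"
    cut_mode: str = "noise"
    phasing_k: int = 15
    phasing_w: int = 10
    min_score: int = 3
    tie_ratio: float = 0.8
    min_long_reads: int = 50
    min_overlap: int = 500
    min_chain_score: int = 10
    polish_rounds: int = 2
    min_bridges: int = 3
    stop_threshold: float = 0.02
    max_iter: int = 11
    # per-iteration working subsample (0 = use all remaining reads)
    iter_long_bases: int = 0
    iter_short_bases: int = 0
    seed: int = 0


def run_iteration(state: IterationState, estimator: QualityEstimator,
                  opts: PipelineOptions) -> IterationState:
    """One pass of the workflow on the remaining reads.

    Draft-assemble (the working subsample of) the remaining long reads,
    bin the draft contigs, phase reads to bins, hybrid-assemble each bin,
    gate the MAGs, subtract qualified MAGs' reads from the remaining
    pools, and update the stop statistic.
    """
    it = state.iteration + 1
    long_rs, short_rs = state.remaining_long, state.remaining_short
    if opts.iter_long_bases and long_rs.total_bases > opts.iter_long_bases:
        long_rs = subsample_to_bases(long_rs, opts.iter_long_bases,
                                     seed=opts.seed + 1000 * it)
    if opts.iter_short_bases and short_rs.total_bases > opts.iter_short_bases:
        short_rs = subsample_to_bases(short_rs, opts.iter_short_bases,
                                      seed=opts.seed + 1000 * it + 1)
    new_state = replace(state, iteration=it,
                        accepted=list(state.accepted),
                        qualified_abundance_this_iter=0.0)
    if len(long_rs) == 0:
        return new_state

    # step 2: draft assembly of the remaining long reads
    draft = mini_olc_assemble(long_rs, min_overlap=opts.min_overlap,
                              min_chain_score=opts.min_chain_score)
    draft = [c for c in draft if len(c) >= 1000]
    if not draft:
        return new_state

    # steps 3 + 5: cluster draft contigs, amend
    profiles = [_binning.tnf_profile(c) for c in draft]
    features = _binning.build_feature_matrix(profiles,
                                             cov_weight=opts.cov_weight)
    Z = _binning.hierarchical_cluster(features, method=opts.linkage,
                                      metric=opts.metric)
    bins = _binning.cut_to_bins(Z, draft, profiles=profiles,
                                mode=opts.cut_mode,
                                min_bin_bases=opts.min_bin_bases)
    bins = _binning.amend_bins(bins, profiles, features)
    contig_map = {c.id: c for c in draft}
    real_bins = [b for b in bins if b.id != LEFTOVER_BIN]
    new_state.leftover_contigs = [
        contig_map[cid] for b in bins if b.id == LEFTOVER_BIN
        for cid in b.contig_ids]
    if not real_bins:
        return new_state

    # phasing
    idx = build_minimizer_index(real_bins, contig_map,
                                k=opts.phasing_k, w=opts.phasing_w)
    assign_long = assign_reads(long_rs, idx, min_score=opts.min_score,
                               tie_ratio=opts.tie_ratio)
    assign_short = assign_reads(short_rs, idx, min_score=opts.min_score,
                                tie_ratio=opts.tie_ratio)
    reads_by_id_l = {r.id: r for r in long_rs}
    reads_by_id_s = {r.id: r for r in short_rs}

    # per-bin hybrid assembly and gating
    mags_this_iter: list[MAGRecord] = []
    qualified: list[MAGRecord] = []
    for b in real_bins:
        bl = ReadSet([reads_by_id_l[i]
                      for i in sorted(assign_long.reads_of_bin(b.id))])
        bs = ReadSet([reads_by_id_s[i]
                      for i in sorted(assign_short.reads_of_bin(b.id))])
        res = assemble_bin(b.id, bl, bs,
                           backend=MiniOLCBackend(
                               min_overlap=opts.min_overlap,
                               min_chain_score=opts.min_chain_score),
                           min_long_reads=opts.min_long_reads,
                           polish_rounds=opts.polish_rounds,
                           min_bridges=opts.min_bridges)
        if res.status != "ok":
            logger.info("iteration %d: bin %s %s (%s)", it, b.id,
                        res.status, res.message)
            continue
        new_state.leftover_contigs.extend(res.dropped)
        for mag_id, contigs_i, qi in gate_candidates(
                f"it{it}_{b.id}", res.contigs, estimator):
            mag = MAGRecord(mag_id=mag_id, contigs=contigs_i, quality=qi,
                            tier=classify_tier(qi), iteration=it)
            if retain_filter(qi):
                mags_this_iter.append(mag)
            if is_qualified(qi):
                qualified.append(mag)

    # subtraction: fresh assignment of the full remaining reads against
    # the qualified MAGs' sequences
    consumed_bases = 0
    if qualified:
        mag_bins = [CandidateBin(id=m.mag_id,
                                 contig_ids=[c.id for c in m.contigs])
                    for m in qualified]
        mag_contigs = {c.id: c for m in qualified for c in m.contigs}
        midx = build_minimizer_index(mag_bins, mag_contigs,
                                     k=opts.phasing_k, w=opts.phasing_w)
        for rs_name in ("remaining_long", "remaining_short"):
            rs = getattr(state, rs_name)
            asg = assign_reads(rs, midx, min_score=opts.min_score,
                               tie_ratio=opts.tie_ratio)
            for m in qualified:
                ids = asg.reads_of_bin(m.mag_id)
                m.consumed_read_ids |= ids
                consumed_bases += _consumed_bases(rs, ids)
            all_consumed = {i for m in qualified
                            for i in m.consumed_read_ids}
            setattr(new_state, rs_name,
                    subtract_reads(rs, all_consumed))
    total = state.total_long_bases + state.total_short_bases
    for m in qualified:
        m.relative_abundance = (
            (_consumed_bases(state.remaining_long, m.consumed_read_ids)
             + _consumed_bases(state.remaining_short, m.consumed_read_ids))
            / total) if total else 0.0
    new_state.qualified_abundance_this_iter = (consumed_bases / total
                                               if total else 0.0)
    new_state.accepted.extend(mags_this_iter)
    logger.info("iteration %d: %d bins, %d retained MAGs, %d qualified, "
                "qualified abundance %.3f", it, len(real_bins),
                len(mags_this_iter), len(qualified),
                new_state.qualified_abundance_this_iter)
    return new_state


def run_pipeline(long_rs: ReadSet, short_rs: ReadSet,
                 estimator: QualityEstimator,
                 opts: PipelineOptions | None = None
                 ) -> tuple[IterationState, list[MAGRecord]]:
    """Run iterations until the stop rule fires; dereplicate the accepted
    MAGs into the final set."""
    opts = opts or PipelineOptions()
    state = IterationState(iteration=0, remaining_long=long_rs,
                           remaining_short=short_rs,
                           total_long_bases=long_rs.total_bases,
                           total_short_bases=short_rs.total_bases)
    while True:
        state = run_iteration(state, estimator, opts)
        if should_stop(state, threshold=opts.stop_threshold,
                       max_iter=opts.max_iter):
            break
    final = dereplicate(state.accepted) if state.accepted else []
    return state, final
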