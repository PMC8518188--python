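"""Synthetic communities and hybrid read sets with full ground truth.

Generates mock bacterial communities (single circular replicons with
optional shared-ancestor divergence, exact internal repeats and a planted
1.5-kb rRNA-like marker locus), ONT-like error-prone long reads and
Illumina-like accurate paired short reads, together with a truth table
mapping every read back to its genomic interval. The defaults mirror the
sequencing characteristics the pipeline is designed for: long reads at
86.7% mean accuracy with a lognormal length distribution floored at 1 kb,
and 2x150 short-read pairs at ~0.3% substitution error with an insert of
Normal(350, 50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import ContigSeq, ReadSet, SequenceRead, LONG, SHORT

BASES = np.array(list("ACGT"))

MARKER_LEN = 1500  # planted rRNA-like locus length (bp)


@dataclass
class CommunitySpec:
    """Parameters of a synthetic community.

    target_pairwise_ani: None for unrelated (i.i.d. random) genomes, or a
    scalar fraction in (0.5, 1] — genomes are then derived from a common
    ancestor by point mutation so that every pair sits at that ANI.
    abundance_model: "even" or ("lognormal", mu, sigma).
    """

    n_genomes: int = 8
    length_range: tuple[int, int] = (20_000, 50_000)
    target_pairwise_ani: float | None = None
    repeat_spec: tuple[int, int] = (0, 0)  # (n repeats per genome, repeat bp)
    abundance_model: object = "even"
    abundances: tuple[float, ...] | None = None  # explicit override
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.length_range[0] < 5000:
            raise ValueError("minimum genome length is 5,000 bp")
        a = self.target_pairwise_ani
        if a is not None and not (0.5 < a <= 1.0):
            raise ValueError("target_pairwise_ani must lie in (0.5, 1]")


@dataclass
class TruthTable:
    """Ground truth: genomes, abundances and per-read source intervals."""

    genomes: dict[str, str]  # genome id -> sequence
    abundances: dict[str, float]
    markers: dict[str, str]  # genome id -> planted marker sequence
    rrna_flags: dict[str, bool]
    # read id -> (genome id, start, end, strand); end may exceed the genome
    # length for reads wrapping the circular origin (coordinates mod L)
    read_origin: dict[str, tuple[str, int, int, str]] = field(
        default_factory=dict)

    def __post_init__(self):
        s = sum(self.abundances.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {s}, expected 1")


def _random_seq(rng: np.random.Generator, n: int, comp=None) -> str:
    if comp is None:
        return "".join(BASES[rng.integers(0, 4, n)])
    return "".join(BASES[rng.choice(4, n, p=comp)])


def _mutation_rate_for_ani(ani: float) -> float:
    # two genomes independently mutated at per-site rate m from one ancestor
    # match with probability (1-m)^2 + m^2/3; solve for the target ANI
    a, b, c = 4.0 / 3.0, -2.0, 1.0 - ani
    return (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)


def _point_mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.where(rng.random(arr.size) < rate)[0]
    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    for i in hits:
        arr[i] = lut[arr[i]][rng.integers(0, 3)]
    return arr.tobytes().decode()


def generate_community(spec: CommunitySpec) -> tuple[list[ContigSeq], TruthTable]:
    """Generate genomes + truth for a community spec (deterministic by seed).

    Genomes are single circular replicons. When target_pairwise_ani is set
    they descend from a common random ancestor by point mutation; each
    genome then receives its exact internal duplications (repeat_spec) and
    one planted rRNA-like marker locus recorded in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_genomes)]

    # (sequence, marker interval) per genome; related genomes inherit a
    # homologous marker locus from the ancestor (like a conserved rRNA
    # operon), unrelated genomes get independent random loci. Unrelated
    # genomes each draw their own base composition — the genome-specific
    # oligonucleotide signature that composition-based binning relies on
    # in real bacteria.
    seqs: list[tuple[str, int]] = []
    if spec.target_pairwise_ani is None:
        for n in lengths:
            comp = rng.dirichlet([6.0, 6.0, 6.0, 6.0])
            s = _random_seq(rng, n, comp)
            ins = int(rng.integers(0, n))
            s = s[:ins] + _random_seq(rng, MARKER_LEN, comp) + s[ins:]
            seqs.append((s, ins))
    else:
        m = _mutation_rate_for_ani(spec.target_pairwise_ani)
        ancestor = _random_seq(rng, max(lengths) + MARKER_LEN)
        ins = int(rng.integers(0, lo))
        for n in lengths:
            seqs.append((_point_mutate(rng, ancestor[:n + MARKER_LEN], m),
                         ins))

    genomes: dict[str, str] = {}
    markers: dict[str, str] = {}
    n_rep, rep_len = spec.repeat_spec
    for i, (s, ins) in enumerate(seqs):
        gid = f"g{i + 1}"
        markers[gid] = s[ins:ins + MARKER_LEN]
        for _ in range(n_rep):
            if rep_len <= 0 or rep_len >= len(s) // 2:
                break
            src = int(rng.integers(0, len(s) - rep_len))
            # duplications never land inside the marker locus
            dst = int(rng.integers(0, len(s) - MARKER_LEN))
            if dst >= ins:
                dst += MARKER_LEN
            s = s[:dst] + s[src:src + rep_len] + s[dst:]
            if dst < ins:
                ins += rep_len
        genomes[gid] = s

    if spec.abundances is not None:
        ab = np.asarray(spec.abundances, float)
        if ab.size != spec.n_genomes:
            raise ValueError("abundances length != n_genomes")
    elif spec.abundance_model == "even":
        ab = np.ones(spec.n_genomes)
    else:
        model, mu, sigma = spec.abundance_model
        if model != "lognormal":
            raise ValueError(f"unknown abundance model {model!r}")
        ab = rng.lognormal(mu, sigma, spec.n_genomes)
    ab = ab / ab.sum()
    abundances = {g: float(a) for g, a in zip(genomes, ab)}

    contigs = [ContigSeq(id=g, bases=s, circular=True)
               for g, s in genomes.items()]
    truth = TruthTable(genomes=genomes, abundances=abundances,
                       markers=markers,
                       rrna_flags={g: True for g in genomes})
    return contigs, truth


# ---------------------------------------------------------------------------
# long reads


def _inject_long_errors(rng: np.random.Generator, seq: str, err: float,
                        mix=(0.4, 0.3, 0.3)) -> str:
    """Apply i.i.d. per-base errors (substitution/insertion/deletion mix)."""
    out = []
    sub_p, ins_p, _ = mix
    r = rng.random(len(seq))
    kinds = rng.random(len(seq))
    subs = rng.integers(0, 3, len(seq))
    ins_bases = rng.integers(0, 4, len(seq))
    lut = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i, ch in enumerate(seq):
        if r[i] >= err:
            out.append(ch)
            continue
        kind = kinds[i]
        if kind < sub_p:
            out.append(lut[ch][subs[i]])
        elif kind < sub_p + ins_p:
            out.append(ch)
            out.append("ACGT"[ins_bases[i]])
        # else deletion: emit nothing
    return "".join(out)


def _pick_genomes(rng, truth: TruthTable, n: int) -> list[str]:
    gids = list(truth.genomes)
    # base-level sampling: a genome contributes reads in proportion to
    # abundance x length (cell abundance times genome size)
    w = np.array([truth.abundances[g] * len(truth.genomes[g]) for g in gids])
    w = w / w.sum()
    return [gids[i] for i in rng.choice(len(gids), n, p=w)]


def simulate_long_reads(genomes, truth: TruthTable, *,
                        mean_accuracy: float = 0.867,
                        mean_length: int = 8000,
                        depth: float = 30.0,
                        seed: int = 0,
                        min_length: int = 1000) -> ReadSet:
    """Simulate ONT-like long reads; truth.read_origin is updated in place.

    depth is the coverage of a genome at even abundance: a genome with
    community abundance a receives depth * a * n_genomes coverage. Read
    lengths are lognormal (median mean_length, sd factor 2) floored at
    min_length; genomes are circular so reads wrap the origin. Errors are
    i.i.d. per base at 40:30:30 substitution:insertion:deletion; the raw
    event rate is calibrated so that the realigned identity of the output
    matches mean_accuracy.
    """
    if not (0.7 <= mean_accuracy <= 1.0):
        raise ValueError("mean_accuracy must lie in [0.7, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    total = depth * sum(truth.abundances[g] * len(s)
                        for g, s in truth.genomes.items()) * len(truth.genomes)
    # identity = matches / alignment_length. Two corrections on top of
    # the nominal rate: insertions lengthen the alignment denominator
    # (factor 1/(0.7 + 0.3 t)), and optimal realignment explains away a
    # few percent of the injected edits (adjacent events collapse into
    # cheaper ones), measured at ~5.6% in the ONT-accuracy regime.
    e = 1.0 - mean_accuracy
    err = 1.056 * e / (0.7 + 0.3 * mean_accuracy)
    qual = min(40, int(round(-10 * math.log10(max(e, 1e-4)))))

    reads = []
    acc = 0
    sigma = math.log(2.0)
    n_guess = max(int(total / mean_length * 2), 16)
    while acc < total:
        gids = _pick_genomes(rng, truth, n_guess)
        lens = np.maximum(rng.lognormal(math.log(mean_length), sigma,
                                        n_guess), min_length).astype(int)
        for gid, ln in zip(gids, lens):
            if acc >= total:
                break
            g = truth.genomes[gid]
            ln = min(int(ln), len(g))
            start = int(rng.integers(0, len(g)))
            end = start + ln
            frag = g[start:end] if end <= len(g) else g[start:] + g[:end - len(g)]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                from ._seq import revcomp
                frag = revcomp(frag)
            if mean_accuracy < 1.0:
                frag = _inject_long_errors(rng, frag, err)
            if len(frag) < min_length:
                continue
            rid = f"L{len(reads)}"
            reads.append(SequenceRead(id=rid, bases=frag,
                                      quals=[qual] * len(frag),
                                      platform=LONG))
            truth.read_origin[rid] = (gid, start, end, strand)
            acc += len(frag)
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# short reads


def _short_qualities(rng, n: int, error_rate: float,
                     q_hi: int = 40, q_lo: int = 15):
    """Two-level quality mix whose implied error rate equals error_rate."""
    e_hi, e_lo = 10 ** (-q_hi / 10), 10 ** (-q_lo / 10)
    f_lo = min(max((error_rate - e_hi) / (e_lo - e_hi), 0.0), 1.0)
    return np.where(rng.random(n) < f_lo, q_lo, q_hi)


def simulate_short_reads(genomes, truth: TruthTable, *,
                         read_len: int = 150,
                         insert_mean: float = 350.0,
                         insert_sd: float = 50.0,
                         error_rate: float = 0.003,
                         depth: float = 100.0,
                         seed: int = 0) -> ReadSet:
    """Simulate proper-FR Illumina-like pairs (substitution errors only).

    Per-base Phred qualities are drawn from a two-level (Q40/Q15) mix whose
    expected error probability equals error_rate, and each base is then
    flipped with its own quality's error probability — qualities and errors
    are mutually consistent. Mates are named <id>/1 and <id>/2.
    """
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed the mean insert size")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    from ._seq import revcomp
    total = depth * sum(truth.abundances[g] * len(s)
                        for g, s in truth.genomes.items()) * len(truth.genomes)
    n_pairs = int(total / (2 * read_len))
    gids = _pick_genomes(rng, truth, n_pairs)
    reads = []
    for p, gid in enumerate(gids):
        g = truth.genomes[gid]
        L = len(g)
        ins = int(np.clip(rng.normal(insert_mean, insert_sd),
                          read_len, max(read_len, L)))
        start = int(rng.integers(0, L))
        frag = g[start:start + ins]
        if len(frag) < ins:
            frag += g[:ins - len(frag)]
        flip = rng.random() < 0.5  # which genomic strand R1 comes from
        if flip:
            frag = revcomp(frag)
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        for mate, seq in (("R1", r1), ("R2", r2)):
            if error_rate <= 0:
                quals = np.full(len(seq), 40)
                hits = np.empty(0, dtype=int)
            else:
                quals = _short_qualities(rng, len(seq), error_rate)
                perr = 10.0 ** (-quals / 10.0)
                hits = np.where(rng.random(len(seq)) < perr)[0]
            if hits.size:
                lut = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
                sl = list(seq)
                for i in hits:
                    sl[i] = lut[sl[i]][rng.integers(0, 3)]
                seq = "".join(sl)
            rid = f"S{p}/{1 if mate == 'R1' else 2}"
            reads.append(SequenceRead(id=rid, bases=seq,
                                      quals=list(map(int, quals)),
                                      platform=SHORT, mate=mate))
        strand = "-" if flip else "+"
        truth.read_origin[f"S{p}"] = (gid, start, start + ins, strand)
    return ReadSet(reads)
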