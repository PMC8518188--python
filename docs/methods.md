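# Methods

`hcbha` is a desk-scale implementation of an iterative haplotype-resolved
hierarchical-clustering-based hybrid assembly (HCBHA) workflow for
reconstructing (near-)complete genomes from complex metagenomes. The
input is a hybrid read set: error-prone long reads (ONT-like, ~87% base
accuracy) and accurate paired short reads (Illumina-like, 2x150). The
central idea is to *phase* both read sets into candidate bacterial
haplotype bins and to hybrid-assemble each bin as an independent
single-organism dataset, subtracting the reads of each qualified genome
and iterating on the remainder.

## Workflow

One iteration runs:

1. **Primary processing** — short reads kept at arithmetic mean Phred
   >= 30, long reads kept at length >= 1 kb. Mean base quality is the
   arithmetic mean of Phred scores (the common QC-tool convention), and
   mates are filtered independently.
2. **Draft assembly** of the (optionally subsampled) remaining long reads
   with the built-in mini OLC backend (below).
3. **Contig clustering** into candidate haplotype bins by canonical
   tetranucleotide frequency (TNF, 136 strand-symmetric 4-mer classes)
   plus weighted log-coverage, average-linkage Euclidean hierarchical
   clustering, and a noise-calibrated dendrogram cut.
4. **Read phasing** — every long read and short-read pair is assigned to
   the bin with which it shares the most distinct canonical window
   minimizers (k = 15, w = 10), provided the score reaches `min_score`
   (3) and the runner-up bin scores at most `tie_ratio` (0.8) of it.
   Exact ties and weak matches stay unassigned and carry forward to the
   next iteration.
5. **Per-bin hybrid assembly** — backend assembly of the bin's long
   reads, two rounds of short-read pileup polishing, long-read bridging
   of contig ends (>= 3 bridging reads, each anchored >= 500 bp on both
   sides), one more polish round over the merged sequence, then a
   coverage/composition outlier filter ("bin accuracy promotion").
6. **Quality gating** — each assembled genome is scored by the
   configured quality estimator. A MAG is *qualified* (and its reads are
   subtracted) iff completeness > 90%, contamination < 10% and contig
   count < 30; it is *retained* into the growing MAG collection iff
   completeness > 50% and contamination < 10%. All inequalities are
   strict: a genome at exactly 90% completeness does not qualify.
7. **Read subtraction** — reads are freshly assigned (same minimizer
   scoring) against the qualified MAGs' sequences and removed from the
   remaining pools. Whether subtraction should reuse the phasing
   assignment or re-map against the final sequences was an open design
   point; re-mapping was chosen because polishing and bridging change
   the sequences the reads must be attributed to.

Iterations stop when the qualified relative abundance of an iteration —
consumed read bases over the full dataset's bases — falls below 2%
(strict), or after 11 iterations. Retained MAGs from all iterations are
then dereplicated dRep-style: single-linkage primary clusters at ANI >=
0.90 with alignment coverage >= 0.65, secondary clusters at ANI >= 0.97,
one representative per secondary cluster maximizing
`completeness − 5·contamination + 0.5·log10(N50)` (an approximation of
dRep's scoring, not a reimplementation).

MIMAG-style tiers are assigned per MAG: *complete* if every contig is a
closed circle (regardless of estimated completeness — reduced genomes
legitimately fall below 90%), *HQ* if completeness >= 90, contamination
<= 5 and a full-length rRNA(-like) locus is present, *MQ* if
completeness >= 50 and contamination <= 10, else failed.

## The mini OLC backend

External assemblers (Flye-class, Unicycler-class) are pluggable through
the backend contract; the built-in backend is a deliberately small
overlap-layout-consensus assembler adequate for genomes up to ~100 kb at
up to ~50x depth:

- **Overlap**: all-vs-all candidate overlaps from shared canonical
  minimizers (k = 13, w = 8; repeat-heavy minimizers occurring > 60
  times are skipped), clustered on the dominant diagonal band (base
  width 200 bp + 12% of the span, re-centered once on the median).
  Overlaps need a chain of >= 10 shared minimizers spanning >= 500 bp.
  A read that extends neither end of its partner by more than the
  offset noise (100 bp + 1%) is contained and excluded from layout.
- **Layout**: greedy best-overlap extension from the longest unused
  read, rightward, then leftward after flipping the path. Each junction
  is refined by an infix edit-distance alignment of the backbone tail
  inside the next read; junctions below 55% identity break the layout.
- **Circularity**: a layout of a circular replicon runs past its own
  start (possibly several laps at high depth). The first re-occurrence
  of the 2-kb head (scanned left to right, so the smallest period wins)
  marks the period; the layout is trimmed to one period and flagged
  circular. The raw-backbone scan tolerates 35% edit distance (two
  ~87% reads diverge ~25%); the post-consensus scan 15%. A genome whose
  first 2 kb recur verbatim elsewhere (a >= 2-kb terminal repeat) would
  be falsely circularized — accepted as out of desk-scale scope.
- **Consensus**: every read (contained ones included) is mapped to its
  best backbone via one shared minimizer index, banded-aligned with
  edlib, and a per-column plurality pileup is called, including
  deletion columns and insertions (insertion presence is voted by
  pooled count because gap placement jitters between reads, then the
  plurality insertion sequence is applied). Two consensus rounds are
  run: the first removes most errors, which disambiguates alignments
  for the second. At 25-30x this leaves a draft around 99-99.5%
  identity, which short-read polishing lifts to Q30+.

## Short-read polishing

Reads are anchored on the draft by unique 21-mers (scanned at a stride,
median offset over consistent anchors, both orientations tried), locally
aligned in a +-25 bp band, and per-column changes (substitutions,
deletions, insertions) are applied only when supported by >= 3 reads
and >= 70% of the column coverage. Uncovered columns are never touched,
and a clean draft is a fixpoint. The 70%/3 threshold balances error
correction against haplotype smashing; both are configurable.

## Synthetic data

The simulator provides the study conditions and the ground truth every
test measures against:

- **Genomes** are single circular replicons (20-50 kb at desk scale).
  Unrelated genomes each draw their own base composition from
  Dirichlet(6,6,6,6) — the genome-specific oligonucleotide signature
  that makes composition-based binning meaningful, exactly as real
  bacterial genomes differ in GC and k-mer usage; uniform-composition
  random DNA would carry no binnable signal at all. Alternatively a
  community can descend from a common ancestor by point mutation to a
  target pairwise ANI (solved in closed form from the double-hit match
  probability). Each genome carries optional exact internal repeats and
  one planted 1.5-kb "rRNA-like" marker locus standing in for the
  full-length rRNA operon of the HQ tier (real rRNA detection is out of
  scope); the locus is homologous across ANI-related genomes, like a
  conserved operon. Marker recovery is tested by >= 99%-identity
  alignment over >= 95% of the locus, in both orientations and across
  the rotation origin of circular contigs.
- **Long reads**: lognormal lengths (median 8 kb, sd factor log 2)
  floored at 1 kb, positions uniform with origin wrap, strand uniform,
  i.i.d. per-base errors at 40:30:30 substitution:insertion:deletion.
  The per-base event rate is calibrated so that the *realigned
  identity* (matches over alignment columns) hits the requested mean
  accuracy: insertions lengthen the alignment denominator (factor
  1/(0.7 + 0.3t)), and optimal realignment explains away ~5.6% of the
  injected edits (adjacent events collapse into cheaper ones), giving
  e' = 1.056·(1 − t)/(0.7 + 0.3t). Measured accuracy lands within
  ±0.1 points of target in the 0.85-0.90 regime; the default 0.867
  reproduces the ONT-like ~Q8.76 regime.
- **Short reads**: proper FR pairs, insert ~ Normal(350, 50),
  substitution-only errors. Per-base qualities are drawn from a
  two-level Q40/Q15 mix whose expected error probability equals the
  requested rate, and each base is then flipped with its own quality's
  error probability — so emitted qualities and realized errors are
  mutually consistent, and the default 0.3% error rate passes the mean
  Q >= 30 input filter as real Illumina data does.
- **Abundances**: even, lognormal, or explicit. Abundance means cell
  abundance: a genome's expected base share is proportional to
  abundance x length, and `depth` is the coverage of a genome at even
  abundance (so uneven abundances scale coverage by a_g x n).

Not emulated: chimeric reads, adapters, quality drift along reads, GC
coverage bias, strain microdiversity within one species. Tests passing
on this generator show the pipeline's logic is sound under clean
community structure; they do not show robustness to those artifacts.

## Binning features and the cut rule

TNF columns are z-scored across contigs and the log(coverage+1) column
is z-scored and weighted (default 3.0). The workflow itself only
prescribes hierarchical clustering of draft contigs; TNF + coverage is
the field-standard signal and is what the simulator can test. The dendrogram cut was a
genuinely open design point. A largest-gap rule proved unreliable on
both edge regimes (one contig per genome, and several fragments per
genome), so the default cut is *noise-calibrated*: the expected squared
z-space distance between two contigs of the same genome is the summed
TNF multinomial sampling variance over the column variances, computable
from contig lengths; the cut sits 1.25x above the noisiest plausible
same-genome pair (preferring contigs >= 10 kb for the calibration).
Merges below the cut are sampling noise; merges above it are
composition signal. Fragments shorter than ~5 kb have noise approaching
the between-genome signal and cannot be reliably binned — they end up
pooled with the leftover bin via `min_bin_bases`.

Clusters smaller than `min_bin_bases` (50 kb default at desk scale;
a real-data preset would use ~200 kb) are pooled into a reserved
leftover bin that is excluded from assembly but not discarded. An
amendment pass then moves any contig to a clearly nearer bin centroid
(distance < (1 − 0.1) of the current one) until a fixpoint (<= 10
rounds).

## Reference-based evaluation

Contigs are aligned to truth genomes by unique-21-mer anchoring,
colinear chain splitting (diagonal band 50 + 5% of contig length), and
banded edit-distance extension; blocks need >= 90% identity over
>= 500 bp. Metrics follow the usual appraisal conventions:

- **AGF** — percent of the reference covered by the union of block
  intervals.
- **Purity** — 1 − unaligned MAG length / reference length, floored
  at 0.
- **Misassemblies** — QUAST-style breakpoints between consecutive
  blocks of a contig (different reference, different strand, or
  reference/contig gap disagreement > 1 kb), reported per Mb. When
  reference lengths are supplied the references are treated as
  circular, so a rotated assembly of a closed genome is not a
  breakpoint.
- **Indel rate** — reported per 100 kb (the QUAST convention),
  labeled explicitly in outputs.
- **Q-score** — fastmer-style −10·log10((mismatches + insertions +
  deletions) / aligned bases), capped at Q90 for zero-error assemblies
  (log of zero); the cap is documented in reports. The same convention
  maps 86.7% read accuracy to Q8.76.
- Best reference per MAG = maximal aligned reference bases, ties broken
  lexicographically.

The same machinery drives the reference-based quality estimator used in
synthetic mode: completeness := AGF of the best reference,
contamination := percent of aligned MAG bases hitting other references.
CheckM-class marker-gene estimation is an adapter contract only — any
callable mapping contigs to a QualityRecord plugs in for real data.

ANI between genomes is estimated Mash-style: bottom-sketch (s = 5000)
Jaccard j of canonical 21-mers, ANI = 1 + ln(2j/(1+j))/k. The
genome-coverage companion (dRep's `-nc`) is approximated as the
fraction of 1-kb windows sharing >= 3 k-mers with the partner genome — a
window homologous at any primary-clustering ANI shares many k-mers, an
unrelated one essentially none. (The raw fraction of shared k-mers
would be ~0.9^21 ≈ 0.11 at 90% ANI and could never clear a 0.65
coverage gate.)

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; 1-based only at report
  boundaries.
- Minimizer ties within a window select the leftmost position;
  dendrogram and argmax ties resolve to the lowest index / lexicographic
  id, so every stage is deterministic given inputs and seed.
- Zero-variance feature columns stay at 0 (no division by zero).
- Subsampling draws reads in a seeded random order until the base
  target is first reached; a target exceeding the input returns the
  whole input with a warning.
- An empty bin or a backend failure marks the bin failed and the
  iteration continues; a bin whose contigs are all rejected by the
  promoter raises a bin-collapse error that is likewise contained.
- `subsample_to_bases`, the simulator, and the pipeline all derive
  their randomness from explicit integer seeds.

## Problem sizes

The package is exercised at desk scale: communities of 3-8 genomes of
20-50 kb, long reads at 25-30x and short reads at 60-100x per genome,
which one CPU handles in minutes. The iterative-subtraction experiment
uses 5 genomes of 12 kb whose abundances span 50x (50:1:1:1:1), a read
pool deep enough to give the rarest genome ~15x long-read coverage,
and per-iteration working subsamples of 2 Mb long / 4 Mb short reads —
the regime where the dominant genome crowds the subsample until its
reads are subtracted. `min_long_reads` is scaled to 10 there (the
default 50 assumes bins holding >= 100 kb of genome). These sizes were chosen so that every
stage — including the end-to-end iterative run — is testable as a unit;
the architecture (pluggable backends, estimator contract, config
presets) is what would scale a real deployment, not the built-in OLC
assembler.

## Known limitations

- The mini OLC backend cannot resolve repeats longer than its reads and
  is not haplotype-aware; strain mixtures within one species collapse
  into one consensus (the tie rule leaves truly ambiguous reads
  unassigned rather than splitting them).
- Binning needs contigs >= ~10 kb and genuinely distinct genome
  composition; at pairwise ANI ≳ 0.9 composition no longer separates
  genomes and phasing precision degrades.
- Marker-locus detection misses loci recovered at < 95% length or
  < 99% identity, by design (the HQ gate is meant to be stringent).
- The leftover contig pool is recomputed each iteration from the
  remaining reads rather than carried as sequence — the reads of
  leftover contigs stay in the pool, so no information is lost, but a
  borderline bin may be re-assembled from scratch.
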