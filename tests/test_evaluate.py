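import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcbha._seq import revcomp
from hcbha.evaluate import (AlignmentBlock, align_to_reference,
                            aligned_genome_fraction, contiguity,
                            evaluate_mags, misassembly_count, n50, purity,
                            qscore, reports_to_frame, unaligned_bases)
from hcbha.io_core import ContigSeq

from conftest import random_seq


def _block(cid="c", qs=0, qe=1000, rid="r", rs=0, re=1000, strand="+",
           m=1000, x=0, i=0, d=0):
    return AlignmentBlock(contig_id=cid, q_start=qs, q_end=qe, ref_id=rid,
                          r_start=rs, r_end=re, strand=strand, matches=m,
                          mismatches=x, insertions=i, deletions=d)


class TestAlignToReference:
    def test_exact_copy_single_full_block(self, rng):
        ref = random_seq(rng, 10_000)
        blocks = align_to_reference([ContigSeq(id="c", bases=ref)],
                                    {"r": ref})
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.q_start, b.q_end) == (0, 10_000)
        assert (b.r_start, b.r_end) == (0, 10_000)
        assert b.identity == 1.0

    def test_one_percent_substitutions_identity(self, rng):
        ref = random_seq(rng, 10_000)
        seq = list(ref)
        pos = rng.choice(len(ref), 100, replace=False)
        for p in pos:
            seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1) % 4]
        blocks = align_to_reference([ContigSeq(id="c",
                                               bases="".join(seq))],
                                    {"r": ref})
        assert len(blocks) == 1
        # exactly 100 mismatching positions planted
        assert blocks[0].identity == pytest.approx(0.99, abs=0.001)

    def test_reverse_complement_found_on_minus_strand(self, rng):
        ref = random_seq(rng, 5_000)
        blocks = align_to_reference(
            [ContigSeq(id="c", bases=revcomp(ref))], {"r": ref})
        assert len(blocks) == 1 and blocks[0].strand == "-"

    def test_unrelated_no_blocks(self, rng):
        blocks = align_to_reference(
            [ContigSeq(id="c", bases=random_seq(rng, 5000))],
            {"r": random_seq(rng, 5000)})
        assert blocks == []


class TestCoverageMetrics:
    def test_agf_full(self):
        assert aligned_genome_fraction([_block()], 1000) == 100.0

    def test_agf_union_overlapping_blocks(self):
        blocks = [_block(rs=0, re=5000), _block(rs=3000, re=8000)]
        assert aligned_genome_fraction(blocks, 10_000) == 80.0

    def test_agf_empty(self):
        assert aligned_genome_fraction([], 10_000) == 0.0

    def test_purity_formula(self):
        assert purity(100_000, 0, 100_000) == 1.0
        assert purity(100_000, 600, 100_000) == pytest.approx(0.994)

    def test_purity_floor(self):
        assert purity(300_000, 200_000, 100_000) == 0.0

    def test_unaligned_bases(self, rng):
        c = ContigSeq(id="c", bases=random_seq(rng, 2000))
        blocks = [_block(cid="c", qs=0, qe=1500)]
        assert unaligned_bases([c], blocks) == 500


class TestMisassemblies:
    def test_colinear_no_breakpoints(self):
        blocks = [_block(qs=0, qe=1000, rs=0, re=1000),
                  _block(qs=1100, qe=2000, rs=1100, re=2000)]
        assert misassembly_count(blocks) == 0

    def test_distant_halves_one_breakpoint(self):
        blocks = [_block(qs=0, qe=1000, rs=0, re=1000),
                  _block(qs=1000, qe=2000, rs=51_000, re=52_000)]
        assert misassembly_count(blocks) == 1

    def test_strand_flip_is_breakpoint(self):
        blocks = [_block(qs=0, qe=1000, rs=0, re=1000),
                  _block(qs=1000, qe=2000, rs=1000, re=2000, strand="-")]
        assert misassembly_count(blocks) == 1

    def test_circular_wrap_not_a_breakpoint(self):
        blocks = [_block(qs=0, qe=1000, rs=9_000, re=10_000),
                  _block(qs=1000, qe=2000, rs=0, re=1000)]
        assert misassembly_count(blocks, ref_lengths={"r": 10_000}) == 0
        assert misassembly_count(blocks) == 1


class TestQscore:
    def test_logarithm_scale(self):
        assert qscore(1, 0, 0, 10_000) == pytest.approx(40.0)
        assert qscore(10, 5, 5, 200_000) == pytest.approx(40.0)

    def test_zero_errors_capped(self):
        assert qscore(0, 0, 0, 10_000) == 90.0

    def test_ont_convention_consistency(self):
        # an error fraction of 13.3% corresponds to Q8.76
        assert qscore(133, 0, 0, 1000) == pytest.approx(8.76, abs=0.01)

    def test_strictly_decreasing_in_errors(self):
        qs = [qscore(e, 0, 0, 100_000) for e in (1, 10, 100, 1000)]
        assert qs == sorted(qs, reverse=True)
        assert qscore(10, 0, 0, 100_000) == pytest.approx(40.0)

    def test_zero_aligned_errors(self):
        with pytest.raises(ValueError):
            qscore(0, 0, 0, 0)


def brute_force_n50(lengths):
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L


class TestN50:
    def test_examples(self):
        assert n50([10]) == 10
        assert n50([5, 4, 3, 2, 1]) == 4
        assert n50([7, 7, 7]) == 7

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=10_000),
                    min_size=1, max_size=50))
    def test_matches_brute_force(self, lengths):
        assert n50(lengths) == brute_force_n50(lengths)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            n50([])


class TestContiguity:
    def test_examples(self):
        assert contiguity([600, 400]) == 60.0
        assert contiguity([123]) == 100.0
        assert contiguity([5, 5]) == 50.0


class TestEvaluateMags:
    def test_exact_mag_perfect_scores(self, rng):
        ref = random_seq(rng, 20_000)
        reports = evaluate_mags(
            {"m1": [ContigSeq(id="c1", bases=ref)]}, {"g1": ref})
        r = reports[0]
        assert r.agf == 100.0
        assert r.purity == 1.0
        assert r.misassemblies == 0
        assert r.qscore == 90.0
        assert r.contiguity == 100.0

    def test_empty_mag_set(self):
        assert evaluate_mags({}, {"g": "ACGT" * 1000}) == []

    def test_summary_row(self, rng):
        ref = random_seq(rng, 20_000)
        reports = evaluate_mags(
            {"m1": [ContigSeq(id="c1", bases=ref)]}, {"g1": ref})
        df = reports_to_frame(reports)
        assert df.iloc[-1]["mag_id"] == "summary"
        assert df.iloc[-1]["agf"] == 100.0


class TestOracleEquivalence:
    """Block-based AGF/purity vs exhaustive per-base truth labeling."""

    def test_agf_purity_match_per_base_labeling(self, rng):
        ref = random_seq(rng, 30_000)
        # MAG = two clean fragments + one foreign contig
        frags = [ref[2_000:12_000], ref[15_000:27_000]]
        foreign = random_seq(rng, 4_000)
        contigs = [ContigSeq(id=f"c{i}", bases=s)
                   for i, s in enumerate(frags + [foreign])]
        blocks = align_to_reference(contigs, {"r": ref})
        agf = aligned_genome_fraction(blocks, len(ref))
        # oracle: label each reference base covered by any planted frag
        covered = np.zeros(len(ref), bool)
        covered[2_000:12_000] = True
        covered[15_000:27_000] = True
        assert agf == pytest.approx(100 * covered.mean(), abs=0.2)
        una = unaligned_bases(contigs, blocks)
        assert una == pytest.approx(4_000, abs=50)
        pur = purity(sum(len(c) for c in contigs), una, len(ref))
        assert pur == pytest.approx(1 - 4_000 / 30_000, abs=0.002)


class TestBlocksPaf:
    def test_write_blocks_paf_roundtrip_columns(self, tmp_path, rng):
        ref = random_seq(rng, 8000)
        contigs = [ContigSeq(id="c", bases=ref)]
        blocks = align_to_reference(contigs, {"r": ref})
        out = tmp_path / "blocks.paf"
        from hcbha.evaluate import write_blocks_paf
        write_blocks_paf(out, blocks, {"c": 8000}, {"r": 8000})
        f = out.read_text().strip().split("\t")
        assert f[0] == "c" and f[5] == "r"
        assert int(f[9]) == 8000 and f[4] == "+"
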