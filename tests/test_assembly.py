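import numpy as np
import pytest

from hcbha._seq import alignment_identity, revcomp
from hcbha.assembly import (BinCollapseError, MiniOLCBackend,
                            assemble_bin, improve_contiguity,
                            mini_olc_assemble, polish_with_short_reads,
                            promote_bin)
from hcbha.evaluate import n50
from hcbha.io_core import ContigSeq, ReadSet, SequenceRead
from hcbha.simdata import (CommunitySpec, generate_community,
                           simulate_long_reads, simulate_short_reads)

from conftest import random_seq, tile_reads


def _best_identity(contig, genome):
    doubled = genome + genome
    return max(alignment_identity(contig, doubled, mode="HW"),
               alignment_identity(revcomp(contig), doubled, mode="HW"))


class TestMiniOLC:
    def test_single_read_identity(self, rng):
        r = SequenceRead(id="r", bases=random_seq(rng, 2000),
                         platform="long")
        out = mini_olc_assemble(ReadSet([r]))
        assert len(out) == 1 and out[0].bases == r.bases

    def test_error_free_linear_tiling_reconstructs(self, rng):
        genome = random_seq(rng, 20_000)
        rs = tile_reads(genome, 5000, 250)  # 20x, 5-kb reads
        out = mini_olc_assemble(rs)
        assert len(out) == 1
        c = out[0]
        assert not c.circular
        # exact reconstruction of a linear genome
        assert c.bases == genome or revcomp(c.bases) == genome

    def test_error_free_circular_flagged_and_exact(self, rng):
        genome = random_seq(rng, 20_000)
        rs = tile_reads(genome, 5000, 250, circular=True)
        out = mini_olc_assemble(rs)
        assert len(out) == 1
        c = out[0]
        assert c.circular
        doubled = genome + genome
        assert c.bases in doubled or revcomp(c.bases) in doubled
        assert abs(len(c) - len(genome)) <= 5

    def test_noisy_reads_high_identity_draft(self):
        spec = CommunitySpec(n_genomes=1, length_range=(20_000, 20_000),
                             seed=61)
        genomes, truth = generate_community(spec)
        rs = simulate_long_reads(genomes, truth, mean_accuracy=0.867,
                                 depth=25, seed=62)
        out = mini_olc_assemble(rs)
        big = max(out, key=len)
        assert _best_identity(big.bases, truth.genomes["g1"]) >= 0.98
        assert big.coverage > 10

    def test_no_reads_errors(self):
        with pytest.raises(ValueError):
            mini_olc_assemble(ReadSet([]))


class TestPolish:
    @pytest.fixture
    def scene(self):
        spec = CommunitySpec(n_genomes=1, length_range=(20_000, 20_000),
                             seed=71)
        genomes, truth = generate_community(spec)
        short = simulate_short_reads(genomes, truth, error_rate=0.0,
                                     depth=50, seed=72)
        return truth.genomes["g1"], short

    def test_idempotent_on_clean_draft(self, scene):
        genome, short = scene
        draft = ContigSeq(id="d", bases=genome)
        out = polish_with_short_reads(draft, short, rounds=1)
        assert out.bases == genome

    def test_planted_errors_corrected(self, scene, rng):
        genome, short = scene
        corrupted = list(genome)
        hits = rng.choice(len(genome), int(0.05 * len(genome)),
                          replace=False)
        for i in hits:
            corrupted[i] = "ACGT"[(("ACGT".index(corrupted[i])) + 1) % 4]
        draft = ContigSeq(id="d", bases="".join(corrupted))
        out = polish_with_short_reads(draft, short, rounds=2)
        assert alignment_identity(out.bases, genome) >= 0.999

    def test_uncovered_region_unchanged(self, rng):
        genome = random_seq(rng, 20_000)
        junk = random_seq(rng, 3000)  # no reads cover this appendix
        short = tile_reads(genome, 150, 3, prefix="s")  # 50x, linear
        draft = ContigSeq(id="d", bases=genome + junk)
        out = polish_with_short_reads(draft, short, rounds=1)
        assert out.bases.endswith(junk)
        assert out.bases == genome + junk  # and clean input is untouched

    def test_no_anchorable_reads_warns_and_returns(self, rng, caplog):
        draft = ContigSeq(id="d", bases=random_seq(rng, 2000))
        junk = ReadSet([SequenceRead(id="s", bases=random_seq(rng, 150),
                                     platform="short")])
        out = polish_with_short_reads(draft, junk, rounds=1)
        assert out.bases == draft.bases


class TestImproveContiguity:
    def test_no_bridges_unchanged(self, rng):
        contigs = [ContigSeq(id="a", bases=random_seq(rng, 5000)),
                   ContigSeq(id="b", bases=random_seq(rng, 5000))]
        out = improve_contiguity(contigs, ReadSet([]))
        assert [c.id for c in out] == ["a", "b"]

    def test_split_genome_merged_by_spanning_reads(self, rng):
        genome = random_seq(rng, 24_000)
        a = ContigSeq(id="a", bases=genome[:11_500])
        b = ContigSeq(id="b", bases=genome[12_500:])  # 1-kb gap
        spans = ReadSet([
            SequenceRead(id=f"s{i}",
                         bases=genome[10_000 - 300 * i:14_500 + 300 * i],
                         platform="long")
            for i in range(4)])
        out = improve_contiguity([a, b], spans, min_bridges=3)
        assert len(out) == 1
        merged = out[0]
        ident = max(alignment_identity(merged.bases, genome),
                    alignment_identity(revcomp(merged.bases), genome))
        assert ident >= 0.995
        # N50 never decreases
        assert n50([len(c) for c in out]) >= n50([11_500, 11_500])

    def test_self_bridge_circularizes(self, rng):
        genome = random_seq(rng, 20_000)
        contig = ContigSeq(id="a", bases=genome)
        wrap = ReadSet([
            SequenceRead(id=f"w{i}",
                         bases=genome[-(2000 + 100 * i):]
                         + genome[:2000 + 100 * i],
                         platform="long")
            for i in range(4)])
        out = improve_contiguity([contig], wrap, min_bridges=3)
        assert len(out) == 1 and out[0].circular


class TestPromoteBin:
    def _contigs(self, rng, covs, comp=None):
        return [ContigSeq(id=f"c{i}", bases=random_seq(rng, 12_000),
                          coverage=c) for i, c in enumerate(covs)]

    def test_homogeneous_unchanged(self, rng):
        contigs = self._contigs(rng, [100, 102, 98, 101])
        kept, dropped = promote_bin(contigs)
        assert len(kept) == 4 and not dropped

    def test_coverage_outlier_dropped(self, rng):
        contigs = self._contigs(rng, [100, 102, 98, 101, 10])
        kept, dropped = promote_bin(contigs)
        assert [c.id for c in dropped] == ["c4"]

    def test_all_dropped_raises(self):
        with pytest.raises(BinCollapseError):
            promote_bin([])

    def test_conservation(self, rng):
        contigs = self._contigs(rng, [100, 99, 5])
        kept, dropped = promote_bin(contigs)
        assert sorted(c.id for c in kept + dropped) == \
            sorted(c.id for c in contigs)


class TestAssembleBin:
    def test_empty_bin_fails_gracefully(self):
        res = assemble_bin("b1", ReadSet([]), ReadSet([]))
        assert res.status == "failed" and not res.contigs

    def test_clean_bin_end_to_end(self):
        spec = CommunitySpec(n_genomes=1, length_range=(20_000, 20_000),
                             seed=81)
        genomes, truth = generate_community(spec)
        long_rs = simulate_long_reads(genomes, truth, depth=25, seed=82)
        short_rs = simulate_short_reads(genomes, truth, depth=60, seed=83)
        res = assemble_bin("b1", long_rs, short_rs)
        assert res.status == "ok"
        assert 1 <= len(res.contigs) <= 2
        big = max(res.contigs, key=len)
        assert _best_identity(big.bases, truth.genomes["g1"]) >= 0.999

    def test_deterministic(self):
        spec = CommunitySpec(n_genomes=1, length_range=(20_000, 20_000),
                             seed=84)
        genomes, truth = generate_community(spec)
        long_rs = simulate_long_reads(genomes, truth, depth=20, seed=85)
        a = assemble_bin("b", long_rs, ReadSet([]),
                         backend=MiniOLCBackend())
        b = assemble_bin("b", long_rs, ReadSet([]),
                         backend=MiniOLCBackend())
        assert [c.bases for c in a.contigs] == [c.bases for c in b.contigs]
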