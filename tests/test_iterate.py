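import pytest

from hcbha._seq import alignment_identity
from hcbha.io_core import ContigSeq, ReadSet, SequenceRead
from hcbha.iterate import (IterationState, MAGRecord, QualityRecord,
                           ReferenceQualityEstimator, classify_tier,
                           dereplicate, estimate_ani, is_qualified,
                           retain_filter, should_stop)
from hcbha.simdata import CommunitySpec, generate_community

from conftest import random_seq


def _q(completeness=95, contamination=1, n_contigs=1, n50=1_000_000,
       total_bp=2_000_000, circular=False, rrna=False):
    return QualityRecord(completeness=completeness,
                         contamination=contamination, n_contigs=n_contigs,
                         n50=n50, total_bp=total_bp, circular_all=circular,
                         rrna_full=rrna)


class TestGates:
    @pytest.mark.parametrize("c,con,n,expect", [
        (91, 9, 29, True),    # all three strict bounds satisfied
        (90, 5, 10, False),   # "more than 90" is strict
        (90.0001, 5, 10, True),
        (95, 10, 10, False),  # "less than 10" is strict
        (95, 5, 30, False),   # "less than 30" is strict
        (100, 0, 1, True),
    ])
    def test_is_qualified(self, c, con, n, expect):
        assert is_qualified(_q(c, con, n)) is expect

    @pytest.mark.parametrize("c,con,expect", [
        (51, 9.9, True),
        (50, 5, False),       # "more than 50" is strict
        (99, 10, False),      # "less than 10" is strict
        (50.5, 0, True),
    ])
    def test_retain_filter(self, c, con, expect):
        assert retain_filter(_q(c, con)) is expect

    @pytest.mark.parametrize("kw,tier", [
        (dict(completeness=85, circular=True), "complete"),
        (dict(completeness=92, contamination=4, rrna=True), "HQ"),
        (dict(completeness=92, contamination=4, rrna=False), "MQ"),
        (dict(completeness=90, contamination=5, rrna=True), "HQ"),
        (dict(completeness=89.9, contamination=4, rrna=True), "MQ"),
        (dict(completeness=50, contamination=10), "MQ"),
        (dict(completeness=49.9, contamination=1), "failed"),
        (dict(completeness=60, contamination=10.1), "failed"),
    ])
    def test_classify_tier(self, kw, tier):
        assert classify_tier(_q(**kw)) == tier


class TestShouldStop:
    def _state(self, qa, iteration=1):
        empty = ReadSet([])
        return IterationState(iteration=iteration, remaining_long=empty,
                              remaining_short=empty,
                              qualified_abundance_this_iter=qa)

    def test_below_threshold_stops(self):
        assert should_stop(self._state(0.019)) is True

    def test_at_threshold_continues(self):
        assert should_stop(self._state(0.020)) is False

    def test_max_iterations_stops_regardless(self):
        assert should_stop(self._state(0.5, iteration=11)) is True
        assert should_stop(self._state(0.5, iteration=10)) is False


class TestReferenceQuality:
    @pytest.fixture
    def community(self):
        spec = CommunitySpec(n_genomes=2, length_range=(20_000, 20_000),
                             seed=91)
        return generate_community(spec)

    def test_exact_copy(self, community):
        _, truth = community
        est = ReferenceQualityEstimator(references=truth.genomes,
                                        markers=truth.markers)
        q = est([ContigSeq(id="c", bases=truth.genomes["g1"])])
        assert q.completeness == 100.0
        assert q.contamination == 0.0
        assert q.rrna_full

    def test_chimeric_mag_contamination(self, community):
        _, truth = community
        est = ReferenceQualityEstimator(references=truth.genomes,
                                        markers=truth.markers)
        ga, gb = truth.genomes["g1"], truth.genomes["g2"]
        contigs = [
            ContigSeq(id="a", bases=ga[:int(0.9 * len(ga))]),
            ContigSeq(id="b", bases=gb[:2000]),  # foreign 2-kb contig
        ]
        q = est(contigs)
        assert q.completeness == pytest.approx(90, abs=2)
        expected_cont = 100 * 2000 / (0.9 * len(ga) + 2000)
        assert q.contamination == pytest.approx(expected_cont, abs=1.5)

    def test_empty_contigs_error(self, community):
        _, truth = community
        est = ReferenceQualityEstimator(references=truth.genomes)
        with pytest.raises(ValueError):
            est([])


class TestEstimateAni:
    def test_identical_genomes(self, rng):
        g = random_seq(rng, 20_000)
        ani, cov = estimate_ani(g, g)
        assert ani == 1.0 and cov == 1.0

    def test_mutated_copy_matches_alignment_identity(self, rng):
        spec = CommunitySpec(n_genomes=2, length_range=(20_000, 20_000),
                             target_pairwise_ani=0.95, seed=92)
        _, truth = generate_community(spec)
        a, b = truth.genomes["g1"], truth.genomes["g2"]
        ani, cov = estimate_ani(a, b)
        assert 0.94 <= ani <= 0.96
        ident = alignment_identity(a, b)
        assert abs(ani - ident) <= 0.01
        assert cov > 0.9

    def test_unrelated_low_ani(self, rng):
        a, b = random_seq(rng, 20_000), random_seq(rng, 20_000)
        ani, cov = estimate_ani(a, b)
        assert ani <= 0.8
        assert cov < 0.05

    def test_short_genomes_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_ani(random_seq(rng, 5000), random_seq(rng, 20_000))


def _mag(mag_id, seq, completeness=95.0, contamination=1.0, n50v=None):
    contigs = [ContigSeq(id=f"{mag_id}_c", bases=seq)]
    q = QualityRecord(completeness=completeness,
                      contamination=contamination, n_contigs=1,
                      n50=n50v or len(seq), total_bp=len(seq))
    return MAGRecord(mag_id=mag_id, contigs=contigs, quality=q, tier="HQ",
                     iteration=1)


class TestDereplicate:
    def test_duplicates_collapse_to_best(self, rng):
        g = random_seq(rng, 20_000)
        a = _mag("a", g, completeness=99)
        b = _mag("b", g, completeness=80)
        out = dereplicate([a, b])
        assert [m.mag_id for m in out] == ["a"]

    def test_same_primary_distinct_secondary_both_kept(self):
        spec = CommunitySpec(n_genomes=2, length_range=(20_000, 20_000),
                             target_pairwise_ani=0.95, seed=93)
        _, truth = generate_community(spec)
        a = _mag("a", truth.genomes["g1"])
        b = _mag("b", truth.genomes["g2"])
        out = dereplicate([a, b])
        assert sorted(m.mag_id for m in out) == ["a", "b"]

    def test_unrelated_all_kept(self, rng):
        mags = [_mag(f"m{i}", random_seq(rng, 20_000)) for i in range(3)]
        out = dereplicate(mags)
        assert len(out) == 3

    def test_idempotent(self, rng):
        g = random_seq(rng, 20_000)
        mags = [_mag("a", g), _mag("b", g),
                _mag("c", random_seq(rng, 20_000))]
        once = dereplicate(mags)
        twice = dereplicate(once)
        assert [m.mag_id for m in once] == [m.mag_id for m in twice]


class TestRelativeAbundance:
    def _reads(self, n, length=100):
        return ReadSet([SequenceRead(id=f"r{i}", bases="A" * length,
                                     platform="long") for i in range(n)])

    def _mag_with(self, mag_id, ids, rng_seq):
        q = QualityRecord(completeness=95, contamination=1, n_contigs=1,
                          n50=20_000, total_bp=20_000)
        return MAGRecord(mag_id=mag_id,
                         contigs=[ContigSeq(id="c", bases=rng_seq)],
                         quality=q, tier="HQ", iteration=1,
                         consumed_read_ids=ids)

    def test_all_and_none_consumed(self, rng):
        from hcbha.iterate import relative_abundance
        seq = random_seq(rng, 100)
        rs = self._reads(10)
        a = self._mag_with("a", {f"r{i}" for i in range(10)}, seq)
        b = self._mag_with("b", set(), seq)
        ab = relative_abundance([a, b], rs)
        assert ab["a"] == 1.0 and ab["b"] == 0.0

    def test_fractions_by_base_share(self, rng):
        from hcbha.iterate import relative_abundance
        seq = random_seq(rng, 100)
        rs = self._reads(10)
        a = self._mag_with("a", {"r0", "r1", "r2"}, seq)
        b = self._mag_with("b", {"r3", "r4"}, seq)
        ab = relative_abundance([a, b], rs)
        assert ab["a"] == pytest.approx(0.3)
        assert ab["b"] == pytest.approx(0.2)


class TestGateCandidates:
    @pytest.fixture
    def community(self):
        spec = CommunitySpec(n_genomes=2, length_range=(20_000, 20_000),
                             seed=95)
        return generate_community(spec)

    def test_clean_bin_stays_whole(self, community):
        from hcbha.iterate import gate_candidates
        _, truth = community
        est = ReferenceQualityEstimator(references=truth.genomes,
                                        markers=truth.markers)
        contigs = [ContigSeq(id="c", bases=truth.genomes["g1"],
                             circular=True)]
        out = gate_candidates("m", contigs, est)
        assert len(out) == 1 and out[0][0] == "m"

    def test_chimeric_bin_split_per_contig(self, community):
        from hcbha.iterate import gate_candidates, retain_filter
        _, truth = community
        est = ReferenceQualityEstimator(references=truth.genomes,
                                        markers=truth.markers)
        # two complete genomes mis-clustered into one bin
        contigs = [ContigSeq(id="a", bases=truth.genomes["g1"],
                             circular=True),
                   ContigSeq(id="b", bases=truth.genomes["g2"],
                             circular=True)]
        out = gate_candidates("m", contigs, est)
        assert len(out) == 2
        for mag_id, cs, q in out:
            assert len(cs) == 1
            assert retain_filter(q)
            assert q.completeness == 100.0
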