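"""Tests for the four site features and focal re-alignment."""

import numpy as np
import pytest

from splicejump.candidate_sites import CandidateSite, Direction, Origin
from splicejump.features import (
    FeatureVector,
    RealignStatus,
    SiteIndex,
    anchor_mean_coverage,
    count_clipped_reads,
    count_discordant_encompassing,
    count_realigned_segments,
    coverage_difference,
    integrate_new_sites,
    max_mismatches,
    normalize_features,
    placement_discordant,
    realign_clipped_segment,
)
from splicejump.io_align import (
    ClipEvent,
    ClipSide,
    CoverageTrack,
    Genome,
    InsertSizeModel,
    PairIndex,
    extract_clip_events,
)

from conftest import make_record

MODEL = InsertSizeModel(m=300, v=30)


def _random_genome(n, seed=0):
    rng = np.random.default_rng(seed)
    return rng.choice(list("ACGT"), size=n)


def _pair_index(*record_pairs):
    idx = PairIndex()
    records = [r for pair in record_pairs for r in pair]
    return PairIndex.build(records, MODEL)


def site(pos, direction, contig="chr", origin=Origin.CLIP):
    return CandidateSite(contig, pos, direction, origin, merged_from=[pos])


class TestCounts:
    def test_clipped_reads_distinct(self):
        s = site(100, Direction.DONOR)
        for name in "ABC":
            s.clip_events.append(
                ClipEvent(name, "chr", 100, ClipSide.SUFFIX, 10, "A" * 10,
                          (50, 100), None)
            )
        assert count_clipped_reads(s) == 3

    def test_coverage_change_site_zero(self):
        assert count_clipped_reads(site(100, Direction.DONOR)) == 0

    def test_fixture_count_matches_brute_scan(self, clean_analysis):
        # oracle: count clips within s bp of the site directly from events
        checked = 0
        for s in clean_analysis.sites[:40]:
            if s.origin is not Origin.CLIP:
                continue
            want_side = (
                ClipSide.SUFFIX if s.direction is Direction.DONOR else ClipSide.PREFIX
            )
            brute = {
                (e.read_name, e.is_read1)
                for e in clean_analysis.events
                if e.contig == s.contig
                and abs(e.clip_pos - s.pos) <= 10
                and e.side is want_side
            }
            assert count_clipped_reads(s) == len(brute)
            checked += 1
        assert checked > 10

    def test_realigned_segment_count(self, clean_analysis):
        an = clean_analysis
        total = sum(
            count_realigned_segments(s, an.results) for s in an.sites
        )
        placed = sum(1 for r in an.results if r.target_site is not None)
        assert total == placed and placed > 0


class TestDiscordantEncompassing:
    def _idx(self, spans, contig="chr"):
        # spans: list of ((s1,e1),(s2,e2), tlen)
        records = []
        for i, ((s1, e1), (s2, e2), tlen) in enumerate(spans):
            records.append(
                make_record(read_name=f"p{i}", contig=contig, pos=s1,
                            cigar=f"{e1 - s1}M", template_len=tlen,
                            is_read1=True)
            )
            records.append(
                make_record(read_name=f"p{i}", contig=contig, pos=s2,
                            cigar=f"{e2 - s2}M", template_len=-tlen,
                            is_read1=False, is_reverse=True)
            )
        return PairIndex.build(records, MODEL)

    def test_opposite_sides_counted(self):
        idx = self._idx([((100, 200), (5000, 5100), 5000)])
        assert count_discordant_encompassing(site(1000, Direction.DONOR), idx) == 1

    def test_concordant_pair_not_counted(self):
        idx = self._idx([((100, 200), (350, 450), 350)])
        assert count_discordant_encompassing(site(300, Direction.DONOR), idx) == 0

    def test_mate_overlapping_site_not_encompassing(self):
        idx = self._idx([((100, 200), (950, 1050), 950)])
        assert count_discordant_encompassing(site(1000, Direction.DONOR), idx) == 0

    def test_fixture_matches_brute_pair_scan(self, clean_analysis):
        an = clean_analysis
        sites = [s for s in an.sites if s.origin is Origin.CLIP][:30]
        for s in sites:
            brute = 0
            for name, flag in an.pair_index.discordant.items():
                if not flag:
                    continue
                mates = an.pair_index.get(name)
                a, b = mates[1], mates[2]
                if a.contig != s.contig or b.contig != s.contig:
                    continue
                (ls, le), (rs, re) = sorted(
                    [(a.pos, a.end), (b.pos, b.end)]
                )
                if le <= s.pos and rs >= s.pos:
                    brute += 1
            assert count_discordant_encompassing(s, an.pair_index) == brute


class TestCoverageDifference:
    def test_step_down_donor(self):
        d = np.zeros(200, dtype=int)
        d[:100] = 10
        track = CoverageTrack({"chr": d})
        assert coverage_difference(site(100, Direction.DONOR), track, l=25) == 10.0

    def test_uniform_zero_difference(self):
        track = CoverageTrack({"chr": np.full(200, 7)})
        assert coverage_difference(site(100, Direction.DONOR), track, l=25) == 0.0

    def test_acceptor_mirror(self):
        d = np.zeros(200, dtype=int)
        d[100:] = 6
        track = CoverageTrack({"chr": d})
        assert coverage_difference(site(100, Direction.ACCEPTOR), track, l=25) == 6.0

    def test_random_array_direct_sum_oracle(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 30, size=500)
        track = CoverageTrack({"chr": d})
        for pos in (30, 250, 490):
            got = coverage_difference(site(pos, Direction.DONOR), track, l=25)
            left = d[max(0, pos - 25) : pos]
            right = d[pos : pos + 25]
            lm = left.sum() / len(left) if len(left) else 0.0
            rm = right.sum() / len(right) if len(right) else 0.0
            assert got == pytest.approx(lm - rm)


class TestNormalize:
    def test_division_by_anchor(self):
        d = np.zeros(200, dtype=int)
        d[:100] = 10
        track = CoverageTrack({"chr": d})
        fv = FeatureVector(20, 10, 5, 10.0)
        out = normalize_features(fv, site(100, Direction.DONOR), track, l=25)
        assert np.allclose(out.normalized, [2.0, 1.0, 0.5, 1.0])

    def test_zero_anchor_all_zero(self):
        track = CoverageTrack({"chr": np.zeros(200, dtype=int)})
        fv = FeatureVector(3, 2, 1, 4.0)
        out = normalize_features(fv, site(100, Direction.DONOR), track, l=25)
        assert np.array_equal(out.normalized, np.zeros(4))

    def test_scale_invariance_between_depths(self, tmp_path):
        # doubling coverage should leave normalized f_clip roughly unchanged
        from splicejump import simulate as sim
        from splicejump.junctions import PipelineConfig, analyze

        norms = {}
        for cov in (10.0, 20.0):
            cfg = sim.SimConfig(seed=21, n_transcripts=4, coverage=cov)
            fx = sim.generate_fixture(cfg, tmp_path / f"fx{int(cov)}")
            an = analyze(fx.bam, fx.ref_fasta, [fx.fastq1, fx.fastq2],
                         PipelineConfig())
            vals = [
                an.features[id(s)].normalized[0]
                for s in an.sites
                if s.origin is Origin.CLIP
            ]
            norms[cov] = np.mean(vals)
        assert norms[10.0] == pytest.approx(norms[20.0], rel=0.25)


class TestRealign:
    def _mate_guided_setup(self):
        """Mate-bounded search with two flush placements; the far one is
        concordant, the near one discordant."""
        rng = np.random.default_rng(99)
        g = rng.choice(list("ACGT"), size=3000)
        A, C, D = 480, 800, 2000
        clip = list("ACGTACGTACGTAA")
        g[A - 14 : A] = clip
        g[C - 14 : C] = clip
        genome = Genome({"chr": "".join(g)})
        seq_1b = "".join(clip) + genome.fetch("chr", D, D + 86)
        rec_1b = make_record(
            read_name="pair1", contig="chr", pos=D, cigar="14S86M",
            seq=seq_1b, is_read1=False, is_reverse=True,
            mate_contig="chr", mate_pos=200, template_len=-(2086 - 200),
            is_mate_mapped=True,
        )
        rec_1a = make_record(
            read_name="pair1", contig="chr", pos=200, cigar="100M",
            is_read1=True, mate_contig="chr", mate_pos=D,
            template_len=2086 - 200,
        )
        pair_index = PairIndex.build([rec_1a, rec_1b], MODEL)
        sites = [
            site(A, Direction.DONOR),
            site(C, Direction.DONOR),
            site(D, Direction.ACCEPTOR),
        ]
        (event,) = extract_clip_events(rec_1b)
        return genome, pair_index, sites, event, (A, C, D)

    def test_mate_guided_choice_rejects_discordant_near_site(self):
        genome, pairs, sites, event, (A, C, D) = self._mate_guided_setup()
        res = realign_clipped_segment(event, SiteIndex(sites), pairs, MODEL, genome)
        # C (intron 1200 -> implied insert 686) conflicts; A (intron 1520
        # -> implied 366) is chosen although it is farther from the clip
        assert res.status is RealignStatus.MATCHED_SITE
        assert res.target_site.pos == A
        assert res.junction() == (A, D)

    def test_mate_bounds_search_interval(self):
        genome, pairs, sites, event, (A, C, D) = self._mate_guided_setup()
        res = realign_clipped_segment(event, SiteIndex(sites), pairs, MODEL, genome)
        assert res.bounds.bp == 200 and res.bounds.b1 == 200 and res.bounds.b2 == D

    def test_unmatchable_segment_unaligned(self):
        genome, pairs, sites, event, _ = self._mate_guided_setup()
        event.clip_seq = "N" * 14  # matches nowhere
        res = realign_clipped_segment(event, SiteIndex(sites), pairs, MODEL, genome)
        assert res.status is RealignStatus.UNALIGNED

    def test_empty_clip_seq_raises(self):
        genome, pairs, sites, event, _ = self._mate_guided_setup()
        event.clip_seq = ""
        with pytest.raises(ValueError, match="hard-clip"):
            realign_clipped_segment(event, SiteIndex(sites), pairs, MODEL, genome)

    def test_new_site_from_local_scan(self):
        genome, pairs, sites, event, (A, C, D) = self._mate_guided_setup()
        # remove the donor sites: the flush placements are now only
        # reachable through the local sliding scan
        only_acceptor = [s for s in sites if s.direction is Direction.ACCEPTOR]
        res = realign_clipped_segment(
            event, SiteIndex(only_acceptor), pairs, MODEL, genome
        )
        assert res.status is RealignStatus.NEW_SITE
        assert res.p_new in (A, C)

    def test_long_intron_short_clip_recovered_nearest_first(self):
        # a 2,447 bp intron bridged by 14- and 21-bp clips, with decoy
        # acceptor candidates in between: nearest-first focal search still
        # lands on the distal truth boundary
        rng = np.random.default_rng(123)
        g = "".join(rng.choice(list("ACGT"), size=6000))
        genome = Genome({"chr": g})
        d, a = 1000, 3447
        sites = [
            site(d, Direction.DONOR),
            site(1500, Direction.ACCEPTOR),
            site(2200, Direction.ACCEPTOR),
            site(3000, Direction.ACCEPTOR),
            site(a, Direction.ACCEPTOR),
        ]
        for clip_len in (14, 21):
            read_seq = g[d - (100 - clip_len) : d] + g[a : a + clip_len]
            rec = make_record(
                read_name="x", contig="chr", pos=d - (100 - clip_len),
                cigar=f"{100 - clip_len}M{clip_len}S", seq=read_seq,
                mate_contig="chr", mate_pos=3500, template_len=3600 - 914,
                is_mate_mapped=True,
            )
            mate = make_record(
                read_name="x", contig="chr", pos=3500, cigar="100M",
                is_read1=False, is_reverse=True, template_len=-(3600 - 914),
            )
            pairs = PairIndex.build([rec, mate], MODEL)
            (event,) = extract_clip_events(rec)
            res = realign_clipped_segment(event, SiteIndex(sites), pairs, MODEL, genome)
            assert res.status is RealignStatus.MATCHED_SITE
            assert res.target_site.pos == a

    def test_fixture_exhaustive_scan_oracle(self, clean_fx, clean_analysis):
        # for events whose segment has a unique flush placement in the
        # bounded region, the realigner must land exactly there
        an = clean_analysis
        genome = Genome(clean_fx.genomes)
        checked = 0
        for res in an.results[:300]:
            ev = res.event
            if not ev.clip_seq or res.bounds is None:
                continue
            seg = np.frombuffer(ev.clip_seq.encode(), dtype=np.uint8)
            garr = genome.array(ev.contig)
            lo, hi = res.bounds.b1, res.bounds.b2
            max_mm = max_mismatches(ev.clip_len)
            hits = []
            if ev.side is ClipSide.SUFFIX:
                for p in range(ev.clip_pos + 1, min(hi, garr.size - seg.size) + 1):
                    if np.count_nonzero(garr[p : p + seg.size] != seg) <= max_mm:
                        hits.append(p)
            else:
                for p in range(max(lo, seg.size), ev.clip_pos):
                    if np.count_nonzero(garr[p - seg.size : p] != seg) <= max_mm:
                        hits.append(p)
            if len(hits) != 1:
                continue
            assert res.target_pos == hits[0], ev
            checked += 1
            if checked >= 25:
                break
        assert checked >= 10

    def test_side_consistency_invariant(self, clean_analysis):
        for res in clean_analysis.results:
            if res.target_site is None:
                continue
            if res.event.side is ClipSide.SUFFIX:
                assert res.target_site.direction is Direction.ACCEPTOR
            else:
                assert res.target_site.direction is Direction.DONOR

    def test_junction_length_within_max_jump(self, clean_analysis):
        for res in clean_analysis.results:
            j = res.junction()
            if j is None:
                continue
            assert 0 < j[1] - j[0] <= 1_500_000

    def test_f_seg_bounded_by_reachable_events(self, clean_analysis):
        an = clean_analysis
        for s in an.sites[:50]:
            n = count_realigned_segments(s, an.results)
            reachable = sum(
                1
                for r in an.results
                if r.bounds is not None
                and r.event.contig == s.contig
                and r.bounds.b1 <= s.pos <= r.bounds.b2
            )
            assert n <= reachable

    def test_reciprocal_support_on_clean_fixture(self, clean_fx, clean_analysis):
        # every truth junction with spanning clip evidence on both sides
        # gets f_clip and f_seg support at both boundaries
        an = clean_analysis
        by_pos = {(s.contig, s.pos, s.direction): s for s in an.sites}
        for contig, d, a in clean_fx.truth.junctions:
            donor = by_pos.get((contig, d, Direction.DONOR))
            acceptor = by_pos.get((contig, a, Direction.ACCEPTOR))
            if donor is None or acceptor is None:
                continue
            if count_clipped_reads(donor) and count_clipped_reads(acceptor):
                assert count_realigned_segments(acceptor, an.results) > 0
                assert count_realigned_segments(donor, an.results) > 0


class TestIntegrateNewSites:
    def test_new_site_added_and_retargeted(self):
        genome = Genome({"chr": "A" * 100})
        ev = ClipEvent("r", "chr", 10, ClipSide.SUFFIX, 10, "A" * 10, (0, 10), None)
        from splicejump.features import RealignmentResult

        res = RealignmentResult(ev, RealignStatus.NEW_SITE, p_new=50)
        sites = integrate_new_sites([], [res], s=10)
        assert len(sites) == 1
        assert sites[0].origin is Origin.REALIGN and sites[0].pos == 50
        assert res.target_site is sites[0]

    def test_new_site_near_existing_merges(self):
        existing = site(48, Direction.ACCEPTOR)
        ev = ClipEvent("r", "chr", 10, ClipSide.SUFFIX, 10, "A" * 10, (0, 10), None)
        from splicejump.features import RealignmentResult

        res = RealignmentResult(ev, RealignStatus.NEW_SITE, p_new=50)
        sites = integrate_new_sites([existing], [res], s=10)
        assert len(sites) == 1
        assert res.target_site is existing


def test_max_mismatches_rule():
    assert max_mismatches(14) == 1
    assert max_mismatches(25) == 1
    assert max_mismatches(26) == 2
    assert max_mismatches(1) == 1
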