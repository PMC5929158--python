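"""Docking-site calling, set characterizations, motif scanning,
conservation meta-profiles."""

import numpy as np
import pandas as pd
import pytest

from dockscan.docking import (
    best_motif_per_peak, classify_active_tss, conservation_metaprofile,
    constitutive_ctcf, docking_gene_sets, docking_overlap_venn,
    find_docking_tss, scan_motifs, MotifHit,
)
from dockscan.enhancers import Enhancer
from dockscan.interactions import ChromatinInteraction
from dockscan.intervals import GenomicInterval, Tss, overlaps, window_around
from dockscan.io import ValueTrack
from conftest import iv, peak

SIZES = {"chr1": 1_000_000}


def interaction(a, b, score=0.95, count=12):
    first, second = sorted([a, b], key=lambda p: (p.chrom, p.start))
    return ChromatinInteraction(anchorA=first, anchorB=second, pet_count=count,
                                expected=1.0, score=score,
                                span=abs(second.interval.midpoint - first.interval.midpoint))


class TestActiveTss:
    CAT = [Tss("g1", "chr1", 100, "+", {"c": 5.0}),
           Tss("g2", "chr1", 500, "-", {"c": 0.0})]

    def test_threshold_splits_catalog(self):
        assert [t.gene for t in classify_active_tss(self.CAT, "c", 1.0)] == ["g1"]

    def test_zero_threshold_keeps_everything(self):
        assert len(classify_active_tss(self.CAT, "c", 0.0)) == 2

    def test_missing_cell_type_errors(self):
        with pytest.raises(KeyError):
            classify_active_tss(self.CAT, "missing", 1.0)


class TestDockingCaller:
    def planted(self):
        tss = Tss("geneA", "chr1", 100_000, "+", {"c": 9.0})
        dock = peak("chr1", 97_800, 98_200, name="dock")        # ~2 kb upstream
        enh_ctcf = peak("chr1", 150_000, 150_400, name="se_ctcf")
        enhancer = Enhancer(iv("chr1", 148_000, 152_000), signal=40.0)
        loop = interaction(dock, enh_ctcf)
        return tss, dock, enhancer, loop

    def test_planted_instance_yields_one_call(self):
        tss, dock, enhancer, loop = self.planted()
        calls = find_docking_tss([tss], [dock], [loop], [enhancer], SIZES,
                                 cell_type="c")
        assert len(calls) == 1
        assert calls[0].ctcf_peak == dock and calls[0].supporting == (loop,)

    def test_peak_outside_radius_not_called(self):
        tss, dock, enhancer, loop = self.planted()
        far = peak("chr1", 90_000, 90_400)
        loop_far = interaction(far, peak("chr1", 150_000, 150_400))
        calls = find_docking_tss([tss], [far], [loop_far], [enhancer], SIZES)
        assert calls == []

    def test_no_interactions_empty(self):
        tss, dock, enhancer, _ = self.planted()
        assert find_docking_tss([tss], [dock], [], [enhancer], SIZES) == []

    def test_loop_partner_must_touch_an_enhancer(self):
        tss, dock, _, loop = self.planted()
        elsewhere = Enhancer(iv("chr1", 300_000, 301_000), signal=5.0)
        assert find_docking_tss([tss], [dock], [loop], [elsewhere], SIZES) == []

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(5):
            n_tss = 200
            tss_list = [Tss(f"g{k}", "chr1", int(rng.integers(5_000, 995_000)), "+",
                            {"c": float(rng.choice([0.0, 5.0]))})
                        for k in range(n_tss)]
            peaks = [peak("chr1", int(s), int(s) + 400)
                     for s in rng.integers(0, 995_000, 120)]
            enhancers = [Enhancer(iv("chr1", int(s), int(s) + 2_000),
                                  signal=float(rng.uniform(1, 50)))
                         for s in rng.integers(0, 995_000, 40)]
            loops = [interaction(peaks[int(i)], peaks[int(j)])
                     for i, j in rng.integers(0, len(peaks), size=(30, 2))
                     if not overlaps(peaks[int(i)].interval, peaks[int(j)].interval)]
            active = classify_active_tss(tss_list, "c", 1.0)
            got = {(c.tss.gene, c.ctcf_peak.start)
                   for c in find_docking_tss(active, peaks, loops, enhancers,
                                             SIZES, cell_type="c")}
            expected = set()
            for t in active:
                win = window_around(t.pos, 2_500, t.chrom, SIZES["chr1"])
                for p in peaks:
                    if not overlaps(win, p.interval):
                        continue
                    for x in loops:
                        for mine, partner in ((x.anchorA, x.anchorB),
                                              (x.anchorB, x.anchorA)):
                            if overlaps(mine.interval, p.interval) and any(
                                    overlaps(partner.interval, e.interval)
                                    for e in enhancers):
                                expected.add((t.gene, p.start))
            assert got == expected


class TestConstitutive:
    A = [peak("chr1", 0, 100), peak("chr1", 1_000, 1_100)]

    def test_overlap_in_all_sets_is_constitutive(self):
        others = [[peak("chr1", 50, 150)], [peak("chr1", 90, 95)]]
        out = constitutive_ctcf([self.A] + others)
        assert out == [self.A[0]]

    def test_two_of_three_is_not_constitutive(self):
        out = constitutive_ctcf([self.A, [peak("chr1", 50, 150)],
                                 [peak("chr1", 500, 600)]])
        assert out == []

    def test_single_set_vacuously_constitutive(self):
        assert constitutive_ctcf([self.A]) == self.A

    def test_output_shrinks_as_cell_types_added(self, rng):
        sets = [[peak("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 50_000, 40)] for _ in range(4)]
        prev = None
        for k in range(1, 5):
            out = constitutive_ctcf(sets[:k])
            if prev is not None:
                assert set((p.start, p.end) for p in out) <= prev
            prev = set((p.start, p.end) for p in out)


class TestVenn:
    def test_worked_example(self):
        counts = docking_overlap_venn({"s1": {"a", "b", "c"}, "s2": {"b", "c"},
                                       "s3": {"c"}})
        assert counts[("s1",)] == 1
        assert counts[("s1", "s2")] == 1
        assert counts[("s1", "s2", "s3")] == 1
        assert sum(counts.values()) == 3

    def test_disjoint_sets_have_empty_intersection(self):
        counts = docking_overlap_venn({"a": {"x"}, "b": {"y"}, "c": {"z"}})
        assert counts[("a", "b", "c")] == 0
        assert counts[("a",)] == counts[("b",)] == counts[("c",)] == 1

    def test_identical_sets_concentrate_in_triple_region(self):
        s = {"x", "y"}
        counts = docking_overlap_venn({"a": set(s), "b": set(s), "c": set(s)})
        assert counts[("a", "b", "c")] == 2 and sum(counts.values()) == 2

    def test_counts_sum_to_union(self, rng):
        for _ in range(20):
            sets = {f"s{k}": set(rng.choice(50, size=rng.integers(0, 30),
                                            replace=False).tolist())
                    for k in range(3)}
            counts = docking_overlap_venn(sets)
            assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ValueError):
            docking_overlap_venn({str(k): set() for k in range(4)})


def _brute_force_scan(seq, pwm, background=None):
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    pwm = np.asarray(pwm, float)
    colsum = pwm.sum(axis=0)
    pseudo = 0.01 * colsum
    probs = (pwm + pseudo) / (colsum + 4 * pseudo)
    lom = np.log2(probs / bg[:, None])
    width = lom.shape[1]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = []
    for i in range(len(seq) - width + 1):
        window = seq[i:i + width].upper()
        if any(b not in idx for b in window):
            continue
        fwd = sum(lom[idx[b], k] for k, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(lom[idx[b], k] for k, b in enumerate(rc))
        out.append((i, fwd, rev))
    return out, lom.min(axis=0).sum(), lom.max(axis=0).sum()


class TestScanMotifs:
    def test_consensus_scores_relative_one(self):
        pwm = np.array([[9, 0, 0], [0, 9, 0], [0, 0, 9], [0, 0, 0]], float)
        hits = scan_motifs("TTACGTT", pwm)
        best = max(hits, key=lambda h: h.relative_score)
        assert best.interval.start == 2 and best.strand == "+"
        assert np.isclose(best.relative_score, 1.0)

    def test_uniform_pwm_scores_every_offset_equally(self):
        pwm = np.ones((4, 3))
        scores = {h.log_odds for h in scan_motifs("ACGTACGT", pwm)}
        assert len(scores) == 1

    def test_matches_brute_force_on_random_pwm(self, rng):
        pwm = rng.integers(0, 20, size=(4, 2)).astype(float) + 0.5
        seq = "ACGT"
        hits = scan_motifs(seq, pwm)
        oracle, lo_min, lo_max = _brute_force_scan(seq, pwm)
        by_key = {(h.interval.start, h.strand): h for h in hits}
        for i, fwd, rev in oracle:
            assert np.isclose(by_key[(i, "+")].log_odds, fwd)
            assert np.isclose(by_key[(i, "-")].log_odds, rev)
            assert np.isclose(by_key[(i, "+")].relative_score,
                              (fwd - lo_min) / (lo_max - lo_min))

    def test_strand_symmetry_under_reverse_complement(self, rng):
        from Bio.Seq import Seq
        pwm = rng.integers(1, 30, size=(4, 5)).astype(float)
        seq = "".join(rng.choice(list("ACGT"), 40))
        fwd_hits = scan_motifs(seq, pwm)
        rc_hits = scan_motifs(str(Seq(seq).reverse_complement()), pwm)
        n = len(seq) - 5
        flipped = {(n - h.interval.start, {"+": "-", "-": "+"}[h.strand]):
                   round(h.log_odds, 9) for h in rc_hits}
        for h in fwd_hits:
            assert flipped[(h.interval.start, h.strand)] == round(h.log_odds, 9)

    def test_non_acgt_windows_skipped_with_warning(self):
        pwm = np.ones((4, 2))
        with pytest.warns(UserWarning):
            hits = scan_motifs("ACNGT", pwm)
        starts = {h.interval.start for h in hits}
        assert starts == {0, 3}  # windows touching the N are gone


class TestBestMotifPerPeak:
    def hit(self, start, score, strand="+", width=4):
        return MotifHit(iv("chr1", start, start + width), strand, score, score)

    def test_highest_score_wins(self):
        peaks = [peak("chr1", 0, 100)]
        best = best_motif_per_peak(peaks, [self.hit(10, 0.7), self.hit(50, 0.9)])
        assert best[0].interval.start == 50

    def test_tie_breaks_leftmost_then_plus(self):
        peaks = [peak("chr1", 0, 100)]
        best = best_motif_per_peak(peaks, [self.hit(50, 0.9), self.hit(10, 0.9)])
        assert best[0].interval.start == 10
        best = best_motif_per_peak(peaks, [self.hit(10, 0.9, "-"),
                                           self.hit(10, 0.9, "+")])
        assert best[0].strand == "+"

    def test_hit_must_be_fully_inside_peak(self):
        best = best_motif_per_peak([peak("chr1", 0, 12)], [self.hit(10, 0.9)])
        assert best == {}

    def test_matches_brute_force(self, rng):
        peaks = [peak("chr1", int(s), int(s) + int(rng.integers(20, 200)))
                 for s in rng.integers(0, 5_000, 30)]
        hits = [self.hit(int(s), float(np.round(rng.uniform(), 3)),
                         str(rng.choice(["+", "-"])))
                for s in rng.integers(0, 5_000, 150)]
        got = best_motif_per_peak(peaks, hits)
        for k, p in enumerate(peaks):
            inside = [h for h in hits if h.interval.start >= p.start
                      and h.interval.end <= p.end]
            if not inside:
                assert k not in got
                continue
            top = sorted(inside, key=lambda h: (-h.relative_score, h.interval.start,
                                                h.strand != "+"))[0]
            assert got[k] == top


class TestConservationProfile:
    def track(self, rows):
        return ValueTrack.from_dataframe(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))

    def test_constant_track_gives_flat_profile(self):
        track = self.track([("c", 0, 10_000, 0.7)])
        hits = [MotifHit(iv("c", 1_000, 1_019), "+", 1.0, 1.0),
                MotifHit(iv("c", 2_000, 2_019), "-", 1.0, 1.0)]
        profile = conservation_metaprofile(hits, track, flank=50)
        assert profile.shape == (119,)
        assert np.allclose(profile, 0.7)

    def test_plus_strand_profile_is_the_track_slice(self):
        track = self.track([("c", 0, 1_000, 0.1), ("c", 1_000, 1_010, 0.9),
                            ("c", 1_010, 2_000, 0.1)])
        (hit,) = [MotifHit(iv("c", 1_000, 1_010), "+", 1.0, 1.0)]
        profile = conservation_metaprofile([hit], track, flank=5)
        assert np.allclose(profile, [0.1] * 5 + [0.9] * 10 + [0.1] * 5)

    def test_minus_strand_window_is_reversed(self):
        track = self.track([("c", 990, 1_000, 0.5), ("c", 1_000, 1_010, 0.9)])
        hit = MotifHit(iv("c", 1_000, 1_010), "-", 1.0, 1.0)
        profile = conservation_metaprofile([hit], track, flank=5)
        # reversed: uncovered right flank first, then motif, then 0.5 flank
        assert np.allclose(profile, [0.0] * 5 + [0.9] * 10 + [0.5] * 5)

    def test_no_hits_errors(self):
        with pytest.raises(ValueError):
            conservation_metaprofile([], self.track([("c", 0, 10, 1.0)]))


def test_docking_gene_sets_counts_gene_once():
    tss = Tss("g", "chr1", 10_000, "+", {"c": 5.0})
    calls = find_docking_tss(
        [tss],
        [peak("chr1", 8_000, 8_400), peak("chr1", 11_000, 11_400)],
        [interaction(peak("chr1", 8_000, 8_400), peak("chr1", 50_000, 50_400)),
         interaction(peak("chr1", 11_000, 11_400), peak("chr1", 50_000, 50_400))],
        [Enhancer(iv("chr1", 49_000, 51_000), signal=10.0)],
        SIZES, cell_type="c")
    assert len(calls) == 2  # one per (tss, peak)
    assert docking_gene_sets(calls) == {"c": {"g"}}
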