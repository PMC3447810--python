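"""TAR segmentation, max-slope TSS inference, annotation, grouping."""

import numpy as np
import pytest

from promotile.genome import Gene
from promotile.tiling import BackgroundModel, ProbeTrack
from promotile.tars import (
    TSS,
    annotate_tss,
    group_tss,
    infer_tss,
    segment_tars,
)

BG = BackgroundModel(mode=7.0, sd=0.5)
THR = 9.0


def track_from_spans(high_spans, n=400, step=14, strand="+", high=10.0, low=7.0):
    """Track with `high` signal for probes whose start falls in high_spans."""
    starts = np.arange(n) * step
    sig = np.full(n, low)
    for a, b in high_spans:
        sig[(starts >= a) & (starts < b)] = high
    return ProbeTrack(strand, starts, sig)


class TestSegmentation:
    def test_single_run_one_tar(self):
        t = track_from_spans([(1000, 1200)])
        tars = segment_tars(t, THR)
        assert len(tars) == 1
        # span: first probe start .. last probe start + probe length
        assert tars[0].start == 1008 and tars[0].end == 1190 + 60

    def test_gap_of_50_joined(self):
        # runs end at probe start 994 (covered to 1054) and resume at 1106
        t = track_from_spans([(700, 1000), (1104, 1400)])
        tars = segment_tars(t, THR, max_gap=60)
        assert len(tars) == 1

    def test_gap_of_61_split(self):
        t = track_from_spans([(700, 1000), (1120, 1400)])
        # gap = 1120 - (994 + 60) = 66 > 60
        tars = segment_tars(t, THR, max_gap=60)
        assert len(tars) == 2

    def test_short_run_discarded_long_kept(self):
        # single probe: span 60 nt < 120 -> discarded
        t1 = track_from_spans([(1000, 1010)])
        assert segment_tars(t1, THR) == []
        # five probes: span = 4*14 + 60 = 116 < 120 discarded;
        # six probes: span = 5*14 + 60 = 130 kept
        t2 = track_from_spans([(0, 14 * 5)])
        assert segment_tars(t2, THR) == []
        t3 = track_from_spans([(0, 14 * 6)])
        tars = segment_tars(t3, THR)
        assert len(tars) == 1 and tars[0].end - tars[0].start == 130

    def test_exact_boundary_lengths(self):
        # engineered spans of exactly 100 and 120 nt with a 20-nt probe
        starts = np.array([0, 40, 80, 200, 300, 340, 380, 400])
        sig = np.array([10.0, 10, 10, 7, 10, 10, 10, 10])
        t = ProbeTrack("+", starts, sig, probe_length=20)
        # gap 300-(80+20)=200 > 60 keeps the runs apart;
        # run1 span [0,100) -> 100 nt discarded; run2 span [300,420) -> 120 kept
        tars = segment_tars(t, THR, max_gap=60, min_len=120)
        assert [(x.start, x.end) for x in tars] == [(300, 420)]

    def test_idempotent_and_chunk_invariant(self):
        rng = np.random.default_rng(8)
        sig = rng.normal(7, 0.5, 2000)
        sig[300:340] += 4
        sig[900:980] += 4
        t = ProbeTrack("+", np.arange(2000) * 14, sig)
        tars = segment_tars(t, THR)
        spans = [(x.start, x.end) for x in tars]
        # chunking the track at a far-away point and re-segmenting each
        # half reproduces the same spans
        cut = 1000
        left = ProbeTrack("+", t.probe_starts[:cut], sig[:cut])
        right = ProbeTrack("+", t.probe_starts[cut:], sig[cut:])
        spans2 = [(x.start, x.end) for x in segment_tars(left, THR)]
        spans2 += [(x.start, x.end) for x in segment_tars(right, THR)]
        assert spans == spans2

    def test_empty_track_below_threshold(self):
        t = track_from_spans([])
        assert segment_tars(t, THR) == []


def ramp_track(p0=2000, slope=0.1, n=400, step=14, strand="+", mode=7.0, top=12.0):
    """Background at `mode`, then a linear rise of `slope`/nt starting at p0.

    Signal is attributed to a probe's transcription-downstream terminus.
    """
    starts = np.arange(n) * step
    anchors = starts + 60 if strand == "+" else starts
    if strand == "+":
        ramp = np.clip((anchors - p0) * slope, 0, top - mode)
    else:
        ramp = np.clip((p0 - anchors) * slope, 0, top - mode)
    return ProbeTrack(strand, starts, mode + ramp)


class TestInferTss:
    def test_linear_ramp_exact_intercept_plus(self):
        t = ramp_track(p0=2000, slope=0.1)
        tars = segment_tars(t, THR)
        assert len(tars) == 1
        tss = infer_tss(tars[0], t, BG)
        assert abs(tss.position - 2000) <= 1  # exact up to grid rounding
        assert not tss.low_confidence

    def test_linear_ramp_exact_intercept_minus(self):
        t = ramp_track(p0=3000, slope=0.1, strand="-")
        tars = segment_tars(t, THR)
        assert len(tars) == 1
        tss = infer_tss(tars[0], t, BG)
        assert abs(tss.position - 3000) <= 1

    def test_step_jump_lands_inside_probe_interval(self):
        t = track_from_spans([(2002, 3000)], high=11.0)
        tars = segment_tars(t, THR)
        tss = infer_tss(tars[0], t, BG)
        # the jump happens between adjacent probes anchored 14 nt apart
        lo = tars[0].start + 60 - 14
        assert lo <= tss.position <= lo + 14

    def test_flat_tar_flagged_at_boundary(self):
        # a flat TAR whose upstream window only ever slopes downward: a
        # short high block, a probe-grid hole wider than max_gap, then the
        # flat TAR itself slightly lower
        starts = np.concatenate([np.arange(3) * 14, 200 + np.arange(20) * 14])
        sig = np.concatenate([np.full(3, 9.6), np.full(20, 9.5)])
        t = ProbeTrack("+", starts, sig)
        tars = segment_tars(t, THR)  # the 3-probe block is < 120 nt, dropped
        assert len(tars) == 1 and tars[0].start == 200
        tss = infer_tss(tars[0], t, BG, upstream_margin=300)
        assert tss.low_confidence
        assert tss.position == tars[0].five_prime

    def test_extrapolation_clamped_to_margin(self):
        # tiny slope with huge signal: naive intercept would fly far upstream
        starts = np.arange(400) * 14
        sig = np.full(400, 7.0)
        sig[200:260] = 12.0
        sig[199] = 11.99  # minuscule positive slope at the 5' edge
        t = ProbeTrack("+", starts, sig)
        tars = segment_tars(t, THR)
        tss = infer_tss(tars[0], t, BG, upstream_margin=300)
        assert tss.position >= tars[0].start - 300


GENES = [Gene("gp", 5000, 7000, "+"), Gene("gm", 9000, 11000, "-")]


def make_tss(pos, strand, tar_span):
    from promotile.tars import TAR

    tar = TAR(strand, tar_span[0], tar_span[1], 10.0, 0, 0)
    return TSS(position=pos, strand=strand, tar=tar)


class TestAnnotate:
    def test_sense_assigned_downstream_gene(self):
        t = make_tss(4900, "+", (4900, 6000))
        annotate_tss([t], GENES)
        assert t.category == "sense" and t.assigned_gene == "gp"

    def test_antisense_opposite_strand_gene(self):
        t = make_tss(6500, "-", (5500, 6500))
        annotate_tss([t], GENES)
        assert t.category == "antisense"

    def test_noncoding_in_gene_free_region(self):
        t = make_tss(2000, "+", (2000, 2400))
        annotate_tss([t], GENES)
        assert t.category == "noncoding" and t.assigned_gene is None

    def test_minus_strand_sense_assignment(self):
        t = make_tss(11200, "-", (9500, 11200))
        annotate_tss([t], GENES)
        assert t.category == "sense" and t.assigned_gene == "gm"


class TestGroup:
    def _track(self):
        # step track: 7 below position 5000, 10 above
        starts = np.arange(0, 20000, 14)
        sig = np.where(starts < 5000, 7.0, 10.0)
        return {"+": ProbeTrack("+", starts, sig)}

    def test_quintiles_of_distinct_diffs(self):
        rng = np.random.default_rng(9)
        starts = np.arange(0, 20000, 14)
        tracks = {"+": ProbeTrack("+", starts, rng.normal(7, 0.1, len(starts)))}
        tss = [make_tss(1000 + 1500 * i, "+", (1000, 1100)) for i in range(10)]
        # hand-set distinct mean_diffs via monkeypatched signal? instead,
        # check ranking against computed mean_diff directly
        group_tss(tss, tracks)
        order = sorted(tss, key=lambda t: (t.mean_diff, t.position))
        labels = [t.group for t in order]
        assert labels == ["E", "E", "D", "D", "C", "C", "B", "B", "A", "A"]

    def test_tie_rule_sizes(self):
        tracks = {"+": ProbeTrack("+", np.arange(0, 20000, 14),
                                  np.full(1429, 7.0))}
        tss = [make_tss(500 + 977 * i, "+", (500, 600)) for i in range(11)]
        group_tss(tss, tracks)  # all mean_diff equal -> ties by position
        from collections import Counter

        sizes = Counter(t.group for t in tss)
        assert set(sizes.values()) <= {2, 3}
        # ties broken by position: earliest positions get E
        assert [t.group for t in sorted(tss, key=lambda t: t.position)][:3] == ["E", "E", "E"]

    def test_step_mean_diff_about_three(self):
        tss = [make_tss(5000, "+", (5000, 6000))]
        filler = [make_tss(200 + i, "+", (200, 300)) for i in range(4)]
        group_tss(tss + filler, self._track())
        assert tss[0].mean_diff == pytest.approx(3.0, abs=0.1)

    def test_too_few_tss_rejected(self):
        with pytest.raises(ValueError):
            group_tss([make_tss(100, "+", (100, 200))], self._track())


def test_group_filter_drops_only_requested_groups():
    from promotile.tars import filter_tss_by_group

    tss = [make_tss(100 * i, "+", (0, 200)) for i in range(6)]
    for t, g in zip(tss, "AABCDE"):
        t.group = g
    kept = filter_tss_by_group(tss, drop_groups=("E",))
    assert [t.group for t in kept] == list("AABCD")
    assert filter_tss_by_group(tss) == tss
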