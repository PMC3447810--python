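"""Transcriptionally active regions and transcription start sites.

A track is segmented into TARs: maximal runs of above-threshold probes,
with runs separated by at most ``max_gap`` nt of uncovered genome joined,
and spans shorter than ``min_len`` discarded.  Each TAR's TSS is inferred
by finding the adjacent-probe pair with the steepest signal rise at the
TAR's 5' end and linearly extrapolating that slope down to the background
mode.  Probe signal is anchored at the probe's transcription-downstream
terminus: a probe starts reporting a transcript as soon as that end enters
it, so on a perfect linear onset the extrapolation recovers the 5' end
exactly.  TSSs are then annotated against the gene annotation
(sense / antisense / noncoding) and ranked into five expression groups
(A strongest .. E weakest) by the difference of mean signal downstream
minus upstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Gene
from .tiling import BackgroundModel, ProbeTrack

__all__ = [
    "TAR",
    "TSS",
    "segment_tars",
    "infer_tss",
    "annotate_tss",
    "group_tss",
    "filter_tss_by_group",
    "tss_to_dataframe",
    "write_tars_gff3",
    "write_tss_tsv",
]

GROUP_LABELS = ("E", "D", "C", "B", "A")  # ascending mean_diff


@dataclass(frozen=True)
class TAR:
    strand: str
    start: int
    end: int
    mean_signal: float
    first_probe: int
    last_probe: int  # inclusive index into the track

    @property
    def five_prime(self) -> int:
        """5'-most genomic coordinate in the direction of transcription."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TSS:
    position: int
    strand: str
    tar: TAR
    low_confidence: bool = False
    category: str | None = None
    assigned_gene: str | None = None
    mean_diff: float | None = None
    group: str | None = None


def segment_tars(
    track: ProbeTrack,
    threshold: float,
    max_gap: int = 60,
    min_len: int = 120,
) -> list[TAR]:
    """Segment a track into transcriptionally active regions.

    The gap between two probe runs is the uncovered genomic distance
    between the end of the last probe of one run and the start of the
    first probe of the next.
    """
    above = track.signal > threshold
    if not above.any():
        return []
    idx = np.nonzero(above)[0]
    starts = track.probe_starts
    plen = track.probe_length
    # two consecutive above-threshold probes share a TAR iff the uncovered
    # genomic distance between them is <= max_gap; this joins runs across
    # short sub-threshold dips and splits at probe-grid holes alike
    gaps = starts[idx[1:]] - (starts[idx[:-1]] + plen)
    breaks = np.nonzero(gaps > max_gap)[0]
    merged = list(
        zip(np.r_[idx[0], idx[breaks + 1]].tolist(), np.r_[idx[breaks], idx[-1]].tolist())
    )
    tars: list[TAR] = []
    for i0, i1 in merged:
        span_start = int(starts[i0])
        span_end = int(starts[i1]) + plen
        if span_end - span_start < min_len:
            continue
        mean_sig = float(track.signal[i0 : i1 + 1].mean())
        tars.append(
            TAR(track.strand, span_start, span_end, mean_sig, i0, i1)
        )
    return tars


def _anchors(track: ProbeTrack) -> np.ndarray:
    """Transcription-downstream probe terminus: right end on +, start on -."""
    if track.strand == "+":
        return track.probe_starts + track.probe_length
    return track.probe_starts.copy()


def infer_tss(
    tar: TAR,
    track: ProbeTrack,
    bg: BackgroundModel,
    upstream_margin: int = 300,
    max_tar_probes: int = 10,
) -> TSS:
    """Infer the TSS of a TAR by maximum-slope linear extrapolation.

    Adjacent-probe slopes (signal change per nt in the direction of
    transcription) are computed from ``upstream_margin`` nt upstream of
    the TAR's 5' boundary through its first ``max_tar_probes`` probes; at
    the steepest pair's downstream probe, the line through that probe's
    signal with the maximum slope is extrapolated back to the background
    mode.  If no positive slope exists the TAR's 5' boundary is returned,
    flagged low-confidence.
    """
    starts = track.probe_starts
    anchors = _anchors(track)
    sig = track.signal
    if track.strand == "+":
        lo_pos = tar.start - upstream_margin
        first = int(np.searchsorted(starts, lo_pos, side="left"))
        last = min(tar.first_probe + max_tar_probes - 1, tar.last_probe)
        pos = anchors[first : last + 1].astype(float)
        y = sig[first : last + 1]
        boundary = tar.start
        limit = tar.start - upstream_margin
        sign = +1
    else:
        hi_pos = tar.end + upstream_margin
        last = int(np.searchsorted(starts, hi_pos, side="right")) - 1
        first = max(tar.last_probe - max_tar_probes + 1, tar.first_probe)
        # walk in the direction of transcription: decreasing coordinate
        pos = anchors[first : last + 1].astype(float)[::-1]
        y = sig[first : last + 1][::-1]
        boundary = tar.end - 1
        limit = tar.end - 1 + upstream_margin
        sign = -1
    if len(pos) < 2:
        return TSS(position=boundary, strand=tar.strand, tar=tar, low_confidence=True)
    # slope per nt moved downstream (transcription direction)
    dy = np.diff(y)
    dx = sign * np.diff(pos)  # positive nt steps downstream
    slopes = dy / dx
    k = int(np.argmax(slopes))
    if slopes[k] <= 0:
        return TSS(position=boundary, strand=tar.strand, tar=tar, low_confidence=True)
    down_pos = pos[k + 1]
    down_sig = y[k + 1]
    # extrapolate back (upstream) to the background mode
    tss = down_pos - sign * (down_sig - bg.mode) / slopes[k]
    if sign > 0:
        tss = max(tss, limit)
    else:
        tss = min(tss, limit)
    return TSS(position=int(round(tss)), strand=tar.strand, tar=tar)


def annotate_tss(tss_list: list[TSS], genes: list[Gene]) -> list[TSS]:
    """Label TSSs sense / antisense / noncoding from TAR-gene overlap.

    noncoding: the TAR overlaps no gene; antisense: it overlaps genes only
    on the opposite strand; otherwise sense, assigned to the closest
    downstream gene on the same strand.
    """
    for t in tss_list:
        tar = t.tar
        same = opp = False
        for g in genes:
            if g.start < tar.end and g.end > tar.start:
                if g.strand == t.strand:
                    same = True
                else:
                    opp = True
        if not same and not opp:
            t.category = "noncoding"
        elif not same:
            t.category = "antisense"
        else:
            t.category = "sense"
            if t.strand == "+":
                cands = [g for g in genes if g.strand == "+" and g.start >= t.position]
                if cands:
                    t.assigned_gene = min(cands, key=lambda g: g.start).id
            else:
                cands = [g for g in genes if g.strand == "-" and g.end <= t.position + 1]
                if cands:
                    t.assigned_gene = max(cands, key=lambda g: g.end).id
    return tss_list


def group_tss(
    tss_list: list[TSS],
    tracks: dict[str, ProbeTrack],
    flank_window: int = 140,
) -> list[TSS]:
    """Assign expression groups A..E by ranked up/downstream signal change.

    mean_diff = mean signal over ``flank_window`` nt downstream of the TSS
    minus the mean over the same window upstream (strand-oriented); TSSs
    ranked ascending by mean_diff are split into quintiles E (lowest) to A
    (highest), ties broken by genomic position.
    """
    if len(tss_list) < 5:
        raise ValueError("need at least 5 TSSs to form quintiles")
    for t in tss_list:
        track = tracks[t.strand]
        starts = track.probe_starts
        if t.strand == "+":
            down = (starts >= t.position) & (starts < t.position + flank_window)
            up = (starts >= t.position - flank_window) & (starts < t.position)
        else:
            down = (starts > t.position - flank_window) & (starts <= t.position)
            up = (starts > t.position) & (starts <= t.position + flank_window)
        dmean = float(track.signal[down].mean()) if down.any() else 0.0
        umean = float(track.signal[up].mean()) if up.any() else 0.0
        t.mean_diff = dmean - umean
    order = sorted(range(len(tss_list)), key=lambda i: (tss_list[i].mean_diff, tss_list[i].position))
    n = len(tss_list)
    for rank, i in enumerate(order):
        tss_list[i].group = GROUP_LABELS[rank * 5 // n]
    return tss_list


def filter_tss_by_group(tss_list: list[TSS], drop_groups=()) -> list[TSS]:
    """Drop TSSs in the given expression groups (e.g. ('E',)).

    Off by default everywhere: low-expression TSSs are positioned
    ambiguously and some analyses exclude them before validation.
    """
    drop = set(drop_groups)
    return [t for t in tss_list if t.group not in drop]


# ---------------------------------------------------------------- output

def tss_to_dataframe(tss_list: list[TSS]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [t.position for t in tss_list],
            "strand": [t.strand for t in tss_list],
            "tar_start": [t.tar.start for t in tss_list],
            "tar_end": [t.tar.end for t in tss_list],
            "category": [t.category for t in tss_list],
            "assigned_gene": [t.assigned_gene for t in tss_list],
            "mean_diff": [t.mean_diff for t in tss_list],
            "group": [t.group for t in tss_list],
            "low_confidence": [t.low_confidence for t in tss_list],
        }
    )


def write_tss_tsv(tss_list: list[TSS], path) -> None:
    tss_to_dataframe(tss_list).to_csv(path, sep="\t", index=False)


def read_tss_tsv(path) -> list[TSS]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        tar = TAR(str(row.strand), int(row.tar_start), int(row.tar_end), 0.0, -1, -1)
        out.append(
            TSS(
                position=int(row.position),
                strand=str(row.strand),
                tar=tar,
                low_confidence=bool(row.low_confidence),
                category=None if pd.isna(row.category) else str(row.category),
                assigned_gene=None if pd.isna(row.assigned_gene) else str(row.assigned_gene),
                mean_diff=None if pd.isna(row.mean_diff) else float(row.mean_diff),
                group=None if pd.isna(row.group) else str(row.group),
            )
        )
    return out


def write_tars_gff3(tars: list[TAR], path, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, t in enumerate(tars):
            fh.write(
                f"{seqid}\tpromotile\tTAR\t{t.start + 1}\t{t.end}\t{t.mean_signal:.3f}\t"
                f"{t.strand}\t.\tID=tar{i}\n"
            )
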