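"""Tiling-array probe tracks: normalization and background modelling.

Replicate strand-specific probe intensities are quantile-normalized and
averaged into one track per strand.  The transcription threshold derives
from a normal background model fitted to the left-of-the-mode part of the
log2 signal distribution: the mode is located on a fixed-width histogram
with quadratic peak refinement, and the background standard deviation is
the root mean square deviation of the sub-mode signal, which equals the
normal sd when the background is Gaussian.  The global threshold is the
signal level a background probe exceeds with probability ``alpha``
(default 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ProbeTrack",
    "BackgroundModel",
    "quantile_normalize",
    "normalize",
    "estimate_background",
    "global_threshold",
    "read_probe_table",
    "write_probe_table",
    "write_track_tsv",
    "read_track_tsv",
]


@dataclass(frozen=True)
class ProbeTrack:
    """Strand-specific ordered probe positions with log2 intensities."""

    strand: str
    probe_starts: np.ndarray
    signal: np.ndarray
    probe_length: int = 60

    def __post_init__(self):
        starts = np.asarray(self.probe_starts, dtype=np.int64)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "probe_starts", starts)
        object.__setattr__(self, "signal", sig)
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(starts) != len(sig):
            raise ValueError("probe_starts and signal lengths differ")
        if len(starts) > 1 and not np.all(np.diff(starts) > 0):
            raise ValueError("probe_starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.probe_starts)


@dataclass(frozen=True)
class BackgroundModel:
    """Normal background fitted to the left of the signal mode."""

    mode: float
    sd: float
    alpha: float | None = None
    threshold: float | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


def quantile_normalize(tracks: list[ProbeTrack]) -> list[ProbeTrack]:
    """Classic quantile normalization across replicate tracks.

    Each replicate's values are replaced by the mean of the replicates'
    sorted values at the corresponding rank; ties receive the mean of
    their ranks' values.  Per-replicate rank order is preserved.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two replicates")
    n = len(tracks[0])
    for t in tracks[1:]:
        if len(t) != n or not np.array_equal(t.probe_starts, tracks[0].probe_starts):
            raise ValueError("replicates must share identical probe grids")
        if t.strand != tracks[0].strand:
            raise ValueError("replicates must share the same strand")
    sorted_mean = np.mean([np.sort(t.signal) for t in tracks], axis=0)
    out = []
    for t in tracks:
        ranks = rankdata(t.signal, method="average")
        newsig = np.interp(ranks, np.arange(1, n + 1), sorted_mean)
        out.append(replace(t, signal=newsig))
    return out


def normalize(replicates: list[ProbeTrack]) -> ProbeTrack:
    """Quantile-normalize replicates, then average per probe."""
    qn = quantile_normalize(replicates)
    avg = np.mean([t.signal for t in qn], axis=0)
    return replace(qn[0], signal=avg)


def estimate_background(
    track: ProbeTrack,
    bin_width: float = 0.05,
    min_probes: int = 1000,
    min_left: int = 50,
) -> BackgroundModel:
    """Fit the left-of-the-mode normal background of a track.

    The mode is the peak of a fixed-width histogram, refined by fitting a
    parabola through the peak bin and its neighbours; the sd is
    sqrt(mean((x - mode)^2)) over signal below the mode.
    """
    x = track.signal
    if len(x) < min_probes:
        raise ValueError(f"need >= {min_probes} probes, got {len(x)}")
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < bin_width:
        raise ValueError("signal is (nearly) constant; background undefined")
    nbins = int(np.ceil((hi - lo) / bin_width))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, lo + nbins * bin_width))
    m = int(np.argmax(counts))
    center = 0.5 * (edges[m] + edges[m + 1])
    if 0 < m < nbins - 1:
        y0, y1, y2 = counts[m - 1], counts[m], counts[m + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            center += 0.5 * bin_width * (y0 - y2) / denom
    mode = float(center)
    left = x[x < mode]
    if len(left) < min_left:
        raise ValueError("too few probes left of the mode")
    sd = float(np.sqrt(np.mean((left - mode) ** 2)))
    if sd <= 0:
        raise ValueError("left-of-mode sd is zero")
    return BackgroundModel(mode=mode, sd=sd)


def global_threshold(bg: BackgroundModel, alpha: float = 1e-6) -> float:
    """Signal level exceeded by a background probe with probability alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return bg.mode + float(norm.ppf(1.0 - alpha)) * bg.sd


# ---------------------------------------------------------------- I/O

_SCALE_COMMENT = "# intensity_scale: log2"


def write_probe_table(tracks_by_strand: dict[str, list[ProbeTrack]], path) -> None:
    """Write replicate probe intensities (log2) as a tab-separated table.

    Columns: probe_start, strand, intensity_rep1, intensity_rep2, ...
    """
    nrep = len(next(iter(tracks_by_strand.values())))
    with open(path, "w") as fh:
        fh.write(_SCALE_COMMENT + "\n")
        fh.write(
            "probe_start\tstrand\t"
            + "\t".join(f"intensity_rep{i + 1}" for i in range(nrep))
            + "\n"
        )
        for strand in sorted(tracks_by_strand):
            reps = tracks_by_strand[strand]
            for j in range(len(reps[0])):
                vals = "\t".join(f"{t.signal[j]:.5f}" for t in reps)
                fh.write(f"{reps[0].probe_starts[j]}\t{strand}\t{vals}\n")


def read_probe_table(
    path, probe_length: int = 60, log2_input: bool | None = None
) -> dict[str, list[ProbeTrack]]:
    """Read replicate probe intensities.

    Raw (linear) intensities are log2-transformed on read; tables written
    by :func:`write_probe_table` carry a scale comment and are taken as
    log2 already.  Pass ``log2_input`` to override the autodetection.
    """
    with open(path) as fh:
        first = fh.readline()
    is_log2 = first.strip() == _SCALE_COMMENT if log2_input is None else log2_input
    df = pd.read_csv(path, sep="\t", comment="#")
    rep_cols = [c for c in df.columns if c.startswith("intensity")]
    if not rep_cols:
        raise ValueError(f"{path}: no intensity columns found")
    out: dict[str, list[ProbeTrack]] = {}
    for strand, grp in df.groupby("strand"):
        grp = grp.sort_values("probe_start")
        starts = grp["probe_start"].to_numpy(dtype=np.int64)
        tracks = []
        for c in rep_cols:
            sig = grp[c].to_numpy(dtype=float)
            if not is_log2:
                if np.any(sig <= 0):
                    raise ValueError("linear intensities must be positive")
                sig = np.log2(sig)
            tracks.append(
                ProbeTrack(strand=str(strand), probe_starts=starts, signal=sig,
                           probe_length=probe_length)
            )
        out[str(strand)] = tracks
    return out


def write_track_tsv(track: ProbeTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(_SCALE_COMMENT + "\n")
        fh.write("probe_start\tstrand\tintensity\n")
        for s, v in zip(track.probe_starts, track.signal):
            fh.write(f"{s}\t{track.strand}\t{v:.5f}\n")


def read_track_tsv(path, probe_length: int = 60) -> ProbeTrack:
    df = pd.read_csv(path, sep="\t", comment="#")
    strand = str(df["strand"].iloc[0])
    return ProbeTrack(
        strand=strand,
        probe_starts=df["probe_start"].to_numpy(dtype=np.int64),
        signal=df["intensity"].to_numpy(dtype=float),
        probe_length=probe_length,
    )
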