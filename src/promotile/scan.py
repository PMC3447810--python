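"""Genome-wide motif scanning, overlap deduplication and hit classification.

Both strands of the genome are scored at every position against every
matrix; windows containing N are skipped.  Hit significance is the exact
background tail probability of the window score (see :mod:`promotile.pwm`).
Overlapping hits are reduced to the most significant one, hits are
classified by their genomic context relative to the gene annotation, and a
Bonferroni correction over the number of scored windows is available.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import Gene, Genome, merge_intervals
from .pwm import NEG_SENTINEL, PWM, ScoreDistribution, score_pvalue_table

__all__ = [
    "MotifHit",
    "scan_genome",
    "dedup_overlaps",
    "classify_location",
    "bonferroni",
    "default_n_tests",
    "hits_to_dataframe",
    "write_hits_gff3",
    "write_hits_tsv",
]

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_RC = np.array([3, 2, 1, 0, 4], dtype=np.int8)


@dataclass(frozen=True)
class MotifHit:
    """A scored, p-valued, strand-oriented motif occurrence."""

    matrix_name: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    corrected_pvalue: float | None = None
    location_class: str | None = None

    @property
    def three_prime_end(self) -> int:
        """Strand-oriented downstream end of the hit."""
        return self.end - 1 if self.strand == "+" else self.start


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_strand(codes: np.ndarray, lo5: np.ndarray, q5: np.ndarray,
                 dist: ScoreDistribution, p_cutoff: float):
    # score in the discretized (integer-grid) domain shared with the
    # p-value table, so reported significances are exactly calibrated
    w = q5.shape[0]
    n = len(codes) - w + 1
    qscores = np.zeros(n, dtype=np.int64)
    for i in range(w):
        qscores += q5[i][codes[i : i + n]]
    valid = qscores > NEG_SENTINEL // 2  # no N, no zero-probability base
    pvals = np.ones(n)
    pvals[valid] = dist.grid_pvalue(qscores[valid])
    keep = pvals < p_cutoff
    idx = np.nonzero(keep)[0]
    scores = np.zeros(len(idx))
    for i in range(w):
        scores += lo5[i][codes[idx + i]]
    return idx, scores, pvals[keep]


def scan_genome(
    genome: Genome,
    pwms: list[PWM],
    p_cutoff: float = 1e-4,
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Score every window on both strands; return hits with p < ``p_cutoff``."""
    if not pwms:
        raise ValueError("no matrices given")
    widest = max(p.width for p in pwms)
    if genome.length < widest:
        raise ValueError(
            f"genome length {genome.length} shorter than widest matrix ({widest})"
        )
    codes = encode_sequence(genome.sequence)
    rc = _RC[codes[::-1]]
    hits: list[MotifHit] = []
    L = genome.length
    for pwm in pwms:
        dist = score_pvalue_table(pwm, granularity)
        lo = pwm.logodds
        lo5 = np.hstack([lo, np.full((pwm.width, 1), -np.inf)])
        q5 = np.hstack([dist.column_scores,
                        np.full((pwm.width, 1), NEG_SENTINEL, dtype=np.int64)])
        w = pwm.width
        pos, sc, pv = _scan_strand(codes, lo5, q5, dist, p_cutoff)
        for j, s, p in zip(pos, sc, pv):
            hits.append(MotifHit(pwm.name, int(j), int(j) + w, "+", float(s), float(p)))
        pos, sc, pv = _scan_strand(rc, lo5, q5, dist, p_cutoff)
        for j, s, p in zip(pos, sc, pv):
            hits.append(
                MotifHit(pwm.name, L - int(j) - w, L - int(j), "-", float(s), float(p))
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand, h.matrix_name))
    return hits


def dedup_overlaps(hits: list[MotifHit]) -> list[MotifHit]:
    """Keep, among overlapping same-strand hits, the most significant one.

    Greedy by ascending (pvalue, -score, start): a hit is accepted iff its
    span overlaps no already-accepted hit on the same strand.  Applied
    jointly across matrices and spacer variants.
    """
    order = sorted(hits, key=lambda h: (h.pvalue, -h.score, h.start, h.strand))
    accepted: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    kept: list[MotifHit] = []
    for h in order:
        ivs = accepted[h.strand]
        i = bisect_left(ivs, (h.start, h.end))
        clash = False
        if i < len(ivs) and ivs[i][0] < h.end:
            clash = True
        if i > 0 and ivs[i - 1][1] > h.start:
            clash = True
        if not clash:
            insort(ivs, (h.start, h.end))
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.strand))
    return kept


def classify_location(
    hits: list[MotifHit],
    genes: list[Gene],
    filter_level: str = "keep_all",
) -> list[MotifHit]:
    """Label each hit intergenic / gene_overlapping / intragenic.

    ``filter_level``: ``keep_all`` labels only; ``drop_intragenic`` removes
    hits fully inside gene bodies; ``intergenic_only`` keeps only hits
    disjoint from all gene bodies.
    """
    if filter_level not in ("keep_all", "drop_intragenic", "intergenic_only"):
        raise ValueError(f"unknown filter_level {filter_level!r}")
    bodies = merge_intervals((g.start, g.end) for g in genes)
    starts = np.array([a for a, _ in bodies], dtype=np.int64)
    ends = np.array([b for _, b in bodies], dtype=np.int64)
    out: list[MotifHit] = []
    for h in hits:
        # merged intervals are disjoint and sorted; walk those overlapping the hit
        j = int(np.searchsorted(ends, h.start, side="right"))
        overlap = 0
        inside = False
        while j < len(starts) and starts[j] < h.end:
            ov = min(int(ends[j]), h.end) - max(int(starts[j]), h.start)
            if ov > 0:
                overlap += ov
                if starts[j] <= h.start and h.end <= ends[j]:
                    inside = True
            j += 1
        if overlap == 0:
            cls = "intergenic"
        elif inside:
            cls = "intragenic"
        else:
            cls = "gene_overlapping"
        if filter_level == "intergenic_only" and cls != "intergenic":
            continue
        if filter_level == "drop_intragenic" and cls == "intragenic":
            continue
        out.append(replace(h, location_class=cls))
    return out


def default_n_tests(genome: Genome, pwms: list[PWM]) -> int:
    """Number of scored windows: sum over matrices of 2*(L - width + 1)."""
    return sum(2 * (genome.length - p.width + 1) for p in pwms)


def bonferroni(hits: list[MotifHit], n_tests: int) -> list[MotifHit]:
    """Family-wise correction: corrected = min(1, p * n_tests)."""
    if n_tests <= 0:
        raise ValueError("n_tests must be > 0")
    return [replace(h, corrected_pvalue=min(1.0, h.pvalue * n_tests)) for h in hits]


# ---------------------------------------------------------------- output

def hits_to_dataframe(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "matrix": [h.matrix_name for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "score": [h.score for h in hits],
            "pvalue": [h.pvalue for h in hits],
            "corrected_pvalue": [h.corrected_pvalue for h in hits],
            "location_class": [h.location_class for h in hits],
            "three_prime_end": [h.three_prime_end for h in hits],
        }
    )


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    hits_to_dataframe(hits).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_hits_tsv(path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        cp = None if pd.isna(row.corrected_pvalue) else float(row.corrected_pvalue)
        lc = None if pd.isna(row.location_class) else str(row.location_class)
        out.append(
            MotifHit(
                str(row.matrix), int(row.start), int(row.end), str(row.strand),
                float(row.score), float(row.pvalue), cp, lc,
            )
        )
    return out


def write_hits_gff3(hits: list[MotifHit], path, seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits):
            attrs = f"ID=promoter{i};matrix={h.matrix_name}"
            if h.location_class:
                attrs += f";location_class={h.location_class}"
            score = -np.log10(max(h.pvalue, 1e-300))
            fh.write(
                f"{seqid}\tpromotile\tpromoter\t{h.start + 1}\t{h.end}\t{score:.3f}\t"
                f"{h.strand}\t.\t{attrs}\n"
            )
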