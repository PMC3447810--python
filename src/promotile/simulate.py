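"""Ground-truthed synthetic genome, annotation, and tiling probe tracks.

The generator emulates the study conditions the pipeline assumes: a
bacterial-sized chromosome (default 200 kb) with non-overlapping genes, a
set of active sigma70 promoters written into the sequence (-35 box, 16-22
nt spacer, -10 box, each sampled from the canonical bipartite PWM), TSSs
placed 8-14 nt downstream of the -10 element, transcripts whose expression
levels span five groups, and two replicate strand-specific probe tracks
(60-nt probes every 14 nt) carrying Gaussian log2 background plus the
transcript signal.  Highly expressed transcripts rise sharply (linearly,
through probe overlap) at their 5' end; weakly expressed ones rise
sigmoidally.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Gene, Genome, write_genes_gff3
from .motifs import sigma70_pwm
from .pwm import PWM, score_kmer, score_pvalue_table
from .tiling import ProbeTrack

__all__ = [
    "SimulationParams",
    "PlantedPromoter",
    "Transcript",
    "TrueTSS",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_tiling",
    "simulate_dataset",
    "validate_truth",
    "write_truth_tables",
]

# expression groups from weakest to strongest; the top two rise linearly
GROUPS = ("E", "D", "C", "B", "A")
LINEAR_GROUPS = ("B", "A")


@dataclass(frozen=True)
class SimulationParams:
    genome_length: int = 200_000
    n_genes: int = 120
    gc_content: float = 0.45
    n_active_promoters: int = 60
    spacer_length_range: tuple[int, int] = (16, 22)
    tss_offset_range: tuple[int, int] = (8, 14)  # -10 box 3' end -> TSS
    probe_step: int = 14
    probe_length: int = 60
    background_mode: float = 7.0
    background_sd: float = 0.5
    expression_increments: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)  # E..A
    sigmoid_scale: float = 100.0  # nt, logistic 5' onset of low-expression groups
    replicate_noise_sd: float = 0.25
    antisense_fraction: float = 0.15
    noncoding_fraction: float = 0.10
    consensus_prob: float = 0.95
    planting_max_pvalue: float = 1e-3
    gene_length_range: tuple[int, int] = (500, 1500)
    # 260 nt leaves room for one promoter+TSS at each end of a gap without
    # the two ever colliding (a promoter footprint stays within 127 nt of
    # its gene start)
    min_gap: int = 260
    noncoding_gap_boost: int = 900
    seed: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("genome_length", "n_genes", "probe_step", "probe_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_active_promoters < 0:
            raise ValueError("n_active_promoters must be >= 0")


@dataclass(frozen=True)
class PlantedPromoter:
    start: int
    end: int
    strand: str
    sequence: str  # strand-oriented, as sampled from the PWM
    spacer_length: int
    tss_index: int

    @property
    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Transcript:
    start: int
    end: int
    strand: str
    expression: float  # log2 increment over background mode
    group: str
    shape: str  # 'linear' or 'sigmoid'

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class TrueTSS:
    position: int
    strand: str
    group: str
    category: str  # sense / antisense / noncoding
    transcript_index: int


@dataclass
class SyntheticTruth:
    params: SimulationParams
    promoters: list[PlantedPromoter]
    transcripts: list[Transcript]
    tss: list[TrueTSS]
    genes: list[Gene]
    pwm: PWM = field(repr=False, default=None)


def _sample_site(pwm: PWM, dist, rng: np.random.Generator, max_pvalue: float) -> str:
    """Sample a functional site: rejection-sample until p < max_pvalue.

    Active promoters are, by definition, sequences the sigma factor
    recognizes, so the generator resamples the rare draws that fall below
    the recognition threshold of the generating model.
    """
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        idx = np.array([rng.choice(4, p=row) for row in pwm.probs])
        site = "".join(bases[idx])
        if dist.pvalue(score_kmer(pwm, site)) < max_pvalue:
            return site
    raise RuntimeError("rejection sampling failed; generating PWM too weak")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_genome(params: SimulationParams):
    """Generate genome, gene annotation and planted ground truth.

    Returns ``(Genome, genes, SyntheticTruth)``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.genome_length
    gc = params.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L, p=base_p)

    # --- transcript composition (decided first: noncoding transcripts
    # need widened gaps, reserved during placement)
    n = params.n_active_promoters
    n_anti = int(round(params.antisense_fraction * n))
    n_nc = int(round(params.noncoding_fraction * n))
    n_sense = n - n_anti - n_nc
    if n_sense > params.n_genes:
        raise ValueError("more sense transcripts than genes")
    # expression groups spread as evenly as possible over all transcripts
    group_idx = np.array([i * 5 // n for i in range(n)])
    rng.shuffle(group_idx)

    # --- gene placement: left to right with Dirichlet-skewed gaps;
    # gaps hosting a noncoding transcript are widened deterministically
    glo, ghi = params.gene_length_range
    lengths = rng.integers(glo, ghi + 1, params.n_genes)
    n_gaps = params.n_genes + 1
    boost = params.noncoding_gap_boost
    extra = L - int(lengths.sum()) - n_gaps * params.min_gap - n_nc * boost
    if extra < 0:
        raise ValueError("infeasible packing: too many/long genes for genome length")
    weights = rng.dirichlet(np.full(n_gaps, 0.5))
    gaps = params.min_gap + rng.multinomial(extra, weights)
    nc_gap_idx = rng.choice(n_gaps, size=n_nc, replace=False)
    gaps[nc_gap_idx] += boost
    genes: list[Gene] = []
    gap_spans: list[tuple[int, int]] = []
    pos = 0
    for i, glen in enumerate(lengths):
        gap_spans.append((pos, pos + int(gaps[i])))
        pos += int(gaps[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"sg{i:04d}", pos, pos + int(glen), strand, True))
        pos += int(glen)
    gap_spans.append((pos, L))

    sense_genes = list(rng.choice(params.n_genes, size=n_sense, replace=False))
    # antisense hosts: long genes not used as sense targets
    anti_pool = [i for i in range(params.n_genes)
                 if i not in set(sense_genes) and genes[i].end - genes[i].start >= 600]
    if len(anti_pool) < n_anti:
        raise ValueError("not enough long genes for antisense transcripts")
    anti_genes = [anti_pool[i] for i in rng.choice(len(anti_pool), size=n_anti, replace=False)]
    nc_gaps = [gap_spans[i] for i in nc_gap_idx]

    promoters: list[PlantedPromoter] = []
    transcripts: list[Transcript] = []
    true_tss: list[TrueTSS] = []
    pwm_cache: dict[int, tuple[PWM, object]] = {}

    def pwm_for(spacer: int):
        if spacer not in pwm_cache:
            p = sigma70_pwm(spacer, params.consensus_prob)
            pwm_cache[spacer] = (p, score_pvalue_table(p))
        return pwm_cache[spacer]

    def plant(tss_pos: int, strand: str, lo: int, hi: int, group: str, category: str):
        """Write a sampled promoter for a TSS at tss_pos; transcript [lo,hi)."""
        spacer = int(rng.integers(params.spacer_length_range[0],
                                  params.spacer_length_range[1] + 1))
        offset = int(rng.integers(params.tss_offset_range[0],
                                  params.tss_offset_range[1] + 1))
        p, dist = pwm_for(spacer)
        site = _sample_site(p, dist, rng, params.planting_max_pvalue)
        plen = p.width
        if strand == "+":
            pe = tss_pos - offset + 1  # -10 box 3' end at pe-1
            ps = pe - plen
            seq[ps:pe] = np.frombuffer(site.encode(), dtype=np.uint8)
        else:
            ps = tss_pos + offset  # -10 box 3' end (strand-oriented) at ps
            pe = ps + plen
            seq[ps:pe] = np.frombuffer(_revcomp(site).encode(), dtype=np.uint8)
        gi = GROUPS.index(group)
        expr = params.expression_increments[gi]
        shape = "linear" if group in LINEAR_GROUPS else "sigmoid"
        ti = len(transcripts)
        promoters.append(PlantedPromoter(ps, pe, strand, site, spacer, ti))
        transcripts.append(Transcript(lo, hi, strand, expr, group, shape))
        true_tss.append(TrueTSS(tss_pos, strand, group, category, ti))

    ci = 0
    for k, gi_ in enumerate(sense_genes):
        g = genes[gi_]
        group = GROUPS[group_idx[ci]]
        utr = int(rng.integers(20, 81))
        if g.strand == "+":
            tss = g.start - utr
            plant(tss, "+", tss, g.end, group, "sense")
        else:
            tss = g.end - 1 + utr
            plant(tss, "-", g.start, tss + 1, group, "sense")
        ci += 1
    for gi_ in anti_genes:
        g = genes[gi_]
        group = GROUPS[group_idx[ci]]
        glen = g.end - g.start
        tlen = int(rng.integers(300, 801))
        anti_strand = "-" if g.strand == "+" else "+"
        if anti_strand == "-":
            tss = int(rng.integers(g.start + 250, g.end - 60))
            lo = max(0, tss + 1 - tlen)
            plant(tss, "-", lo, tss + 1, group, "antisense")
        else:
            tss = int(rng.integers(g.start + 60, g.end - 250))
            hi = min(L, tss + tlen)
            plant(tss, "+", tss, hi, group, "antisense")
        ci += 1
    for a, b in nc_gaps:
        group = GROUPS[group_idx[ci]]
        # keep 260 nt clear at both gap ends for the flanking genes' promoters
        tlen = min(400, b - a - 520 - 140)
        if tlen < 200:
            raise ValueError("noncoding gap too narrow")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = a + 260 + 70
            plant(tss, "+", tss, tss + tlen, group, "noncoding")
        else:
            tss = b - 260 - 70
            plant(tss, "-", tss + 1 - tlen, tss + 1, group, "noncoding")
        ci += 1

    genome = Genome(id="synthetic", sequence=seq.tobytes().decode("ascii"))
    truth = SyntheticTruth(
        params=params,
        promoters=promoters,
        transcripts=transcripts,
        tss=true_tss,
        genes=genes,
        pwm=pwm_for(17)[0],
    )
    return genome, genes, truth


def _occupancy(truth: SyntheticTruth, strand: str) -> np.ndarray:
    """Per-base expected log2 increment over background on one strand."""
    p = truth.params
    L = p.genome_length
    occ = np.zeros(L)
    for t in truth.transcripts:
        if t.strand != strand:
            continue
        x = np.arange(t.start, t.end)
        if t.shape == "linear":
            w = np.ones(len(x), dtype=float)
        else:
            # logistic onset over sigmoid_scale nt from the 5' end
            d = (x - t.tss) if strand == "+" else (t.tss - x)
            w = 1.0 / (1.0 + np.exp(-(d - 2 * p.sigmoid_scale) / p.sigmoid_scale))
        occ[t.start:t.end] += t.expression * w
    return occ


def simulate_tiling(truth: SyntheticTruth, seed: int | None = None):
    """Two replicate probe tracks per strand for a simulated truth.

    Probe signal = N(mode, sd) background + expression x (mean occupancy
    of the probe's footprint), independently per replicate, plus
    replicate noise.  Returns ``{strand: [rep1, rep2]}``.
    """
    p = truth.params
    rng = np.random.default_rng(p.seed + 1 if seed is None else seed)
    L = p.genome_length
    starts = np.arange(0, L - p.probe_length + 1, p.probe_step, dtype=np.int64)
    out: dict[str, list[ProbeTrack]] = {}
    for strand in "+-":
        occ = _occupancy(truth, strand)
        cum = np.concatenate([[0.0], np.cumsum(occ)])
        probe_mean = (cum[starts + p.probe_length] - cum[starts]) / p.probe_length
        reps = []
        for _ in range(2):
            noise = rng.normal(p.background_mode, p.background_sd, len(starts))
            extra = rng.normal(0.0, p.replicate_noise_sd, len(starts))
            reps.append(
                ProbeTrack(
                    strand=strand,
                    probe_starts=starts,
                    signal=noise + probe_mean + extra,
                    probe_length=p.probe_length,
                )
            )
        out[strand] = reps
    return out


def simulate_dataset(params: SimulationParams):
    """Convenience wrapper: genome + annotation + truth + probe tracks."""
    genome, genes, truth = simulate_genome(params)
    tracks = simulate_tiling(truth)
    return genome, genes, truth, tracks


def validate_truth(truth: SyntheticTruth) -> None:
    """Check the generator's structural invariants; raises on violation."""
    p = truth.params
    lo_off, hi_off = p.tss_offset_range
    assert len(truth.promoters) == len(truth.tss) == len(truth.transcripts)
    for prom, tss in zip(truth.promoters, truth.tss):
        assert prom.strand == tss.strand
        if prom.strand == "+":
            d = tss.position - (prom.end - 1)
        else:
            d = prom.start - tss.position
        assert lo_off <= d <= hi_off, f"-10 to TSS offset {d} outside {lo_off}-{hi_off}"
        t = truth.transcripts[prom.tss_index]
        assert t.tss == tss.position, "transcript does not start at its TSS"
        assert 0 <= prom.start < prom.end <= p.genome_length
    spans = sorted((pr.start, pr.end, pr.strand) for pr in truth.promoters)
    for (a1, b1, s1), (a2, b2, s2) in zip(spans, spans[1:]):
        assert not (s1 == s2 and a2 < b1), "planted promoters overlap"


# ---------------------------------------------------------------- output

def write_truth_tables(truth: SyntheticTruth, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "start": [x.start for x in truth.promoters],
            "end": [x.end for x in truth.promoters],
            "strand": [x.strand for x in truth.promoters],
            "sequence": [x.sequence for x in truth.promoters],
            "spacer_length": [x.spacer_length for x in truth.promoters],
            "tss_index": [x.tss_index for x in truth.promoters],
        }
    ).to_csv(outdir / "true_promoters.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "position": [x.position for x in truth.tss],
            "strand": [x.strand for x in truth.tss],
            "group": [x.group for x in truth.tss],
            "category": [x.category for x in truth.tss],
            "transcript_index": [x.transcript_index for x in truth.tss],
        }
    ).to_csv(outdir / "true_tss.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "start": [x.start for x in truth.transcripts],
            "end": [x.end for x in truth.transcripts],
            "strand": [x.strand for x in truth.transcripts],
            "expression": [x.expression for x in truth.transcripts],
            "group": [x.group for x in truth.transcripts],
            "shape": [x.shape for x in truth.transcripts],
        }
    ).to_csv(outdir / "true_transcripts.tsv", sep="\t", index=False)


def write_dataset(genome: Genome, genes, truth: SyntheticTruth, tracks, outdir) -> None:
    from pathlib import Path

    from .tiling import write_probe_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fasta", "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 80):
            fh.write(genome.sequence[i : i + 80] + "\n")
    write_genes_gff3(genes, outdir / "genes.gff3", seqid=genome.id)
    write_probe_table(tracks, outdir / "probes.tsv")
    write_truth_tables(truth, outdir)
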