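"""Position weight matrices with spacer-length variants and exact p-values.

A :class:`PWM` models a (possibly bipartite) DNA motif as per-position
nucleotide probabilities.  Bipartite promoter motifs (-35 box, spacer,
-10 box) mark their weakly conserved spacer columns in ``spacer_cols``;
:func:`spacer_variants` derives matrices for alternative spacer lengths by
deleting or duplicating the least informative spacer columns.

Score significance is exact, not sampled: :func:`score_pvalue_table`
convolves the per-column score distributions of a background-random k-mer
on a fixed-point grid, yielding the tail probability P(score >= s) for
every attainable score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PWM",
    "ScoreDistribution",
    "build_pwm",
    "information_content",
    "spacer_variants",
    "score_kmer",
    "score_pvalue_table",
    "pvalue",
    "read_sites",
    "write_meme",
    "read_meme",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
UNIFORM = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide probability matrix with log-odds scoring."""

    name: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    spacer_cols: tuple[int, ...] = ()

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability columns must sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if any(not 0 <= c < probs.shape[0] for c in self.spacer_cols):
            raise ValueError("spacer_cols out of range")
        object.__setattr__(self, "spacer_cols", tuple(sorted(self.spacer_cols)))

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def logodds(self) -> np.ndarray:
        """log2(prob / background); -inf where the probability is zero."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)[None, :]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def build_pwm(
    sites: list[str],
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
    name: str = "motif",
    spacer_cols: tuple[int, ...] = (),
) -> PWM:
    """Build a PWM from equal-length aligned sites by per-column counting.

    ``probs[i][b] = (count(b at i) + pseudocount) / (n + 4 * pseudocount)``.
    """
    if not sites:
        raise ValueError("need at least one site")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must all have the same length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.zeros((width, 4))
    for s in sites:
        for i, b in enumerate(s.upper()):
            if b not in _IDX:
                raise ValueError(f"invalid base {b!r} in site {s!r}")
            counts[i, _IDX[b]] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    bg = UNIFORM.copy() if background is None else np.asarray(background, float)
    return PWM(name=name, probs=probs, background=bg, spacer_cols=spacer_cols)


def information_content(pwm: PWM) -> np.ndarray:
    """Per-column information content in bits, uniform-background convention.

    IC(i) = 2 + sum_b p log2 p, with 0*log(0) = 0.
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=1)


def spacer_variants(pwm: PWM, target_lengths=range(16, 23)) -> list[PWM]:
    """Derive one matrix per target spacer length.

    Shorter targets delete the lowest-information spacer columns (ties
    broken leftmost); longer targets duplicate the lowest-information
    columns in place, each copy inserted immediately right of its source.
    The native length returns the input matrix; box columns are never
    touched.
    """
    if not pwm.spacer_cols:
        raise ValueError("pwm has no spacer columns")
    native = len(pwm.spacer_cols)
    ic = information_content(pwm)
    # spacer columns ordered by (IC, index): least informative first
    order = sorted(pwm.spacer_cols, key=lambda c: (ic[c], c))
    out: list[PWM] = []
    for t in target_lengths:
        if t < 1:
            raise ValueError(f"target spacer length {t} < 1")
        if t == native:
            out.append(pwm)
            continue
        if t < native:
            k = native - t
            if k > native:
                raise ValueError(f"cannot delete {k} of {native} spacer columns")
            drop = set(order[:k])
            keep = [i for i in range(pwm.width) if i not in drop]
            probs = pwm.probs[keep]
            new_spacer = tuple(
                j for j, i in enumerate(keep) if i in pwm.spacer_cols
            )
        else:
            k = t - native
            # round-robin over the least informative columns if k > native
            src = [order[i % native] for i in range(k)]
            rows: list[np.ndarray] = []
            is_spacer: list[bool] = []
            for i in range(pwm.width):
                rows.append(pwm.probs[i])
                is_spacer.append(i in pwm.spacer_cols)
                for _ in range(src.count(i)):
                    rows.append(pwm.probs[i])
                    is_spacer.append(True)
            probs = np.vstack(rows)
            new_spacer = tuple(j for j, sp in enumerate(is_spacer) if sp)
        out.append(
            PWM(
                name=f"{pwm.name}_sp{t}",
                probs=probs,
                background=pwm.background,
                spacer_cols=new_spacer,
            )
        )
    return out


def score_kmer(pwm: PWM, kmer: str) -> float:
    """Log-odds score of a k-mer: sum of per-position log2(p/bg)."""
    if len(kmer) != pwm.width:
        raise ValueError(f"kmer length {len(kmer)} != matrix width {pwm.width}")
    lo = pwm.logodds
    total = 0.0
    for i, b in enumerate(kmer.upper()):
        if b not in _IDX:
            raise ValueError(f"invalid base {b!r}")
        total += lo[i, _IDX[b]]
    return total


NEG_SENTINEL = np.int64(-(2**40))  # integer stand-in for -inf column scores


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact tail distribution of the discretized background score.

    Scoring and significance share one fixed-point grid: each column's
    log-odds are floored onto a grid of ``granularity`` log2 units
    (``column_scores``), a window's discretized score is the sum of its
    per-column grid scores, and ``tail[i]`` is the exact probability that
    a background-random k-mer's discretized score is >= ``kmin + i``.
    Scoring queries in the same discretized domain keeps the reported
    p-values exactly calibrated; float queries are floored with a
    (width - 1)-unit allowance for per-column rounding, which can only
    overstate the p-value (conservative).
    """

    granularity: float
    kmin: int
    tail: np.ndarray  # non-increasing
    column_scores: np.ndarray  # (width, 4) int64, NEG_SENTINEL where p == 0

    @property
    def width(self) -> int:
        return self.column_scores.shape[0]

    def kmer_grid_score(self, kmer: str) -> int:
        """Discretized score of a k-mer (sum of per-column grid scores)."""
        if len(kmer) != self.width:
            raise ValueError("kmer length != matrix width")
        total = 0
        for i, b in enumerate(kmer.upper()):
            if b not in _IDX:
                raise ValueError(f"invalid base {b!r}")
            total += int(self.column_scores[i, _IDX[b]])
        return total

    def grid_pvalue(self, k) -> np.ndarray | float:
        """Exact tail probability of a discretized score."""
        karr = np.atleast_1d(np.asarray(k, dtype=np.int64))
        idx = np.clip(karr - self.kmin, 0, len(self.tail) - 1)
        out = np.where(karr < self.kmin, 1.0, self.tail[idx])
        out = np.where(karr > self.kmin + len(self.tail) - 1, self.tail[-1], out)
        return out if np.ndim(k) else float(out[0])

    def kmer_pvalue(self, kmer: str) -> float:
        k = self.kmer_grid_score(kmer)
        if k < NEG_SENTINEL // 2:
            return 1.0
        return float(self.grid_pvalue(k))

    def pvalue(self, score: float) -> float:
        """P(background score >= score) for a float (log2) query.

        Per-column flooring can place a k-mer's grid score up to
        width - 1 units below floor(score / granularity); the query is
        lowered by that allowance so the answer never understates the
        p-value.  For exact per-kmer values use :meth:`kmer_pvalue`.
        """
        if not np.isfinite(score):
            return 1.0 if score < 0 else float(self.tail[-1])
        k = int(np.floor(score / self.granularity + 1e-9)) - (self.width - 1)
        return float(self.grid_pvalue(k))


def score_pvalue_table(pwm: PWM, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact score distribution by position-wise convolution.

    Each column's four log-odds scores are floored onto the grid; the
    distribution of their sum under the background is built by dynamic
    programming over columns.  Columns with zero probability (score -inf)
    contribute mass that never reaches any finite score, so the finite
    tail sums to less than one; queries at -inf return p = 1.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    lo = pwm.logodds
    bg = pwm.background
    colmat = np.full((pwm.width, 4), NEG_SENTINEL, dtype=np.int64)
    cols = []
    for i in range(pwm.width):
        finite = np.isfinite(lo[i])
        q = np.floor(lo[i][finite] / granularity + 1e-9).astype(np.int64)
        colmat[i, finite] = q
        cols.append((q, bg[finite]))
    kmin = sum(int(q.min()) for q, _ in cols)
    kmax = sum(int(q.max()) for q, _ in cols)
    dist = np.zeros(kmax - kmin + 1)
    # dist indexed relative to the running minimum attainable score
    dist[0] = 1.0
    cur_min = 0
    cur_len = 1
    for q, w in cols:
        qmin, qmax = int(q.min()), int(q.max())
        new_len = cur_len + (qmax - qmin)
        new = np.zeros(new_len)
        for qi, wi in zip(q, w):
            off = int(qi) - qmin
            new[off : off + cur_len] += wi * dist[:cur_len]
        dist[:new_len] = new
        dist[new_len:] = 0.0
        cur_len = new_len
        cur_min += qmin
    assert cur_min == kmin and cur_len == len(dist)
    tail = np.cumsum(dist[::-1])[::-1]
    return ScoreDistribution(
        granularity=granularity, kmin=kmin, tail=tail, column_scores=colmat
    )


def pvalue(dist: ScoreDistribution, score: float) -> float:
    """Tail probability P(background score >= score), grid-conservative."""
    return dist.pvalue(score)


# ---------------------------------------------------------------- I/O

def read_sites(path) -> list[str]:
    """Read aligned sites from FASTA or one-sequence-per-line text."""
    sites: list[str] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if any(ln.startswith(">") for ln in lines):
        cur: list[str] = []
        for ln in lines:
            if ln.startswith(">"):
                if cur:
                    sites.append("".join(cur))
                cur = []
            else:
                cur.append(ln)
        if cur:
            sites.append("".join(cur))
    else:
        sites = lines
    return [s.upper() for s in sites]


def write_meme(pwms: list[PWM] | PWM, path) -> None:
    """Write motifs in MEME minimal format (spacer columns as a comment)."""
    if isinstance(pwms, PWM):
        pwms = [pwms]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0\n"
            )
            for row in p.probs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            if p.spacer_cols:
                fh.write("# spacer_cols: " + ",".join(map(str, p.spacer_cols)) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms: list[PWM] = []
    bg = UNIFORM.copy()
    name = None
    rows: list[list[float]] = []
    spacer: tuple[int, ...] = ()

    def flush():
        nonlocal name, rows, spacer
        if name is not None and rows:
            pwms.append(PWM(name=name, probs=np.array(rows), background=bg.copy(), spacer_cols=spacer))
        name, rows, spacer = None, [], ()

    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for ln in lines:
        s = ln.strip()
        if s.startswith("Background letter frequencies"):
            vals = next(lines).split()
            bg = np.array([float(vals[i]) for i in (1, 3, 5, 7)])
        elif s.startswith("MOTIF"):
            flush()
            name = s.split()[1]
        elif s.startswith("# spacer_cols:"):
            spacer = tuple(int(x) for x in s.split(":")[1].split(","))
        elif name is not None and s:
            parts = s.split()
            if len(parts) == 4:
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    pass
    flush()
    return pwms


def write_matrix_tsv(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(ALPHABET) + "\tspacer\n")
        for i, row in enumerate(pwm.probs):
            sp = "1" if i in pwm.spacer_cols else "0"
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + f"\t{sp}\n")


def read_matrix_tsv(path, name: str = "motif", background=None) -> PWM:
    rows = []
    spacer = []
    with open(path) as fh:
        header = fh.readline()
        for ln in fh:
            parts = ln.split()
            if not parts:
                continue
            rows.append([float(x) for x in parts[1:5]])
            if len(parts) > 5 and parts[5] == "1":
                spacer.append(int(parts[0]))
    bg = UNIFORM.copy() if background is None else np.asarray(background, float)
    return PWM(name=name, probs=np.array(rows), background=bg, spacer_cols=tuple(spacer))
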