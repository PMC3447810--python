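"""Promoter-TSS co-localization and its significance.

Each inferred TSS is matched to the same-strand predicted promoter whose
3' end is nearest (signed, strand-oriented distance); matches within a
cutoff (default 40 nt) count as co-localized.  The expected co-occurrence
under randomness comes from a Monte-Carlo null that re-places promoter 3'
ends uniformly on the genome, and observed-vs-expected counts are compared
with a one-sided Fisher exact test whose hypergeometric tail is evaluated
in log space (the observed enrichment can be far beyond double-precision
p-values on real genomes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .scan import MotifHit
from .tars import GROUP_LABELS, TSS

__all__ = [
    "ColocalizationMatch",
    "NullDistribution",
    "colocalize",
    "permutation_null",
    "fisher_cooccurrence",
    "log10_fisher_cooccurrence",
    "log_hypergeom_tail",
    "distance_histogram",
    "matches_to_dataframe",
]


@dataclass(frozen=True)
class ColocalizationMatch:
    tss: TSS
    hit: MotifHit
    distance: int  # signed, strand-oriented: TSS - promoter 3' end


@dataclass(frozen=True)
class NullDistribution:
    n_reps: int
    per_rep_fraction: np.ndarray
    expected_fraction: float
    seed: int

    @property
    def se(self) -> float:
        """Monte-Carlo standard error of the expected fraction."""
        return float(self.per_rep_fraction.std(ddof=1) / np.sqrt(self.n_reps))


def _signed_distance(tss_pos: int, three_prime: int, strand: str) -> int:
    """Positive when the TSS lies downstream of the promoter 3' end."""
    return tss_pos - three_prime if strand == "+" else three_prime - tss_pos


def colocalize(
    hits: list[MotifHit],
    tss_list: list[TSS],
    cutoff: int = 40,
    directional: bool = False,
) -> list[ColocalizationMatch]:
    """Match each TSS to its nearest same-strand promoter 3' end.

    One match per TSS at most, reported iff |distance| <= cutoff (or
    0 <= distance <= cutoff in ``directional`` mode, promoter strictly
    upstream).
    """
    ends = {"+": [], "-": []}
    by_strand: dict[str, list[MotifHit]] = {"+": [], "-": []}
    for h in hits:
        by_strand[h.strand].append(h)
    for s in ends:
        by_strand[s].sort(key=lambda h: h.three_prime_end)
        ends[s] = np.array([h.three_prime_end for h in by_strand[s]], dtype=np.int64)
    matches: list[ColocalizationMatch] = []
    for t in tss_list:
        arr = ends[t.strand]
        if len(arr) == 0:
            continue
        i = int(np.searchsorted(arr, t.position))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                h = by_strand[t.strand][j]
                d = _signed_distance(t.position, h.three_prime_end, t.strand)
                key = (abs(d), d)
                if best is None or key < best[0]:
                    best = (key, h, d)
        if best is None:
            continue
        _, h, d = best
        ok = (0 <= d <= cutoff) if directional else (abs(d) <= cutoff)
        if ok:
            matches.append(ColocalizationMatch(tss=t, hit=h, distance=d))
    return matches


def permutation_null(
    tss_list: list[TSS],
    n_promoters: int,
    genome_length: int,
    cutoff: int = 40,
    n_reps: int = 10000,
    seed: int = 0,
    randomize: str = "promoters",
) -> NullDistribution:
    """Monte-Carlo null for the co-localized fraction of TSSs.

    ``randomize='promoters'`` (default) re-places ``n_promoters`` promoter
    3' ends uniformly, half per strand, keeping the TSSs fixed;
    ``randomize='tss'`` re-places the TSSs uniformly instead, keeping the
    promoters' strand split.  Each replicate records the fraction of TSSs
    with a same-strand position within ``cutoff`` nt.
    """
    if randomize not in ("promoters", "tss"):
        raise ValueError("randomize must be 'promoters' or 'tss'")
    rng = np.random.default_rng(seed)
    tss_pos = {
        s: np.sort([t.position for t in tss_list if t.strand == s]) for s in "+-"
    }
    n_tss = len(tss_list)
    fractions = np.zeros(n_reps)
    if n_promoters <= 0 or n_tss == 0:
        return NullDistribution(n_reps, fractions, 0.0, seed)
    n_plus = n_promoters // 2
    counts = {"+": n_plus, "-": n_promoters - n_plus}
    for r in range(n_reps):
        hit_count = 0
        for s in "+-":
            if randomize == "promoters":
                queries = tss_pos[s]
                placed = np.sort(rng.integers(0, genome_length, counts[s]))
            else:
                queries = np.sort(rng.integers(0, genome_length, len(tss_pos[s])))
                placed = tss_pos[s]
            if len(queries) == 0 or len(placed) == 0:
                continue
            i = np.searchsorted(placed, queries)
            left = np.where(i > 0, queries - placed[np.maximum(i - 1, 0)], np.iinfo(np.int64).max)
            right = np.where(
                i < len(placed), placed[np.minimum(i, len(placed) - 1)] - queries,
                np.iinfo(np.int64).max,
            )
            hit_count += int(np.sum(np.minimum(left, right) <= cutoff))
        fractions[r] = hit_count / n_tss
    return NullDistribution(n_reps, fractions, float(fractions.mean()), seed)


_LGAMMA_INT = np.zeros(0)


def _lgamma_table(n: int) -> np.ndarray:
    """gammaln over integers 0..n, cached (log-factorial lookups)."""
    global _LGAMMA_INT
    if len(_LGAMMA_INT) <= n:
        _LGAMMA_INT = gammaln(np.arange(max(n + 1, 4096), dtype=float))
    return _LGAMMA_INT


def log_hypergeom_tail(k: int, total: int, successes: int, draws: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(total, successes, draws)."""
    kmax = min(successes, draws)
    kmin_ = max(0, successes + draws - total)
    if k <= kmin_:
        return 0.0
    if k > kmax:
        return -np.inf
    lg = _lgamma_table(total + 2)
    ks = np.arange(k, kmax + 1)
    logpmf = (
        lg[successes + 1] - lg[ks + 1] - lg[successes - ks + 1]
        + lg[total - successes + 1] - lg[draws - ks + 1]
        - lg[total - successes - draws + ks + 1]
        - (lg[total + 1] - lg[draws + 1] - lg[total - draws + 1])
    )
    m = logpmf.max()
    return float(m + np.log(np.exp(logpmf - m).sum()))


def _fisher_table(observed_hit: int, observed_total: int, null: NullDistribution):
    if not 0 <= observed_hit <= observed_total:
        raise ValueError("need 0 <= observed_hit <= observed_total")
    expected_hit = int(round(null.expected_fraction * observed_total))
    a, b = observed_hit, observed_total - observed_hit
    c, d = expected_hit, observed_total - expected_hit
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        raise ValueError(f"degenerate 2x2 table [[{a},{b}],[{c},{d}]]: zero margin")
    return a, b, c, d


def fisher_cooccurrence(
    observed_hit: int, observed_total: int, null: NullDistribution
) -> float:
    """One-sided Fisher exact p for enrichment of observed over expected."""
    return float(np.exp(log10_fisher_cooccurrence(observed_hit, observed_total, null) * np.log(10)))


def log10_fisher_cooccurrence(
    observed_hit: int, observed_total: int, null: NullDistribution
) -> float:
    """log10 of the one-sided Fisher exact p-value (log-space tail)."""
    a, b, c, d = _fisher_table(observed_hit, observed_total, null)
    logp = log_hypergeom_tail(a, total=a + b + c + d, successes=a + c, draws=a + b)
    return logp / np.log(10)


def distance_histogram(
    matches: list[ColocalizationMatch],
    bin_width: int = 5,
    max_dist: int = 60,
) -> pd.DataFrame:
    """Counts of matches per (signed distance bin x TSS expression group)."""
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width)
    table = pd.DataFrame(
        0, index=edges[:-1], columns=list(reversed(GROUP_LABELS)), dtype=int
    )
    table.index.name = "distance_bin_start"
    for m in matches:
        if not -max_dist <= m.distance < max_dist:
            continue
        b = edges[np.searchsorted(edges, m.distance, side="right") - 1]
        grp = m.tss.group if m.tss.group in table.columns else None
        if grp is not None:
            table.loc[b, grp] += 1
    return table


def matches_to_dataframe(matches: list[ColocalizationMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tss_position": [m.tss.position for m in matches],
            "strand": [m.tss.strand for m in matches],
            "promoter_matrix": [m.hit.matrix_name for m in matches],
            "promoter_start": [m.hit.start for m in matches],
            "promoter_end": [m.hit.end for m in matches],
            "promoter_pvalue": [m.hit.pvalue for m in matches],
            "distance": [m.distance for m in matches],
            "group": [m.tss.group for m in matches],
        }
    )


def plot_distance_histogram(table: pd.DataFrame, ax=None):
    """Stacked bar chart of the distance histogram (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(table))
    for col in table.columns:
        ax.bar(table.index, table[col], width=4, bottom=bottom, label=f"group {col}")
        bottom += table[col].to_numpy()
    ax.set_xlabel("TSS - promoter 3' end distance (nt)")
    ax.set_ylabel("co-localized pairs")
    ax.legend()
    return ax
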