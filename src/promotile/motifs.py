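"""Canonical sigma70 promoter motif models (synthetic consensus fixtures).

The housekeeping sigma factor recognizes a bipartite promoter: a -35 box
(consensus TTGACA) and a -10 box (consensus TATAAT) separated by a weakly
conserved spacer of 16-22 nt.  These constructors build idealized PWMs
directly from the consensus, for use as scanning models and as the
generating model of the synthetic-data module.  They are synthetic
consensus fixtures, not matrices estimated from any organism's sites.
"""

from __future__ import annotations

import numpy as np

from .pwm import ALPHABET, PWM, UNIFORM

__all__ = [
    "MINUS35",
    "MINUS10",
    "EXTENDED_MINUS10",
    "sigma70_pwm",
    "extended_minus10_pwm",
]

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"
EXTENDED_MINUS10 = "TGTATAAT"  # TG dinucleotide extension of the -10 box

_IDX = {b: i for i, b in enumerate(ALPHABET)}


def _consensus_probs(consensus: str, consensus_prob: float) -> np.ndarray:
    off = (1.0 - consensus_prob) / 3.0
    probs = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        probs[i, _IDX[b]] = consensus_prob
    return probs


def sigma70_pwm(
    spacer_length: int = 17,
    consensus_prob: float = 0.95,
    background: np.ndarray | None = None,
    name: str | None = None,
) -> PWM:
    """Bipartite -35/spacer/-10 matrix with a uniform (uninformative) spacer.

    ``consensus_prob`` is the probability of the consensus base at each box
    position; the remainder is spread evenly over the other three bases.
    """
    if spacer_length < 1:
        raise ValueError("spacer_length must be >= 1")
    bg = UNIFORM.copy() if background is None else np.asarray(background, float)
    probs = np.vstack(
        [
            _consensus_probs(MINUS35, consensus_prob),
            np.tile(bg, (spacer_length, 1)),
            _consensus_probs(MINUS10, consensus_prob),
        ]
    )
    spacer_cols = tuple(range(len(MINUS35), len(MINUS35) + spacer_length))
    return PWM(
        name=name or f"sigma70_sp{spacer_length}",
        probs=probs,
        background=bg,
        spacer_cols=spacer_cols,
    )


def extended_minus10_pwm(
    consensus_prob: float = 0.95,
    background: np.ndarray | None = None,
) -> PWM:
    """Extended -10 box matrix (TG + TATAAT), no spacer columns."""
    bg = UNIFORM.copy() if background is None else np.asarray(background, float)
    return PWM(
        name="extended_minus10",
        probs=_consensus_probs(EXTENDED_MINUS10, consensus_prob),
        background=bg,
    )
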