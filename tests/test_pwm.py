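"""PWM construction, information content, spacer variants, exact p-values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotile.motifs import sigma70_pwm
from promotile.pwm import (
    PWM,
    build_pwm,
    information_content,
    read_matrix_tsv,
    read_meme,
    score_kmer,
    score_pvalue_table,
    spacer_variants,
    write_matrix_tsv,
    write_meme,
)

SITES = ["TATAAT", "TATAAT", "TATGAT", "TACAAT"]


class TestBuildPwm:
    def test_unanimous_column(self):
        pwm = build_pwm(SITES, pseudocount=0)
        assert pwm.probs[0, 3] == 1.0  # T everywhere at position 0

    def test_counted_column(self):
        pwm = build_pwm(SITES, pseudocount=0)
        # position 3: A,A,G,A
        assert pwm.probs[3, 0] == pytest.approx(0.75)
        assert pwm.probs[3, 2] == pytest.approx(0.25)

    def test_consensus(self):
        assert build_pwm(SITES, pseudocount=0).consensus() == "TATAAT"

    def test_pseudocount(self):
        pwm = build_pwm(["A"], pseudocount=1.0)
        assert pwm.probs[0] == pytest.approx([0.4, 0.2, 0.2, 0.2])

    def test_errors(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["AC", "A"])
        with pytest.raises(ValueError):
            build_pwm(["AX"])


class TestInformationContent:
    def test_certain_column_two_bits(self):
        pwm = build_pwm(["T"], pseudocount=0)
        assert information_content(pwm)[0] == pytest.approx(2.0)

    def test_uniform_column_zero_bits(self):
        pwm = PWM("u", np.full((1, 4), 0.25))
        assert information_content(pwm)[0] == pytest.approx(0.0)

    def test_hand_computed_mixture(self):
        # p(T)=0.75, p(C)=0.25: 2 + .75 log2 .75 + .25 log2 .25 = 1.18872...
        pwm = PWM("m", np.array([[0.0, 0.25, 0.0, 0.75]]))
        assert information_content(pwm)[0] == pytest.approx(1.18872, abs=1e-5)


class TestSpacerVariants:
    def test_variant_count_and_widths(self):
        base = sigma70_pwm(18)
        variants = spacer_variants(base, range(16, 23))
        assert len(variants) == 7
        assert [v.width - 12 for v in variants] == list(range(16, 23))
        assert [len(v.spacer_cols) for v in variants] == list(range(16, 23))

    def test_native_length_returns_input(self):
        base = sigma70_pwm(18)
        v = spacer_variants(base, [18])[0]
        assert v is base

    def test_box_columns_untouched(self):
        base = sigma70_pwm(18)
        for v in spacer_variants(base, range(16, 23)):
            box = [i for i in range(v.width) if i not in v.spacer_cols]
            assert len(box) == 12
            np.testing.assert_array_equal(v.probs[box], base.probs[[*range(6), *range(24, 30)]])

    def test_deletion_removes_lowest_ic_leftmost(self):
        # make spacer columns with distinct IC: col 8 weakest, then col 6
        base = sigma70_pwm(4)  # spacer cols 6..9, uniform
        probs = base.probs.copy()
        probs[7] = [0.7, 0.1, 0.1, 0.1]
        probs[9] = [0.1, 0.1, 0.7, 0.1]
        pwm = PWM("t", probs, spacer_cols=base.spacer_cols)
        # IC: cols 6,8 = 0 (uniform, leftmost ties), cols 7,9 higher
        v = spacer_variants(pwm, [2])[0]
        # sort-by-IC oracle: drop cols 6 and 8
        keep = [i for i in range(pwm.width) if i not in (6, 8)]
        np.testing.assert_allclose(v.probs, pwm.probs[keep])

    def test_duplication_inserts_right_of_source(self):
        base = sigma70_pwm(4)
        probs = base.probs.copy()
        probs[6] = [0.7, 0.1, 0.1, 0.1]
        probs[8] = [0.6, 0.2, 0.1, 0.1]
        probs[9] = [0.5, 0.3, 0.1, 0.1]
        pwm = PWM("t", probs, spacer_cols=base.spacer_cols)
        v = spacer_variants(pwm, [5])[0]  # duplicate col 7 (only uniform one)
        assert v.width == pwm.width + 1
        np.testing.assert_allclose(v.probs[7], v.probs[8])  # copy sits right of source
        np.testing.assert_allclose(v.probs[9:11], pwm.probs[8:10])

    def test_errors(self):
        base = sigma70_pwm(3)
        with pytest.raises(ValueError):
            spacer_variants(base, [0])
        with pytest.raises(ValueError):
            spacer_variants(PWM("x", np.full((4, 4), 0.25)), [2])


class TestScoreKmer:
    def test_width_one_certain(self):
        pwm = build_pwm(["A"], pseudocount=0)
        assert score_kmer(pwm, "A") == pytest.approx(2.0)  # log2(1/0.25)

    def test_consensus_maximal(self):
        rng = np.random.default_rng(1)
        pwm = PWM("r", rng.dirichlet(np.ones(4), size=4))
        cons = pwm.consensus()
        best = score_kmer(pwm, cons)
        for kmer in itertools.product("ACGT", repeat=4):
            assert score_kmer(pwm, "".join(kmer)) <= best + 1e-12

    def test_additivity_on_toy_matrix(self):
        probs = np.array([[0.5, 0.3, 0.1, 0.1], [0.25] * 4, [0.1, 0.1, 0.1, 0.7]])
        pwm = PWM("t", probs)
        expect = np.log2(0.5 / 0.25) + np.log2(0.25 / 0.25) + np.log2(0.7 / 0.25)
        assert score_kmer(pwm, "ACT") == pytest.approx(expect)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_kmer(build_pwm(["AC"]), "A")


def enumeration_tail(pwm, granularity=1e-3):
    """Brute-force oracle: exact tail of the discretized background score."""
    with np.errstate(divide="ignore"):
        lo = pwm.logodds
    q = np.floor(lo / granularity + 1e-9)
    scores, weights = [], []
    for kmer in itertools.product(range(4), repeat=pwm.width):
        s = sum(q[i, b] for i, b in enumerate(kmer))
        w = np.prod([pwm.background[b] for b in kmer])
        if np.isfinite(s):
            scores.append(int(s))
            weights.append(w)
    return np.array(scores), np.array(weights)


class TestPvalue:
    def test_width_one_max(self):
        pwm = PWM("w1", np.array([[0.7, 0.1, 0.1, 0.1]]))
        dist = score_pvalue_table(pwm)
        assert dist.kmer_pvalue("A") == pytest.approx(0.25)

    def test_width_two_max_matches_enumeration(self):
        rng = np.random.default_rng(2)
        pwm = PWM("w2", rng.dirichlet(np.ones(4), size=2))
        dist = score_pvalue_table(pwm)
        cons = pwm.consensus()
        scores, weights = enumeration_tail(pwm)
        k = dist.kmer_grid_score(cons)
        assert dist.kmer_pvalue(cons) == pytest.approx(
            weights[scores >= k].sum(), abs=1e-12
        )

    def test_minus_infinity_scores_p_one(self):
        pwm = build_pwm(["AA", "AA"], pseudocount=0)  # zero prob for C/G/T
        dist = score_pvalue_table(pwm)
        assert dist.pvalue(-np.inf) == 1.0
        assert dist.kmer_pvalue("CC") == 1.0

    def test_tail_monotone_nonincreasing(self):
        pwm = sigma70_pwm(3)
        dist = score_pvalue_table(pwm)
        assert np.all(np.diff(dist.tail) <= 1e-15)
        assert dist.tail[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [3, 5])
    def test_enumeration_equivalence_nonuniform_background(self, width):
        rng = np.random.default_rng(width)
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = PWM("e", rng.dirichlet(np.ones(4), size=width), background=bg)
        dist = score_pvalue_table(pwm)
        scores, weights = enumeration_tail(pwm)
        for k in np.unique(scores):
            assert dist.grid_pvalue(int(k)) == pytest.approx(
                weights[scores >= k].sum(), abs=1e-9
            )

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=-30, max_value=30), st.floats(min_value=-30, max_value=30))
    def test_pvalue_monotone_in_score(self, s1, s2):
        pwm = sigma70_pwm(2)
        dist = score_pvalue_table(pwm)
        lo, hi = sorted((s1, s2))
        assert dist.pvalue(hi) <= dist.pvalue(lo)

    def test_float_query_is_conservative(self):
        pwm = sigma70_pwm(3)
        dist = score_pvalue_table(pwm)
        for kmer in ["TTGACAGCATATAAT", "TAGACAAAATATAAT", "ACGTACGTACGTACG"]:
            assert dist.pvalue(score_kmer(pwm, kmer)) >= dist.kmer_pvalue(kmer) - 1e-15


class TestSerialization:
    def test_meme_round_trip(self, tmp_path):
        pwms = spacer_variants(sigma70_pwm(17), [16, 17])
        path = tmp_path / "m.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == [p.name for p in pwms]
        for a, b in zip(back, pwms):
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-6)
            assert a.spacer_cols == b.spacer_cols

    def test_matrix_tsv_round_trip(self, tmp_path):
        pwm = sigma70_pwm(16)
        path = tmp_path / "m.tsv"
        write_matrix_tsv(pwm, path)
        back = read_matrix_tsv(path, name=pwm.name)
        np.testing.assert_allclose(back.probs, pwm.probs, atol=1e-6)
        assert back.spacer_cols == pwm.spacer_cols
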