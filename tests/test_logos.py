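"""PFMs, logo information content, degenerate signatures, window scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrpsmith import (
    AlignedBlock,
    DomainToken as D,
    PFM,
    column_frequencies,
    information_content,
    locate_best_window,
    locate_windows_ordered,
    make_signature,
    score_window,
    train_model,
    uniform_background,
)
from nrpsmith.logos import (
    AA_ALPHABET,
    BlockError,
    DegenerateSignature,
    LOG2_20,
    SignatureModel,
    load_models,
    save_models,
)

H = AA_ALPHABET.index("H")
A = AA_ALPHABET.index("A")
C = AA_ALPHABET.index("C")


def _onehot_pfm(consensus: str) -> PFM:
    idx = [AA_ALPHABET.index(ch) for ch in consensus]
    return PFM(np.eye(20)[idx], np.ones(len(consensus)))


class TestColumnFrequencies:
    def test_single_row_is_one_hot(self):
        pfm = column_frequencies(AlignedBlock(D.LCL, ["HH"]), alpha=0.0)
        assert pfm.freqs[0, H] == 1.0
        assert pfm.freqs[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_rows_split_evenly(self):
        pfm = column_frequencies(AlignedBlock(D.LCL, ["A", "C"]), alpha=0.0)
        assert pfm.freqs[0, A] == pytest.approx(0.5)
        assert pfm.freqs[0, C] == pytest.approx(0.5)

    def test_pseudocount_hand_arithmetic(self):
        # counts {A:2, C:1, D:1}, alpha 0.5, uniform bg: (2 + 0.025) / 4.5
        pfm = column_frequencies(AlignedBlock(D.LCL, ["A", "A", "C", "D"]), alpha=0.5)
        assert pfm.freqs[0, A] == pytest.approx((2 + 0.025) / 4.5, rel=1e-6)

    def test_gap_mass_excluded(self):
        pfm = column_frequencies(AlignedBlock(D.LCL, ["A", "-"]), alpha=0.0)
        assert pfm.freqs[0, A] == pytest.approx(1.0)
        assert pfm.counts[0] == 1
        assert pfm.gap_fraction[0] == pytest.approx(0.5)

    def test_ragged_block_rejected(self):
        with pytest.raises(BlockError, match="ragged"):
            AlignedBlock(D.LCL, ["AA", "A"])

    def test_empty_block_rejected(self):
        with pytest.raises(BlockError, match="empty"):
            AlignedBlock(D.LCL, [])


class TestInformationContent:
    def test_conserved_column_large_n_approaches_log2_20(self):
        col = information_content(np.eye(20)[H], n=10**6)
        assert col.R == pytest.approx(LOG2_20, abs=1e-4)

    def test_uniform_column_clipped_to_zero(self):
        col = information_content(uniform_background(), n=5)
        assert col.R == 0.0

    def test_small_sample_correction_n4(self):
        col = information_content(np.eye(20)[H], n=4)
        assert col.e_n == pytest.approx(19.0 / (2 * math.log(2) * 4), rel=1e-9)
        assert col.R == pytest.approx(0.8955, abs=1e-4)

    @given(st.integers(1, 200))
    @settings(max_examples=60, deadline=None)
    def test_heights_sum_to_R_and_R_in_range(self, n):
        rng = np.random.default_rng(n)
        f = rng.dirichlet(np.ones(20))
        col = information_content(f, n)
        assert 0.0 <= col.R <= LOG2_20
        assert sum(col.heights.values()) == pytest.approx(col.R, abs=1e-9)

    def test_R_increases_with_block_depth(self):
        # identical sequences: the correction shrinks as n grows
        rs = [
            information_content(np.eye(20)[H], n=n).R for n in (2, 4, 8, 16)
        ]
        assert rs == sorted(rs)
        assert rs[0] < rs[-1]


class TestDegenerateSignature:
    def test_single_major(self):
        pfm = PFM(np.eye(20)[[H]] * 0.9 + 0.1 / 19 * (1 - np.eye(20)[[H]]), np.ones(1))
        sig = make_signature(pfm)
        assert sig.positions[0][0] == ("H",)
        assert sig.render() == "H"

    def test_alternatives_only(self):
        f = np.full(20, 0.3 / 18)
        f[AA_ALPHABET.index("D")] = 0.4
        f[AA_ALPHABET.index("E")] = 0.3
        sig = make_signature(PFM(f[None, :], np.ones(1)), 0.5, 0.15)
        assert sig.positions[0] == ((), ("D", "E"))
        assert sig.render() == "x[DE]"

    def test_uniform_is_wildcard(self):
        sig = make_signature(PFM(uniform_background()[None, :], np.ones(1)))
        assert sig.render() == "x"

    @pytest.mark.parametrize("text", ["Hx[LM]D", "x", "A[CD]x[EF]G", "(HK)x"])
    def test_parse_render_round_trip(self, text):
        assert DegenerateSignature.parse(text).render() == text

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            make_signature(PFM(uniform_background()[None, :], np.ones(1)), 0.1, 0.5)


class TestScoreWindow:
    def test_consensus_against_one_hot_pfm(self):
        pfm = _onehot_pfm("ACDE")
        # each position log2(1 / 0.05) = log2 20
        assert score_window("ACDE", pfm) == pytest.approx(4 * LOG2_20, rel=1e-9)

    def test_all_x_scores_zero(self):
        assert score_window("XXXX", _onehot_pfm("ACDE")) == 0.0

    def test_background_model_scores_zero(self):
        pfm = PFM(np.tile(uniform_background(), (3, 1)), np.ones(3))
        assert score_window("ACD", pfm) == pytest.approx(0.0, abs=1e-12)

    def test_gap_penalty(self):
        pfm = _onehot_pfm("AC")
        assert score_window("A-", pfm) == pytest.approx(LOG2_20 - 2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            score_window("AC", _onehot_pfm("ACD"))


def _brute_force_best(seq, pfm, bg):
    scores = [
        score_window(seq[o : o + pfm.length], pfm, bg)
        for o in range(len(seq) - pfm.length + 1)
    ]
    best = max(scores)
    return scores.index(best), best


class TestLocateWindows:
    def test_equals_brute_force_on_random_sequences(self, rng):
        pfm = _onehot_pfm("HHWW")
        for _ in range(25):
            seq = "".join(rng.choice(list(AA_ALPHABET), size=60))
            assert locate_best_window(seq, pfm) == pytest.approx(
                _brute_force_best(seq, pfm, uniform_background())
            )

    def test_tie_broken_leftmost(self):
        pfm = _onehot_pfm("HH")
        off, _ = locate_best_window("AAHHAAHHAA", pfm)
        assert off == 2

    def test_sequence_equal_to_window_length(self):
        off, _ = locate_best_window("HH", _onehot_pfm("HH"))
        assert off == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            locate_best_window("H", _onehot_pfm("HH"))

    def test_ordered_constraint_enforced(self):
        # the best single offsets would be out of order; the joint scan
        # must keep WL1 before WL2
        w1, w2 = _onehot_pfm("WW"), _onehot_pfm("HH")
        seq = "HHAAAAWWAAHH"  # HH appears before and after WW
        placements, _ = locate_windows_ordered(seq, [w1, w2])
        (o1, _), (o2, _) = placements
        assert o1 == 6 and o2 == 10
        assert o1 < o2

    def test_joint_total_matches_exhaustive_scan(self, rng):
        w1, w2 = _onehot_pfm("HHW"), _onehot_pfm("CCA")
        bg = uniform_background()
        for _ in range(10):
            seq = "".join(rng.choice(list(AA_ALPHABET), size=30))
            placements, total = locate_windows_ordered(seq, [w1, w2])
            # exhaustive oracle over ordered non-overlapping placements
            best = -np.inf
            for o1 in range(len(seq) - 2):
                for o2 in range(o1 + 3, len(seq) - 2):
                    s = score_window(seq[o1 : o1 + 3], w1, bg) + score_window(
                        seq[o2 : o2 + 3], w2, bg
                    )
                    best = max(best, s)
            assert total == pytest.approx(best)

    def test_planted_windows_recovered(self, models, rng):
        from nrpsmith import GeneratorConfig, sample_downseq

        cfg = GeneratorConfig(seed=0)
        model = models[D.CE]
        hits = 0
        for _ in range(50):
            seq, offsets = sample_downseq(model, cfg, rng)
            placements, _ = model.scan(seq)
            hits += [o for o, _ in placements] == offsets
        assert hits >= 48  # signal strength 0.9 leaves room for rare misplacement


class TestModelTrainingAndSerialization:
    def test_train_recovers_planted_window_positions(self, rng):
        # build an "aligned block" of fixed-geometry sequences: three
        # conserved 12-mers at offsets 10, 60, 110 over random background
        rows = []
        motifs = ("HHWWHHWWHHWW", "CCCAAACCCAAA", "DEDEDEDEDEDE")
        for _ in range(20):
            row = list("".join(rng.choice(list(AA_ALPHABET), size=160)))
            for off, m in zip((10, 60, 110), motifs):
                row[off : off + 12] = m
            rows.append("".join(row))
        model = train_model(AlignedBlock(D.CE, rows), window_len=12)
        consensi = [pfm.consensus() for pfm in model.window_pfms]
        assert consensi == list(motifs)

    def test_json_round_trip(self, models, tmp_path):
        path = tmp_path / "models.json"
        save_models(models, path)
        loaded = load_models(path)
        assert set(loaded) == set(models)
        for k in models:
            np.testing.assert_allclose(
                loaded[k].window_pfms[0].freqs, models[k].window_pfms[0].freqs
            )

    def test_window_count_per_subtype_enforced(self):
        with pytest.raises(ValueError, match="2 windows"):
            SignatureModel(D.CSTARTER, [("WL1", _onehot_pfm("AAAA"))] * 3)
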