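import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crebox import (
    MotifAlignment,
    build_pfm,
    build_weight_matrix,
    consensus_call,
    score_quantile,
    score_window,
)
from crebox.motif_model import (
    best_window,
    read_jaspar_pfm,
    read_log_odds_tsv,
    write_jaspar_pfm,
    write_log_odds_tsv,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestAlignment:
    def test_lowercase_upcased(self):
        aln = MotifAlignment(["acgt", "ACGT"])
        assert aln.sequences == ("ACGT", "ACGT")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            MotifAlignment([])

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            MotifAlignment(["AC", "ACG"])

    def test_bad_character_named_with_position(self):
        with pytest.raises(ValueError, match=r"'s2'.*'U'.*position 3"):
            MotifAlignment(["ACGT", "ACUT"], ids=["s1", "s2"])


class TestBuildPfm:
    def test_unanimous_columns(self):
        pfm = build_pfm(MotifAlignment(["AC", "AC"]))
        assert pfm.counts[0, 0] == 2 and pfm.counts[1, 1] == 2
        assert pfm.counts.sum() == 4

    def test_regulon_central_positions(self, strong_seqs):
        # hand tally of the high-affinity set: position 7 is C in all but one
        # sequence (which has G), position 8 is G throughout
        pfm = build_pfm(MotifAlignment(strong_seqs))
        a, c, g, t = (pfm.counts[i] for i in range(4))
        assert c[6] == 30 and g[6] == 1
        assert g[7] == 31
        assert np.all(pfm.counts.sum(axis=0) == 31)

    @given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=5), min_size=1, max_size=20))
    @settings(deadline=None)
    def test_column_sums_conserve_set_size(self, seqs):
        pfm = build_pfm(MotifAlignment(seqs))
        assert np.all(pfm.counts.sum(axis=0) == len(seqs))
        assert np.allclose(pfm.probabilities.sum(axis=0), 1.0, atol=1e-9)


class TestWeightMatrix:
    def test_unanimous_column_two_bits(self, toy_matrix):
        assert toy_matrix.log_odds[0, 0] == pytest.approx(2.0)

    def test_split_column_log_odds(self):
        pfm = build_pfm(MotifAlignment(["AG", "AG", "CG", "CG"]), pseudocount=0.0)
        wm = build_weight_matrix(pfm)
        assert wm.log_odds[0, 0] == pytest.approx(1.0)  # log2(0.5/0.25)
        assert np.isneginf(wm.log_odds[2, 0])  # G absent, pseudocount 0

    def test_pseudocount_probabilities(self):
        pfm = build_pfm(MotifAlignment(["AG", "AG", "CG", "CG"]), pseudocount=1.0)
        # independent re-tally: (counts + 1) / (4 + 4)
        expect = (pfm.counts + 1.0) / 8.0
        assert np.allclose(pfm.probabilities, expect)

    def test_bad_background(self, toy_matrix):
        pfm = build_pfm(MotifAlignment(["AC"]))
        with pytest.raises(ValueError, match="positive"):
            build_weight_matrix(pfm, background=[0.5, 0.5, 0.0, 0.0])
        with pytest.raises(ValueError, match="sum to 1"):
            build_weight_matrix(pfm, background=[0.3, 0.3, 0.3, 0.3])

    def test_negative_pseudocount(self):
        pfm = build_pfm(MotifAlignment(["AC"]))
        with pytest.raises(ValueError, match="pseudocount"):
            build_weight_matrix(pfm, pseudocount=-0.5)


class TestConsensus:
    def test_unanimous(self):
        pfm = build_pfm(MotifAlignment(["AC", "AC"]))
        assert consensus_call(pfm) == "AC"

    def test_group_discriminating_positions(self, strong_seqs, weak_seqs):
        """Position 6 separates the groups (G vs R), as does 14 (A vs W)."""
        strong = consensus_call(build_pfm(MotifAlignment(strong_seqs)))
        weak = consensus_call(build_pfm(MotifAlignment(weak_seqs)))
        assert strong[5] == "G" and weak[5] == "R"
        assert strong[13] == "A" and weak[13] == "W"

    def test_threshold_validation(self):
        pfm = build_pfm(MotifAlignment(["AC"]))
        with pytest.raises(ValueError):
            consensus_call(pfm, theta_single=0.5)
        with pytest.raises(ValueError):
            consensus_call(pfm, theta_pair=1.2)

    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=4), min_size=1, max_size=8),
           st.integers(min_value=2, max_value=4))
    @settings(deadline=None)
    def test_idempotent_under_duplication(self, seqs, k):
        pfm1 = build_pfm(MotifAlignment(seqs))
        pfm2 = build_pfm(MotifAlignment(seqs * k))
        assert consensus_call(pfm1) == consensus_call(pfm2)


class TestScoreWindow:
    def test_toy_scores(self, toy_matrix):
        assert score_window(toy_matrix, "AC") == pytest.approx(4.0)
        assert np.isneginf(score_window(toy_matrix, "AA"))

    def test_width_mismatch(self, toy_matrix):
        with pytest.raises(ValueError, match="width"):
            score_window(toy_matrix, "ACG")

    def test_ambiguous_base_sentinel(self, toy_matrix):
        assert score_window(toy_matrix, "AN") is None

    @pytest.mark.parametrize("width", [3, 5, 7])
    def test_best_window_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        seqs = ["".join(rng.choice(list("ACGT"), width)) for _ in range(6)]
        wm = build_weight_matrix(build_pfm(MotifAlignment(seqs)))
        brute_best = max(
            ("".join(w) for w in itertools.product("ACGT", repeat=width)),
            key=lambda w: score_window(wm, w),
        )
        assert score_window(wm, best_window(wm)) == pytest.approx(
            score_window(wm, brute_best)
        )


class TestScoreQuantile:
    def test_matches_monte_carlo(self):
        """Exact convolution quantile vs empirical quantile of sampled sites."""
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(10)]
        wm = build_weight_matrix(build_pfm(MotifAlignment(seqs)))
        p = wm.probabilities
        draws = np.array([
            sum(wm.log_odds[rng.choice(4, p=p[:, j]), j] for j in range(6))
            for _ in range(20000)
        ])
        for q in (0.01, 0.1, 0.5):
            exact = score_quantile(wm, q)
            assert abs((draws < exact).mean() - q) < 0.02

    def test_fnr_bound_on_training_set(self, matrices, scan_cutoff, strong_seqs, weak_seqs):
        """At the calibrated cutoff nearly all real sites keep their score."""
        passed = [
            score_window(matrices["combined"], s) >= scan_cutoff
            for s in strong_seqs + weak_seqs
        ]
        assert np.mean(passed) >= 0.95


class TestMatrixIO:
    def test_jaspar_round_trip(self, tmp_path, strong_seqs):
        pfm = build_pfm(MotifAlignment(strong_seqs))
        path = tmp_path / "m.jaspar"
        write_jaspar_pfm(pfm, path)
        back = read_jaspar_pfm(path)
        assert np.array_equal(back.counts, pfm.counts)
        assert back.n_sequences == pfm.n_sequences

    def test_log_odds_round_trip(self, tmp_path, matrices):
        path = tmp_path / "lo.tsv"
        write_log_odds_tsv(matrices["combined"], path)
        assert np.array_equal(read_log_odds_tsv(path), matrices["combined"].log_odds)
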