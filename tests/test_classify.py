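import math

import numpy as np
import pandas as pd
import pytest

from oracles import percent_bruteforce
from promarch.classify import (PromoterAnchor, apply_thresholds, assign_class,
                               cage_tpm, count_motif_occurrences,
                               kmeans_overview, logodds_score, percent_score,
                               score_promoters, select_prototypes,
                               sense_sequence)
from promarch.genomic_io import Genome, StrandedBaseSignal
from promarch.pwm import PWM, default_pwms, default_windows, read_pwms, write_pwms

TWO_POS = PWM("toy", np.array([[0.7, 0.1, 0.1, 0.1],
                               [0.1, 0.1, 0.1, 0.7]]))  # consensus AT


class TestLogOdds:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("flat", np.full((3, 4), 0.25))
        assert logodds_score("ACG", pwm) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert logodds_score("AT", TWO_POS) == pytest.approx(2 * math.log2(2.8))

    def test_n_contributes_zero(self):
        assert logodds_score("NN", TWO_POS) == 0.0
        assert logodds_score("NT", TWO_POS) == pytest.approx(math.log2(2.8))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            logodds_score("ACT", TWO_POS)


class TestPercentScore:
    def test_consensus_scores_100(self):
        pct, off = percent_score("GGATGG", 2, TWO_POS, (0, 2))
        assert pct == pytest.approx(100.0)
        assert off == 0

    def test_anti_consensus_scores_0(self):
        # per-position minimal bases everywhere in the window
        pct, _ = percent_score("CCCCCC", 2, TWO_POS, (0, 2))
        assert pct == pytest.approx(0.0)

    def test_midpoint_sequence(self):
        # one match + one mismatch sits exactly between the extremes
        pct, _ = percent_score("AC", 0, TWO_POS, (0, 0))
        assert pct == pytest.approx(50.0)

    def test_matches_bruteforce_on_random_pwms(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            L = int(rng.integers(2, 5))
            probs = rng.dirichlet(np.full(4, 0.5), size=L)
            probs = np.clip(probs, 1e-3, None)
            probs /= probs.sum(axis=1, keepdims=True)
            pwm = PWM("r", probs)
            seq = "".join(rng.choice(list("ACGT"), 12))
            window = (0, 12 - L)
            got, off = percent_score(seq, 0, pwm, window)
            want, want_off = percent_bruteforce(
                seq, 0, probs.tolist(), [0.25] * 4, window)
            assert got == pytest.approx(want, abs=1e-9)
            assert off == want_off

    def test_window_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_score("ACGT", 0, TWO_POS, (-2, -1))

    def test_occurrence_count(self):
        # toy consensus AT occurs at offsets 0 and 3
        seq = "ATGAT"
        assert count_motif_occurrences(seq, 0, TWO_POS, (0, 3), 99.0) == 2
        assert count_motif_occurrences(seq, 0, TWO_POS, (0, 2), 99.0) == 1


class TestSenseSequence:
    def test_minus_strand_is_reverse_complement(self):
        g = Genome({"c": "AACGTTGCAA"})
        # + strand around tss=4: offsets -2..+2
        assert sense_sequence(g, "c", 4, "+", 2, 2) == "CGTTG"
        # - strand tss=5: sense reads downstream toward lower coordinates
        assert sense_sequence(g, "c", 5, "-", 2, 2) == "GCAAC"


class TestThresholdFlags:
    def test_strictly_greater_semantics(self):
        pct = pd.DataFrame({"TATA": [90.0, 90.1], "DRE": [98.5, 1.0]},
                           index=["p1", "p2"])
        flags = apply_thresholds(pct, {"TATA": 90.0, "DRE": 98.0})
        assert flags.loc["p1", "TATA"] == False  # noqa: E712 — exact boundary
        assert flags.loc["p2", "TATA"] == True   # noqa: E712
        assert flags.loc["p1", "DRE"] == True    # noqa: E712

    def test_missing_motif_rejected(self):
        with pytest.raises(ValueError, match="lacks"):
            apply_thresholds(pd.DataFrame({"TATA": [50.0]}), {"INR": 95.0})


class TestClassAssignment:
    @pytest.mark.parametrize("fired,expected", [
        ({"TATA", "INR"}, "TATA"),
        ({"TCT", "TATA"}, "TCT"),
        ({"DPE", "INR"}, "DPE"),
        ({"Ohler6"}, "Ohler1/6"),
        ({"Ohler1", "DRE"}, "DRE"),
        (set(), "other"),
    ])
    def test_precedence(self, fired, expected):
        motifs = ["TATA", "INR", "DPE", "TCT", "DRE", "Ohler1", "Ohler6"]
        flags = pd.DataFrame({m: [m in fired] for m in motifs}, index=["p"])
        assert assign_class(flags)["p"] == expected


class TestKmeans:
    def test_separated_blocks_recovered(self):
        rng = np.random.default_rng(0)
        block1 = rng.normal(90, 1, (20, 3))
        block2 = rng.normal(10, 1, (20, 3))
        df = pd.DataFrame(np.vstack([block1, block2]))
        labels, centers = kmeans_overview(df, k=2, seed=1)
        assert labels.iloc[:20].nunique() == 1
        assert labels.iloc[20:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_single_cluster_mean(self):
        df = pd.DataFrame([[0.0, 10.0], [2.0, 20.0]])
        _, centers = kmeans_overview(df, k=1, seed=0)
        assert centers.iloc[0].tolist() == pytest.approx([1.0, 15.0])

    def test_k_exceeding_n_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kmeans_overview(df, k=2)


class TestPrototypes:
    def _scores(self, **over):
        base = {"TATA": 50.0, "INR": 50.0, "DPE": 50.0, "MTE": 10.0,
                "TCT": 10.0, "DRE": 10.0, "Ohler1": 10.0, "Ohler6": 10.0,
                "Ohler7": 10.0}
        base.update(over)
        return pd.DataFrame(base, index=["p"])

    def test_tata_prototype_selected(self):
        sel = select_prototypes(self._scores(TATA=96.0, DPE=50.0),
                                pd.Series({"p": True}))
        assert sel["TATA"] == ["p"]

    def test_forbidden_motif_rejects(self):
        sel = select_prototypes(self._scores(TATA=96.0, DPE=92.0),
                                pd.Series({"p": True}))
        assert sel["TATA"] == []

    def test_inactive_rejected_regardless_of_scores(self):
        sel = select_prototypes(self._scores(TATA=99.0), pd.Series({"p": False}))
        assert sel["TATA"] == []

    def test_perfect_match_rule_is_inclusive(self):
        sel = select_prototypes(self._scores(DRE=100.0, TATA=10.0, INR=10.0,
                                             DPE=10.0),
                                pd.Series({"p": True}))
        assert sel["DRE"] == ["p"]

    def test_unknown_motif_in_rule_rejected(self):
        from promarch.classify import PrototypeRule
        with pytest.raises(ValueError, match="unknown motif"):
            select_prototypes(self._scores(), pd.Series({"p": True}),
                              [PrototypeRule("x", [("NOPE", 50.0)])])


class TestScorePromotersAndActivity:
    def test_embedded_consensus_found_on_both_strands(self):
        pwms = {"TATA": default_pwms()["TATA"]}
        windows = {"TATA": default_windows()["TATA"]}
        # TSS at 140, motif instance starting at sense offset -31
        core = "A" * 109 + "CTATAAAAA" + "A" * 109
        g = Genome({"cp": core, "cm": core.translate(
            str.maketrans("ACGT", "TGCA"))[::-1]})
        plus = PromoterAnchor("pp", "cp", 140, "+")
        minus = PromoterAnchor("pm", "cm", len(core) - 1 - 140, "-")
        scores = score_promoters(g, [plus, minus], pwms, windows)
        assert scores.loc["pp", ("percent", "TATA")] == pytest.approx(100.0)
        assert scores.loc["pm", ("percent", "TATA")] == pytest.approx(100.0)
        assert scores.loc["pp", ("offset", "TATA")] == -31

    def test_tpm_counts_window_per_million(self):
        sig = StrandedBaseSignal()
        sig.add("c", "+", 1000, 10)
        sig.add("c", "+", 5000, 990)   # outside the +-50 window
        for i in range(999):
            sig.add("c", "+", 8000 + i, 1000)
        tpm = cage_tpm(sig, [PromoterAnchor("p", "c", 1000, "+")], flank=50)
        assert tpm["p"] == pytest.approx(10 / sig.total() * 1e6)


def test_pwm_text_roundtrip(tmp_path):
    pwms = default_pwms()
    write_pwms(pwms, tmp_path / "pwms.txt")
    back = read_pwms(tmp_path / "pwms.txt")
    assert set(back) == set(pwms)
    for name in pwms:
        np.testing.assert_allclose(back[name].probs, pwms[name].probs)
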