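import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from promarch.depletion import (CountMatrix, bh_fdr, call_downregulated,
                                candidate_intermediaries, chip_zscore,
                                exact_ratio_test, fisher_motif_enrichment,
                                library_size_factors, spike_size_factors,
                                _fisher_two_sided)


def make_matrix(counts: dict, spikes, conditions=("control", "depleted")):
    samples = pd.DataFrame({
        "condition": [conditions[0], conditions[1]],
        "replicate": [1, 1],
        "spike_reads": spikes,
        "reference_reads": [1_000_000, 1_000_000],
    }, index=list(counts))
    return CountMatrix(pd.DataFrame(counts), samples)


class TestCountMatrix:
    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(pd.DataFrame({"a": [1]}),
                        pd.DataFrame({"condition": ["control"],
                                      "spike_reads": [1],
                                      "reference_reads": [1]}, index=["b"]))

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="depleted"):
            samples = pd.DataFrame({"condition": ["control"], "replicate": [1],
                                    "spike_reads": [10], "reference_reads": [10]},
                                   index=["s1"])
            CountMatrix(pd.DataFrame({"s1": [1]}), samples)

    def test_tsv_roundtrip(self, tmp_path):
        cm = make_matrix({"s1": [5, 0], "s2": [2, 9]}, [100, 200])
        cm.write_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountMatrix.read_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, cm.counts, check_names=False)


class TestSizeFactors:
    def test_equal_spikes_give_unit_factors(self):
        f = spike_size_factors(pd.Series([1e4, 1e4], index=["a", "b"]))
        assert f.tolist() == pytest.approx([1.0, 1.0])

    def test_fourfold_spike_difference(self):
        f = spike_size_factors(pd.Series([1e4, 4e4], index=["a", "b"]))
        assert f.tolist() == pytest.approx([0.5, 2.0])
        # equal raw counts become a 4-fold normalized difference
        norm = 100 / f
        assert np.log2(norm["b"] / norm["a"]) == pytest.approx(-2.0)

    def test_geometric_mean_is_one(self):
        f = spike_size_factors(pd.Series([3.0, 7.0, 11.0, 500.0]))
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_spike_rejected(self):
        with pytest.raises(ValueError):
            spike_size_factors(pd.Series([0, 100]))

    def test_library_factors_track_totals(self):
        counts = pd.DataFrame({"a": [10, 10], "b": [40, 40]})
        f = library_size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(4.0)


class TestExactRatioTest:
    def test_modal_outcome_has_p_one(self):
        assert exact_ratio_test(100, 100, 2.0, 2.0) == pytest.approx(1.0)

    def test_extreme_split_tail(self):
        assert exact_ratio_test(20, 0, 2.0, 2.0) == pytest.approx(
            2 * 0.5 ** 20, rel=1e-9)

    def test_untestable_returns_nan(self):
        assert math.isnan(exact_ratio_test(0, 0, 2.0, 2.0))

    def test_matches_rational_enumeration(self):
        cases = [(3, 17, 2.0, 2.0), (40, 9, 3.0, 2.0), (250, 250, 2.0, 2.0),
                 (0, 12, 1.0, 2.5), (123, 45, 2.0, 1.0)]
        for c, t, fc, fd in cases:
            pi0 = fd / (fc + fd)
            want = oracles.binom_two_sided_oracle(c, t, pi0)
            assert exact_ratio_test(c, t, fc, fd) == pytest.approx(want, abs=1e-12)


class TestBH:
    def test_step_up_examples(self):
        assert bh_fdr(pd.Series([0.01, 0.02, 0.03])).tolist() == \
            pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr(pd.Series([0.2])).tolist() == [0.2]
        assert bh_fdr(pd.Series([], dtype=float)).empty

    def test_nan_passthrough(self):
        q = bh_fdr(pd.Series([0.01, np.nan, 0.5]))
        assert math.isnan(q.iloc[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(pd.Series([1.5]))


class TestFisher:
    def test_hand_table(self):
        p = _fisher_two_sided(6, 4, 4, 86)
        want = oracles.fisher_two_sided_oracle(6, 4, 4, 86)
        assert p == pytest.approx(want, abs=1e-12)
        sp = stats.fisher_exact([[6, 4], [4, 86]], alternative="two-sided")[1]
        assert p == pytest.approx(sp, rel=1e-9)

    def test_enrichment_results(self):
        down = {f"d{i}" for i in range(10)}
        rest = {f"r{i}" for i in range(90)}
        flags = pd.DataFrame(
            {"M": [i < 6 for i in range(10)] + [i < 4 for i in range(90)]},
            index=[f"d{i}" for i in range(10)] + [f"r{i}" for i in range(90)])
        (res,) = fisher_motif_enrichment(down, down | rest, flags)
        assert (res.a, res.b, res.c, res.d) == (6, 4, 4, 86)
        assert res.odds_ratio == pytest.approx(32.25)
        assert res.log2_odds_ratio == pytest.approx(math.log2(32.25), abs=1e-6)

    def test_proportional_table_is_null(self):
        p = _fisher_two_sided(5, 5, 50, 50)
        assert p == pytest.approx(1.0)

    def test_empty_down_set_rejected(self):
        with pytest.raises(ValueError):
            fisher_motif_enrichment(set(), {"a"}, pd.DataFrame({"M": [True]},
                                                               index=["a"]))

    def test_down_outside_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_motif_enrichment({"x"}, {"a"},
                                    pd.DataFrame({"M": [True]}, index=["a"]))


class TestCallDownregulated:
    def _matrix(self):
        genes = ["strong_down", "mild_down", "tiny", "flat"]
        counts = pd.DataFrame({
            "control_1": [2000, 1200, 3, 1000],
            "control_2": [2050, 1180, 2, 1010],
            "depleted_1": [500, 1000, 1, 995],
            "depleted_2": [510, 990, 1, 1020],
        }, index=genes)
        samples = pd.DataFrame({
            "condition": ["control", "control", "depleted", "depleted"],
            "replicate": [1, 2, 1, 2],
            "spike_reads": [1000, 1000, 1000, 1000],
            "reference_reads": [1e6] * 4,
        }, index=counts.columns)
        return CountMatrix(counts, samples)

    def test_threshold_logic(self):
        cm = self._matrix()
        factors = pd.Series(1.0, index=cm.counts.columns)
        de = call_downregulated(cm, factors)
        assert bool(de.loc["strong_down", "down"])
        assert not bool(de.loc["mild_down", "down"])      # fails fold threshold
        assert not bool(de.loc["tiny", "down"])           # not testable
        assert not bool(de.loc["tiny", "testable"])
        assert not bool(de.loc["flat", "down"])
        assert de.loc["strong_down", "log2fc"] == pytest.approx(-2.0, abs=0.1)

    def test_down_implies_thresholds(self):
        cm = self._matrix()
        factors = pd.Series(1.0, index=cm.counts.columns)
        de = call_downregulated(cm, factors)
        flagged = de[de["down"]]
        assert (flagged["log2fc"] <= -math.log2(1.5)).all()
        assert (flagged["q"] < 0.05).all()


class TestChipZscore:
    def test_hand_class_means(self):
        classes = ["TATA", "DPE", "INR", "TCT", "DRE", "Ohler1/6"]
        chip = pd.DataFrame({"TBP": [2.0, 1.0, 1.0, 1.0, 1.0, 1.0]},
                            index=[f"p{i}" for i in range(6)])
        nascent = pd.Series(1.0, index=chip.index)
        lengths = pd.Series(1.0, index=chip.index)
        labels = pd.Series(classes, index=chip.index)
        z, n_excluded = chip_zscore(chip, nascent, lengths, labels)
        assert n_excluded == 0
        assert z.loc["TATA", "TBP"] == pytest.approx(math.sqrt(5))
        assert z.loc["DPE", "TBP"] == pytest.approx(-1 / math.sqrt(5))

    def test_zero_nascent_excluded(self):
        chip = pd.DataFrame({"F": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        nascent = pd.Series([1.0, 0.0, 2.0], index=chip.index)
        lengths = pd.Series(1.0, index=chip.index)
        labels = pd.Series(["x", "y", "z"], index=chip.index)
        _, n_excluded = chip_zscore(chip, nascent, lengths, labels)
        assert n_excluded == 1


def test_candidate_intermediaries():
    bound = {"dev": {"A", "B", "C"}, "hk": {"X"}}
    out = candidate_intermediaries(bound, {"B", "C", "D"})
    assert out == {"dev": {"B", "C"}, "hk": set()}
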