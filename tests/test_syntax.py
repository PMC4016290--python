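"""Sequence statistics, PM/MM fitting and generation, closed forms, distances."""

import numpy as np
import pytest

from usvsong import (
    builtin_profiles,
    compare_models,
    expected_ngrams,
    expected_repeats,
    fit_mm,
    fit_pm,
    generate_mm,
    generate_pm,
    model_distance,
    profile_syntax_model,
    sequence_stats,
)
from usvsong.profiles import TYPE13
from usvsong.syntax import SyntaxModel, read_sequences, write_sequences

AB = ("A", "B")


class TestSequenceStats:
    def test_doublets_of_abab(self):
        st = sequence_stats([["A", "B", "A", "B"]], alphabet=AB)
        assert st.doublet_freqs[("A", "B")] == pytest.approx(2 / 3)
        assert st.doublet_freqs[("B", "A")] == pytest.approx(1 / 3)

    def test_single_type_run(self):
        st = sequence_stats([["A", "A", "A"]], alphabet=AB)
        assert st.usage == {"A": 1.0}
        assert st.repeat_dist["A"] == {3: 1.0}

    def test_boundary_distributions(self):
        st = sequence_stats([["A"], ["B"]], alphabet=AB)
        assert st.start == {"A": 0.5, "B": 0.5}
        assert st.stop == {"A": 0.5, "B": 0.5}

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            sequence_stats([["A", "Z"]], alphabet=AB)

    def test_repeat_distributions_normalised_per_type(self):
        st = sequence_stats([["A", "A", "B", "A"]], alphabet=AB)
        for dist in st.repeat_dist.values():
            assert sum(dist.values()) == pytest.approx(1.0)


class TestFitPm:
    def test_uniform_two_types(self):
        st = sequence_stats([["A", "B"], ["B", "A"]], alphabet=AB)
        np.testing.assert_allclose(fit_pm(st), [0.5, 0.5])

    def test_degenerate_single_type(self):
        st = sequence_stats([["A", "A"]], alphabet=AB)
        np.testing.assert_allclose(fit_pm(st), [1.0, 0.0])

    def test_gerf_table_usage(self):
        prof = builtin_profiles()["GER/f"]
        assert prof.type_probs[TYPE13.index("SUP")] == pytest.approx(0.33 / 0.99, abs=1e-9)


class TestFitMm:
    def test_hand_counted_example(self):
        mm = fit_mm([["A", "A", "B"], ["A", "B"]], alphabet=AB)
        ia, ib = 0, 1
        assert mm.start[ia] == 1.0
        assert mm.transition[ia, ia] == pytest.approx(1 / 3)
        assert mm.transition[ia, ib] == pytest.approx(2 / 3)
        assert mm.stop[ia] == 0.0
        assert mm.stop[ib] == 1.0

    def test_single_singleton_sequence(self):
        mm = fit_mm([["A"]], alphabet=AB)
        assert mm.start[0] == 1.0 and mm.stop[0] == 1.0
        assert mm.transition.sum() == 0.0
        assert mm.unobserved == ("B",)

    def test_row_sums_plus_stop_equal_one(self):
        rng = np.random.default_rng(0)
        seqs = [[str(c) for c in rng.integers(0, 3, size=rng.integers(1, 9))]
                for _ in range(50)]
        mm = fit_mm(seqs, alphabet=("0", "1", "2"))
        rowtot = mm.transition.sum(axis=1) + mm.stop
        np.testing.assert_allclose(rowtot, 1.0)


class TestGenerate:
    def test_pm_degenerate_vector(self):
        seqs = generate_pm(np.array([1.0, 0.0]), 20, [3], np.random.default_rng(0),
                           alphabet=AB)
        assert all(s == ["A", "A", "A"] for s in seqs)

    def test_pm_seeded_run_repeats(self):
        p = builtin_profiles()["FRA/f"].type_probs
        a = generate_pm(p, 50, np.arange(1, 20), np.random.default_rng(5))
        b = generate_pm(p, 50, np.arange(1, 20), np.random.default_rng(5))
        assert a == b

    def test_mm_all_stop_gives_singletons(self):
        k = len(AB)
        m = SyntaxModel(alphabet=AB, start=np.array([1.0, 0.0]),
                        transition=np.zeros((k, k)), stop=np.ones(k))
        seqs = generate_mm(m, 50, np.random.default_rng(1))
        assert all(s == ["A"] for s in seqs)

    def test_mm_never_stopping_hits_cap_of_20(self):
        m = SyntaxModel(alphabet=AB, start=np.array([1.0, 0.0]),
                        transition=np.array([[1.0, 0.0], [0.0, 1.0]]),
                        stop=np.zeros(2))
        seqs = generate_mm(m, 20, np.random.default_rng(2))
        assert all(s == ["A"] * 20 for s in seqs)

    def test_all_lengths_within_1_to_20(self):
        model = profile_syntax_model(builtin_profiles()["GER/f"])
        seqs = generate_mm(model, 2000, np.random.default_rng(3))
        lens = {len(s) for s in seqs}
        assert min(lens) >= 1 and max(lens) <= 20

    def test_mm_parameter_recovery(self):
        """fit_mm(generate_mm(M)) recovers M's entries within 3 binomial SEs.

        With ~200 parameters checked simultaneously a per-entry 3-SE bound is
        expected to miss ~0.5 entries by chance even for a perfect fitter, so
        at least 97% of entries must be within 3 SE and every entry within
        6 SE (the length cap at 20 additionally censors a ~1% sliver of
        transitions).
        """
        model = profile_syntax_model(builtin_profiles()["FRA/f"])
        seqs = generate_mm(model, 10000, np.random.default_rng(7))
        fitted = fit_mm(seqs)
        occ = np.zeros(len(TYPE13))
        for s in seqs:
            for c in s:
                occ[TYPE13.index(c)] += 1
        # the SE floor absorbs the forced terminals of cap-censored sequences,
        # which hit entries whose binomial SE is zero or near zero
        floor = 0.012
        z = []
        se_start = np.sqrt(model.start * (1 - model.start) / len(seqs))
        z.extend(np.abs(fitted.start - model.start) / np.maximum(se_start, floor))
        for i in np.flatnonzero(occ > 50):
            se = max(np.sqrt(model.stop[i] * (1 - model.stop[i]) / occ[i]), floor)
            z.append(abs(fitted.stop[i] - model.stop[i]) / se)
            se_t = np.maximum(
                np.sqrt(model.transition[i] * (1 - model.transition[i]) / occ[i]), floor)
            z.extend(np.abs(fitted.transition[i] - model.transition[i]) / se_t)
        z = np.asarray(z)
        assert np.mean(z <= 3.0) >= 0.97
        assert z.max() < 6.0


class TestExpectedRepeats:
    def test_pm_closed_form(self):
        dist = expected_repeats("PM", 0.5, n_max=20)
        w = 0.5 ** np.arange(1, 21)
        np.testing.assert_allclose([dist[n] for n in range(1, 21)], w / w.sum())
        assert dist[2] / dist[1] == pytest.approx(0.5)

    def test_mm_closed_form(self):
        dist = expected_repeats("MM", 0.2, n_max=20)
        # P_n = r^(n-1)(1-r): truncation at 20 renormalises negligibly
        assert dist[1] == pytest.approx(0.8, abs=1e-12)
        assert dist[2] == pytest.approx(0.16, abs=1e-12)

    @pytest.mark.parametrize("kind,param", [("PM", 0.7), ("MM", 0.6)])
    def test_strictly_decreasing_no_interior_mode(self, kind, param):
        dist = expected_repeats(kind, param)
        vals = [dist[n] for n in sorted(dist)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_distribution_sums_to_one(self):
        for kind, param in (("PM", 0.9), ("MM", 0.95)):
            assert sum(expected_repeats(kind, param).values()) == pytest.approx(1.0)

    def test_degenerate_mm_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            expected_repeats("MM", 1.0)


class TestExpectedNgrams:
    def test_pm_triplet_is_product_of_marginals(self):
        p = builtin_profiles()["GER/f"].type_probs
        trips = expected_ngrams(p, order=3)
        i = {t: p[TYPE13.index(t)] for t in ("SDN", "TDU", "TRS")}
        assert trips[("SDN", "TDU", "TRS")] == pytest.approx(
            i["SDN"] * i["TDU"] * i["TRS"])

    def test_pm_uniform_doublets(self):
        d = expected_ngrams(np.array([0.5, 0.5]), order=2, alphabet=AB)
        assert all(v == pytest.approx(0.25) for v in d.values())

    def test_mm_certain_transition(self):
        m = SyntaxModel(alphabet=AB, start=np.array([1.0, 0.0]),
                        transition=np.array([[0.0, 0.9], [0.0, 0.0]]),
                        stop=np.array([0.1, 1.0]))
        d = expected_ngrams(m, order=2)
        assert d[("A", "B")] == pytest.approx(1.0)  # the only possible doublet


class TestModelDistance:
    def test_identical_distributions_zero(self):
        st = sequence_stats([["A", "B", "A"]], alphabet=AB)
        assert model_distance(st, st, "doublets") == 0.0
        assert model_distance(st, st, "repeats") == 0.0

    def test_hand_computed_repeat_distance(self):
        obs = {"A": {1: 1.0}}
        exp = {"A": {1: 0.6, 2: 0.4}}
        assert model_distance(obs, exp, "repeats") == pytest.approx(0.8)

    def test_symmetry(self):
        a = {("A", "B"): 0.7, ("B", "A"): 0.3}
        b = {("A", "B"): 0.2, ("A", "A"): 0.8}
        assert model_distance(a, b, "doublets") == model_distance(b, a, "doublets")


def _second_order_corpus(n, rng):
    """Alternating-pair chain: the next type depends on the two previous ones."""
    seqs = []
    for _ in range(n):
        seq = list(rng.choice(["A", "B"], size=2))
        while len(seq) < 12:
            nxt = seq[-2]  # period-two structure invisible to a first-order chain
            if rng.random() < 0.1:
                nxt = "C"
            seq.append(nxt)
        seqs.append(seq)
    return seqs


class TestCompareModels:
    def test_mm_generated_corpus_favours_mm_doublets(self):
        model = profile_syntax_model(builtin_profiles()["GER/f"])
        seqs = generate_mm(model, 3000, np.random.default_rng(11))
        rep = compare_models(seqs, n_generated=5000, rng=np.random.default_rng(12))
        fits = rep["fits"]
        assert fits["MM"].d_dupl < fits["PM"].d_dupl
        assert fits["MM"].d_dupl < 0.1

    def test_second_order_corpus_defeats_mm_triplets(self):
        seqs = _second_order_corpus(1500, np.random.default_rng(13))
        rep = compare_models(seqs, n_generated=5000,
                             rng=np.random.default_rng(14), alphabet=("A", "B", "C"))
        fits = rep["fits"]
        assert fits["MM"].d_trip > fits["MM"].d_dupl

    def test_iid_corpus_makes_models_comparable(self):
        rng = np.random.default_rng(15)
        seqs = generate_pm(np.array([0.3, 0.7]), 3000, np.arange(1, 15), rng,
                           alphabet=AB)
        rep = compare_models(seqs, n_generated=5000,
                             rng=np.random.default_rng(16), alphabet=AB)
        fits = rep["fits"]
        assert abs(fits["MM"].d_dupl - fits["PM"].d_dupl) < 0.05


def test_sequence_file_round_trip(tmp_path):
    seqs = [["SUP", "SUP", "JED", "TDU"], ["SFL"]]
    p = tmp_path / "seqs.txt"
    write_sequences(seqs, p)
    assert read_sequences(p) == seqs


def test_model_json_round_trip(tmp_path):
    model = profile_syntax_model(builtin_profiles()["FRA/m"])
    p = tmp_path / "model.json"
    model.to_json(p)
    back = SyntaxModel.from_json(p)
    np.testing.assert_allclose(back.start, model.start)
    np.testing.assert_allclose(back.transition, model.transition)
    np.testing.assert_allclose(back.stop, model.stop)
    assert back.alphabet == model.alphabet
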