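"""#MSU predictors, covariates, OLS fits, bootstrap sweeps, pairing plans."""

import numpy as np
import pytest

from chunklex import (
    AoFPTable,
    count_msu_per_word,
    cross_corpus_pairing,
    delta_r2,
    fit_aofp_model,
    phonological_neighborhood,
)
from chunklex.chunk_selection import ChunkSet, MSURecord
from chunklex.corpus_io import PronLexicon
from chunklex.msu_regression import (
    COVARIATE_TERMS,
    MSU_TERM,
    NeighborhoodIndex,
    TargetWordFeatures,
    assemble_features,
    design_frame,
    sweep_regression,
    _fit,
)

from conftest import U, oracle_ols


def _msu(words, syll_prefix):
    words = tuple(words.split())
    return MSURecord(
        syllables=tuple(f"{syll_prefix}{i}" for i in range(max(2, len(words)))),
        words=words, frequency=2, source_corpora=frozenset({"A", "B"}),
    )


def _chunk_set(msus, metric="S"):
    return ChunkSet(metric=metric, size_N=len(msus), members=tuple(msus))


class TestCountMSU:
    def test_counts_distinct_types(self):
        msus = [_msu("throw the ball", "a"), _msu("ball ball pit", "b"),
                _msu("red ball", "c"), _msu("go home", "d"), _msu("big dog", "e")]
        counts = count_msu_per_word(["ball", "dog", "xyz"], _chunk_set(msus))
        assert counts == {"ball": 3, "dog": 1, "xyz": 0}

    def test_double_occurrence_counts_once(self):
        cs = _chunk_set([_msu("day by day", "x")])
        assert count_msu_per_word(["day"], cs) == {"day": 1}


class TestPhonologicalNeighborhood:
    def _lexicon(self):
        lex = PronLexicon()
        lex.add("cat", [["K", "AE", "T"]])
        lex.add("bat", [["B", "AE", "T"]])          # substitution
        lex.add("cats", [["K", "AE", "T", "S"]])    # addition
        lex.add("katt", [["K", "AE", "T"]])         # homophone
        lex.add("dog", [["D", "AO", "G"]])          # unrelated
        lex.add("at", [["AE", "T"]])                # deletion
        return lex

    def test_reference_fixture(self):
        lex = self._lexicon()
        assert phonological_neighborhood("cat", lex) == 4  # bat, cats, katt, at
        assert phonological_neighborhood("dog", lex) == 0

    def test_single_word_lexicon(self):
        lex = PronLexicon()
        lex.add("solo", [["S", "OW"], ["L", "OW"]])
        assert phonological_neighborhood("solo", lex) == 0

    def test_out_of_lexicon_rejected(self):
        with pytest.raises(KeyError):
            phonological_neighborhood("zebra", self._lexicon())

    def test_substitution_symmetry(self):
        lex = self._lexicon()
        idx = NeighborhoodIndex(lex)
        # cat ~ bat and bat ~ cat
        assert phonological_neighborhood("cat", lex, idx) >= 1
        assert phonological_neighborhood("bat", lex, idx) >= 1

    def test_index_matches_brute_force(self, small_bundle):
        lex = small_bundle.lexicon

        def brute(word):
            from chunklex.msu_regression import _edit_distance_le1

            p = lex.phonemes(word)
            return sum(1 for o in lex if o != word.lower()
                       and _edit_distance_le1(p, lex.phonemes(o)))

        idx = NeighborhoodIndex(lex)
        rng = np.random.default_rng(2)
        words = sorted(lex)
        for w in rng.choice(words, size=60, replace=False):
            assert idx.neighborhood(w) == brute(w)


def _features(n, rng, msu_counts=None):
    counts = msu_counts if msu_counts is not None else rng.poisson(2, n)
    return [
        TargetWordFeatures(
            word=f"w{i}", aofp=float(np.exp(rng.normal(1.0, 0.3))),
            msu_count=int(counts[i]), freq=int(rng.integers(1, 500)),
            concreteness=float(1 + 4 * rng.random()),
            n_syll=int(rng.integers(1, 4)),
            phon_neighbors=int(rng.poisson(1.5)),
        )
        for i in range(n)
    ]


class TestAssembleFeatures:
    def _world(self):
        lex = PronLexicon()
        for w in ("ball", "dog", "sun"):
            lex.add(w, [[w.upper()]])
        lex.add("cookie", [["K", "UH"], ["K", "IY"]])
        adult = [U("ball dog"), U("ball sun dog"), U("cookie")]
        aofp = AoFPTable({"ball": 2.0, "dog": 3.0, "cookie": 2.5, "sun": 4.0},
                         "corpus")
        cs = _chunk_set([_msu("ball dog", "a"), _msu("ball sun", "b")])
        con = {"ball": 4.5, "dog": 4.0, "cookie": 3.5}  # sun missing
        return lex, adult, aofp, cs, con

    def test_inner_join_and_values(self):
        lex, adult, aofp, cs, con = self._world()
        feats = assemble_features(aofp, cs, adult, lex, con)
        by_word = {f.word: f for f in feats}
        assert set(by_word) == {"ball", "dog", "cookie"}  # sun lacks Con
        assert by_word["ball"].freq == 2
        assert by_word["ball"].msu_count == 2
        assert by_word["dog"].msu_count == 1
        assert by_word["cookie"].msu_count == 0
        assert by_word["cookie"].n_syll == 2

    def test_join_is_order_invariant(self):
        lex, adult, aofp, cs, con = self._world()
        a = assemble_features(aofp, cs, adult, lex, con)
        b = assemble_features(aofp, cs, list(reversed(adult)), lex, con)
        assert a == b


class TestFit:
    def test_perfect_negative_fit(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, 400)
        feats = _features(400, rng, msu_counts=counts)
        x = np.log(counts + 1)
        z = (x - x.mean()) / x.std()
        # aofp = exp(-z) so that standardized log aofp = -z exactly
        feats = [
            TargetWordFeatures(f.word, float(np.exp(-z[i])), f.msu_count,
                               f.freq, f.concreteness, f.n_syll,
                               f.phon_neighbors)
            for i, f in enumerate(feats)
        ]
        fit = fit_aofp_model(feats, include_msu=True)
        assert fit.params[MSU_TERM] == pytest.approx(-1.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_outcome_gives_zero_effect(self):
        rng = np.random.default_rng(2)
        feats = _features(5000, rng)
        full = fit_aofp_model(feats, include_msu=True)
        base = fit_aofp_model(feats, include_msu=False)
        assert abs(full.params[MSU_TERM]) < 0.05
        assert delta_r2(full, base) == pytest.approx(0.0, abs=0.005)

    def test_six_row_fixture_matches_normal_equations(self):
        feats = [
            TargetWordFeatures("a", 2.0, 3, 10, 4.5, 1, 2),
            TargetWordFeatures("b", 2.5, 1, 40, 3.0, 2, 0),
            TargetWordFeatures("c", 3.5, 0, 5, 2.5, 1, 5),
            TargetWordFeatures("d", 1.5, 6, 200, 4.9, 3, 1),
            TargetWordFeatures("e", 4.0, 2, 17, 1.5, 2, 3),
            TargetWordFeatures("f", 2.2, 4, 80, 3.3, 1, 0),
            TargetWordFeatures("g", 3.1, 1, 33, 2.2, 2, 7),
            TargetWordFeatures("h", 1.9, 5, 120, 4.1, 1, 2),
        ]
        fit = fit_aofp_model(feats, include_msu=True)
        df = design_frame(feats)
        z = (df - df.mean()) / df.std(ddof=0)
        terms = [MSU_TERM, *COVARIATE_TERMS]
        beta, r2 = oracle_ols(z[terms].to_numpy(), z["log_aofp"].to_numpy())
        for t, b in zip(terms, beta):
            assert fit.params[t] == pytest.approx(b, abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_predictor_named(self):
        rng = np.random.default_rng(3)
        feats = [
            TargetWordFeatures(f.word, f.aofp, f.msu_count, f.freq,
                               f.concreteness, 2, f.phon_neighbors)
            for f in _features(50, rng)
        ]
        with pytest.raises(ValueError, match="log_nsyl"):
            fit_aofp_model(feats)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            fit_aofp_model(_features(5, rng))

    def test_nested_delta_r2_nonnegative(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            feats = _features(60, np.random.default_rng(seed))
            full = fit_aofp_model(feats, include_msu=True)
            base = fit_aofp_model(feats, include_msu=False)
            assert delta_r2(full, base) >= -1e-12

    def test_delta_r2_row_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        full = fit_aofp_model(_features(40, rng))
        base = fit_aofp_model(_features(30, rng), include_msu=False)
        with pytest.raises(ValueError):
            delta_r2(full, base)

    def test_planted_unique_variance_share(self):
        # aofp constructed so z(log #MSU+1) uniquely explains ~8% of variance
        rng = np.random.default_rng(7)
        n = 5000
        counts = rng.poisson(3, n)
        x = np.log(counts + 1)
        z = (x - x.mean()) / x.std()
        share = 0.08
        y = -np.sqrt(share) * z + rng.normal(0, np.sqrt(1 - share), n)
        feats = [
            TargetWordFeatures(f"w{i}", float(np.exp(1 + 0.25 * y[i])),
                               int(counts[i]), int(rng.integers(1, 500)),
                               float(1 + 4 * rng.random()),
                               int(rng.integers(1, 4)), int(rng.poisson(1.5)))
            for i in range(n)
        ]
        full = fit_aofp_model(feats, include_msu=True)
        base = fit_aofp_model(feats, include_msu=False)
        assert delta_r2(full, base) == pytest.approx(share, abs=0.02)


class TestSweep:
    def _cells(self, rng, n=300, slope=0.6):
        counts_s = rng.poisson(3, n)
        counts_f = rng.poisson(2, n)
        x = np.log(counts_s + 1)
        z = (x - x.mean()) / x.std()
        noise = rng.normal(0, np.sqrt(1 - slope**2), n)
        base = _features(n, rng)
        cells = {}
        for metric, counts in (("S", counts_s), ("F", counts_f)):
            cells[(metric, 100)] = [
                TargetWordFeatures(f.word, float(np.exp(1 + 0.3 * (-slope * z[i] + noise[i]))),
                                   int(counts[i]), f.freq, f.concreteness,
                                   f.n_syll, f.phon_neighbors)
                for i, f in enumerate(base)
            ]
        return cells

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(8)
        results, diffs = sweep_regression(self._cells(rng), n_resamples=100, seed=1)
        by_metric = {r.metric: r for r in results}
        assert by_metric["S"].beta_msu.hi < 0
        assert by_metric["F"].beta_msu.lo <= 0 <= by_metric["F"].beta_msu.hi
        (d,) = diffs
        assert d["pair"] == "S-F"
        assert d["beta_diff"].significant

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        cells = self._cells(rng, n=100)
        a = sweep_regression(cells, n_resamples=50, seed=5)
        b = sweep_regression(cells, n_resamples=50, seed=5)
        assert a == b

    def test_zero_noise_cell_has_zero_width_ci(self):
        rng = np.random.default_rng(10)
        n = 80
        counts = rng.poisson(3, n)
        x = np.log(counts + 1)
        z = (x - x.mean()) / x.std()
        feats = [
            TargetWordFeatures(f"w{i}", float(np.exp(-z[i])), int(counts[i]),
                               int(rng.integers(1, 100)),
                               float(1 + 4 * rng.random()),
                               int(rng.integers(1, 4)), int(rng.poisson(1)))
            for i in range(n)
        ]
        results, _ = sweep_regression({("S", 10): feats}, n_resamples=40, seed=2)
        (r,) = results
        assert r.beta_msu.lo == pytest.approx(-1.0, abs=1e-8)
        assert r.beta_msu.hi == pytest.approx(-1.0, abs=1e-8)
        assert r.r2_full == pytest.approx(1.0, abs=1e-10)
        # the baseline R² (hence ΔR²) still varies across resamples, since
        # the covariates explain chance-level shares of the outcome

    def test_tiny_cell_skipped(self):
        rng = np.random.default_rng(11)
        cells = {("S", 10): _features(4, rng), ("F", 10): _features(100, rng)}
        results, diffs = sweep_regression(cells, n_resamples=20, seed=0)
        assert [r.metric for r in results] == ["F"]
        assert diffs == []


class TestDegenerateN:
    def test_full_pool_counts_identical_across_metrics(self):
        rng = np.random.default_rng(12)
        msus = [_msu(f"w{int(rng.integers(20))} w{int(rng.integers(20))}", f"p{i}")
                for i in range(30)]
        from chunklex import rank_and_select

        targets = [f"w{i}" for i in range(20)]
        counts = {
            m: count_msu_per_word(targets, rank_and_select(msus, m, len(msus)))
            for m in ("S", "F")
        }
        assert counts["S"] == counts["F"]


class TestPairing:
    def test_two_corpora_and_cdi(self):
        plans = cross_corpus_pairing(["BE", "NA"], cdi_available=True)
        assert len(plans) == 3
        assert plans[0].predictor_corpora == ("BE",)
        assert plans[0].aofp_source == "NA"
        assert plans[1].predictor_corpora == ("NA",)
        assert plans[2].aofp_source == "cdi"
        assert plans[2].max_msu_child_age == 30.0
        assert plans[2].predictor_corpora == ("BE", "NA")

    def test_swapped_corpora_swap_plans(self):
        a = cross_corpus_pairing(["BE", "NA"])
        b = cross_corpus_pairing(["NA", "BE"])
        assert a[0].predictor_corpora == b[1].predictor_corpora
        assert a[0].aofp_source == b[1].aofp_source

    def test_single_corpus_without_cdi_rejected(self):
        with pytest.raises(ValueError):
            cross_corpus_pairing(["BE"], cdi_available=False)

    def test_single_corpus_with_cdi(self):
        plans = cross_corpus_pairing(["BE"], cdi_available=True)
        assert len(plans) == 1
        assert plans[0].aofp_source == "cdi"


def test_ols_oracle_on_random_fixtures():
    rng = np.random.default_rng(13)
    for _ in range(20):
        feats = _features(int(rng.integers(30, 120)), rng)
        df = design_frame(feats)
        z = (df - df.mean()) / df.std(ddof=0)
        terms = [MSU_TERM, *COVARIATE_TERMS]
        beta, r2 = oracle_ols(z[terms].to_numpy(), z["log_aofp"].to_numpy())
        fit = _fit(df, terms)
        for t, b in zip(terms, beta):
            assert fit.params[t] == pytest.approx(b, abs=1e-8)
        assert fit.r2 == pytest.approx(r2, abs=1e-8)
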