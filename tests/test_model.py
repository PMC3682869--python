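"""The fitted all-word analysis: engine consistency, determinism, ranking."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from wordbridge import (
    WordEnrichment,
    analyze_all_words,
    bridge_max_sf,
    count_occurrences,
    z_score,
)
from wordbridge.model import RESULT_COLUMNS


class TestFitTable:
    def test_columns_and_one_row_per_word(self, small_results):
        df = small_results.results
        assert list(df.columns) == RESULT_COLUMNS
        assert len(df) == 4**4 + 4**5
        assert df["word"].is_unique

    def test_sorted_by_z_with_lexicographic_tiebreak(self, small_results):
        df = small_results.results
        z = df["z"].to_numpy()
        assert np.all(np.diff(z) <= 1e-15)
        for _, grp in df.groupby("z", sort=False):
            words = grp["word"].tolist()
            assert words == sorted(words)
        assert df["rank"].tolist() == list(range(1, len(df) + 1))

    def test_planted_word_recovered_near_top(self, small_results, small_spec):
        row = small_results.word_row(small_spec.planted_word)
        assert row["rank"] <= 5
        assert row["direction"] == "down"
        assert row["es_index"] <= 2 * small_spec.n_top
        assert row["fdr"] < 0.05

    def test_occurrence_columns_match_direct_counting(self, small_results, small_dataset):
        rng = np.random.default_rng(0)
        words = rng.choice(small_results.results["word"].to_numpy(), size=8,
                           replace=False)
        for w in words:
            row = small_results.word_row(w)
            counts = [count_occurrences(s, w) for s in small_dataset.sequences]
            assert row["total_occurrences"] == sum(counts)
            assert row["n_genes_with_word"] == sum(c > 0 for c in counts)

    def test_fdr_matches_independent_bh(self, small_results):
        df = small_results.results
        _, expected, _, _ = multipletests(df["p_analytic"], method="fdr_bh")
        assert np.allclose(df["fdr"], expected, atol=1e-12)

    def test_absent_words_are_degenerate_neutral(self):
        """Words occurring in no gene carry no signal: p=1, z=0, D=0."""
        from wordbridge import build_ranked_dataset
        from wordbridge.synthetic import SyntheticSpec, generate_dataset

        spec = SyntheticSpec(n_genes=5, length_range=(40, 60),
                             planted_word=None, n_top=0, seed=30)
        seqs, ranks, _ = generate_dataset(spec)
        res = WordEnrichment(build_ranked_dataset(seqs, ranks), lengths=(6,)).fit()
        absent = res.results.query("n_genes_with_word == 0")
        assert len(absent) > 0
        assert (absent["z"] == 0).all()
        assert (absent["p_analytic"] == 1).all()
        assert (absent["D"] == 0).all()
        assert (absent["sigma"] == 0).all()


class TestEngineAgainstReferencePath:
    def test_engine_matches_per_word_scoring(self, small_results):
        """The vectorized engine reproduces the per-word reference path
        (scalar counting -> binomial -> running sum -> bridge p / Z)."""
        res = small_results
        u = res.model.dataset.u
        rng = np.random.default_rng(1)
        words = list(rng.choice(res.results["word"].to_numpy(), 6, replace=False))
        words += ["ACCAA"]  # include the planted word
        for w in words:
            prof = res.profile(w)
            row = res.word_row(w)
            assert prof.D == pytest.approx(row["D"], abs=1e-9)
            assert prof.sigma == pytest.approx(row["sigma"], abs=1e-12)
            assert prof.es_index == row["es_index"]
            assert prof.direction == row["direction"]
            if prof.degenerate:
                assert row["p_analytic"] == 1.0 and row["z"] == 0.0
            else:
                assert bridge_max_sf(prof.D, prof.sigma, u) == pytest.approx(
                    row["p_analytic"], rel=1e-9, abs=1e-300
                )
                assert z_score(prof.D, prof.sigma, u) == pytest.approx(
                    row["z"], rel=1e-9
                )

    def test_profile_conservation(self, small_results):
        prof = small_results.profile("ACCAA")
        assert prof.r[0] == 0.0
        assert abs(prof.r[-1]) < 1e-9
        assert small_results.diagnostics["max_abs_r_end"] < 1e-9


class TestDeterminism:
    def test_workers_do_not_change_output(self, small_dataset):
        r1 = WordEnrichment(small_dataset, lengths=(4, 5)).fit(workers=1)
        r2 = WordEnrichment(small_dataset, lengths=(4, 5)).fit(workers=3)
        assert r1.results.equals(r2.results)

    def test_refit_identical(self, small_dataset, small_results):
        again = WordEnrichment(small_dataset, lengths=(4, 5)).fit()
        assert again.results.equals(small_results.results)

    def test_analyze_all_words_wrapper(self, small_dataset, small_results):
        df = analyze_all_words(small_dataset, lengths=(4, 5))
        assert df.equals(small_results.results)


class TestValidationAndSummary:
    def test_lengths_must_exceed_order(self, small_dataset):
        with pytest.raises(ValueError, match="exceed"):
            WordEnrichment(small_dataset, lengths=(2,), order=2)

    def test_lengths_bounds(self, small_dataset):
        with pytest.raises(ValueError):
            WordEnrichment(small_dataset, lengths=(11,))
        with pytest.raises(ValueError):
            WordEnrichment(small_dataset, lengths=())

    def test_positive_alpha_and_pseudocount(self, small_dataset):
        with pytest.raises(ValueError):
            WordEnrichment(small_dataset, alpha=0.0)
        with pytest.raises(ValueError):
            WordEnrichment(small_dataset, pseudocount=0.0)

    def test_workers_validated(self, small_dataset):
        with pytest.raises(ValueError):
            WordEnrichment(small_dataset, lengths=(4,)).fit(workers=0)

    def test_summary_mentions_parameters_and_top_word(self, small_results):
        text = small_results.summary(top=3)
        top_word = small_results.results["word"].iloc[0]
        assert top_word in text
        assert "alpha" in text and "1e-05" in text
        assert "4, 5" in text

    def test_top_words_selection(self, small_results):
        top = small_results.top_words(10)
        assert len(top) == 10
        assert top == small_results.results["word"].head(10).tolist()


class TestNullBehaviour:
    def test_null_six_mer_pvalues_roughly_uniform(self):
        """On an unplanted dataset the analytic p-values of 6-mers are
        approximately uniform: the fraction below 0.05 lies in a loose
        band (words are inter-correlated), and nothing survives FDR."""
        from wordbridge import build_ranked_dataset
        from wordbridge.synthetic import SyntheticSpec, make_null

        spec = SyntheticSpec(n_genes=150, length_range=(200, 400), seed=21)
        seqs, ranks = make_null(spec)
        ds = build_ranked_dataset(seqs, ranks)
        res = WordEnrichment(ds, lengths=(6,)).fit()
        df = res.results
        frac = (df["p_analytic"] < 0.05).mean()
        assert 0.001 < frac < 0.12
        assert df["z"].abs().max() < 8
        assert df["fdr"].min() > 0.05
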