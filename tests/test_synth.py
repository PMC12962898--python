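"""Generative model: determinism, exact mode, the analytic inclusion-
probability oracle and recovery of configured structure."""

import math
from dataclasses import replace
from itertools import permutations

import numpy as np
import pytest

from napcensus import Category, build_cohort, prevalence
from napcensus.corpus import _corpus_tables
from napcensus.extraction import ExclusionReason
from napcensus.synth import (
    DATABASE,
    INTEGRATED,
    SyntheticConfig,
    expected_prevalence,
    generate_corpus,
    metabolite_universe,
    weighted_sample_without_replacement,
)


def _metabolite_only(**overrides):
    base = dict(
        n_studies=500, seed=0, categories=(Category.METABOLITE,),
        universe_sizes={Category.METABOLITE: 12},
        mean_list_length={Category.METABOLITE: 4.0},
        over_threshold_rate={Category.METABOLITE: 0.0},
        max_list_length=10,
        single_compound_rate=0.0,
        no_heading_rate={Category.METABOLITE: 0.0},
        incomplete_rate={Category.METABOLITE: 0.0},
        p_integrated={Category.METABOLITE: 0.0},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestGenerateCorpus:
    def test_empty(self):
        assert len(generate_corpus(SyntheticConfig(n_studies=0))) == 0

    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_studies=40, seed=11)
        a = _corpus_tables(generate_corpus(cfg))
        b = _corpus_tables(generate_corpus(cfg))
        c = _corpus_tables(generate_corpus(replace(cfg, seed=12)))
        assert a == b
        assert a != c

    def test_exact_mode_pins_cohort_arithmetic(self, glossary, synonyms):
        cfg = SyntheticConfig(seed=2, exact_counts={
            Category.METABOLITE: {
                ExclusionReason.SINGLE_COMPOUND_STUDY: 305,
                ExclusionReason.NO_MATCHING_HEADING: 259,
                ExclusionReason.EXCEEDS_THRESHOLD: 8,
                ExclusionReason.INCOMPLETE_DATA: 1,
            },
            Category.TARGET: {}, Category.PATHWAY: {},
        })
        corpus = generate_corpus(cfg)
        ledger, _ = build_cohort(corpus, Category.METABOLITE, glossary,
                                 synonyms)
        assert ledger.N == 465
        assert ledger.exclusion_counts()["single_compound_study"] == 305

    def test_marginal_rates_converge(self, glossary, synonyms):
        cfg = SyntheticConfig(n_studies=3000, seed=13)
        corpus = generate_corpus(cfg)
        singles = sum(r.study_focus.value == "single_compound" for r in corpus)
        rate = singles / len(corpus)
        se = math.sqrt(cfg.single_compound_rate
                       * (1 - cfg.single_compound_rate) / len(corpus))
        assert abs(rate - cfg.single_compound_rate) < 4 * se

    def test_infeasible_list_length_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            _metabolite_only(max_list_length=13).validate()


class TestWeightedSampling:
    def test_draws_are_distinct_and_within_support(self):
        rng = np.random.default_rng(0)
        w = np.array([0.5, 0.0, 0.2, 0.2, 0.1])
        for _ in range(50):
            idx = weighted_sample_without_replacement(rng, w, 3)
            assert len(set(idx)) == 3
            assert 1 not in idx

    def test_oversized_draw_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            weighted_sample_without_replacement(rng, np.array([1.0, 0.0]), 2)


class TestExpectedPrevalence:
    def test_uniform_weights_symmetric(self):
        """Uniform draw of a single item from 10 → inclusion 0.1 each."""
        cfg = _metabolite_only(
            universe_sizes={Category.METABOLITE: 10},
            mean_list_length={Category.METABOLITE: 0.1},
            max_list_length=1, threshold=1,
            bias_weight_w=0.0, disease_offset=0, disease_subuniverse_size=10,
        )
        for element in cfg.universe(Category.METABOLITE):
            assert expected_prevalence(cfg, element, INTEGRATED) \
                == pytest.approx(0.1)

    def test_matches_exhaustive_enumeration(self):
        """Universe 4, ℓ=2: exact DP equals the sum over all ordered
        successive draws."""
        cfg = _metabolite_only(
            universe_sizes={Category.METABOLITE: 4},
            mean_list_length={Category.METABOLITE: 2.0},
            max_list_length=2, threshold=2,
        )
        weights = cfg.popularity_weights(Category.METABOLITE)
        pmf = cfg.list_length_probs(Category.METABOLITE)
        universe = cfg.universe(Category.METABOLITE)
        for target in range(4):
            total = 0.0
            for length in (1, 2):
                p_in = 0.0
                for seq in permutations(range(4), length):
                    prob, used = 1.0, 0.0
                    for i in seq:
                        prob *= weights[i] / (1.0 - used)
                        used += weights[i]
                    if target in seq:
                        p_in += prob
                total += pmf[length] * p_in
            assert expected_prevalence(cfg, universe[target], DATABASE) \
                == pytest.approx(total)

    def test_outside_disease_subuniverse_impossible_when_w_zero(self):
        cfg = _metabolite_only(bias_weight_w=0.0, disease_offset=5,
                               disease_subuniverse_size=5,
                               mean_list_length={Category.METABOLITE: 2.0},
                               max_list_length=4)
        universe = cfg.universe(Category.METABOLITE)
        assert expected_prevalence(cfg, universe[0], INTEGRATED) == 0.0
        assert expected_prevalence(cfg, universe[6], INTEGRATED) > 0.0

    def test_monte_carlo_agrees_with_exact(self):
        cfg = _metabolite_only()
        element = cfg.universe(Category.METABOLITE)[0]
        exact = expected_prevalence(cfg, element, DATABASE, method="exact")
        mc = expected_prevalence(cfg, element, DATABASE, method="mc",
                                 n_mc=40000)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_zipf_exponent_monotonically_concentrates_the_top(self):
        """Homogeneity emergence: a steeper popularity law raises the top
        element's inclusion probability."""
        values = []
        for s in (0.5, 0.8, 1.1, 1.5, 2.0):
            cfg = _metabolite_only(zipf_exponent=s)
            values.append(expected_prevalence(
                cfg, cfg.universe(Category.METABOLITE)[0], DATABASE))
        assert all(b > a for a, b in zip(values, values[1:]))


class TestRecovery:
    def test_empirical_prevalence_tracks_the_oracle(self, glossary, synonyms):
        """Census prevalence on generated corpora recovers the analytic
        inclusion probabilities of the top elements."""
        cfg = _metabolite_only(n_studies=1500, seed=101)
        corpus = generate_corpus(cfg)
        ledger, cache = build_cohort(corpus, Category.METABOLITE, glossary,
                                     synonyms)
        assert ledger.N == 1500
        table = prevalence(cache, ledger)
        for element in cfg.universe(Category.METABOLITE)[:5]:
            expected = expected_prevalence(cfg, element, DATABASE)
            row = table.row_for(element)
            empirical = (row.n if row else 0) / ledger.N
            se = math.sqrt(expected * (1 - expected) / ledger.N)
            assert abs(empirical - expected) < 4 * se

    def test_integration_lowers_top_element_prevalence(self, glossary,
                                                       synonyms):
        """Stratified-contrast signature: with w < 1 the integrated stratum
        reports the top element less often, across seeds."""
        from napcensus import stratify

        wins = 0
        for seed in range(6):
            cfg = _metabolite_only(
                n_studies=600, seed=200 + seed,
                p_integrated={Category.METABOLITE: 0.5},
                bias_weight_w=0.2, disease_offset=4,
                disease_subuniverse_size=8,
            )
            corpus = generate_corpus(cfg)
            rep = stratify(corpus, Category.METABOLITE, "metabolite_method",
                           glossary, synonyms)
            top = cfg.universe(Category.METABOLITE)[0]
            db = rep.tables["database_dependent"].row_for(top)
            integ = rep.tables["integrated"].row_for(top)
            p_db = db.n / rep.tables["database_dependent"].N
            p_in = (integ.n if integ else 0) / rep.tables["integrated"].N
            wins += p_db > p_in
        assert wins == 6


def test_metabolite_universe_flavonoid_layout(classmap):
    top20 = metabolite_universe(60, flavonoid_fraction_top20=0.75)[:20]
    n_flav = sum(classmap.class_of(m) == "flavonoid" for m in top20)
    assert n_flav == 15
    assert top20[0] == "Quercetin"
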