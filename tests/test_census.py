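"""Cohorts, prevalence, sensitivity, stratification and report rendering."""

import json
from collections import Counter

import pytest

from napcensus import (
    Category,
    Exclusion,
    ExclusionReason,
    build_cohort,
    class_share,
    extract_study_findings,
    percent,
    prevalence,
    render_report,
    round_half_up,
    sensitivity,
    stratify,
)
from napcensus.corpus import ClassMap, MetaboliteMethod, TargetMethod
from napcensus.synth import table1_fixture, table2_fixture, top5_fixture


# printed n/N pairs whose one-decimal percentage is reproduced by
# round-half-up
@pytest.mark.parametrize("n,total,expected", [
    (294, 465, 63.2),
    (144, 465, 31.0),
    (429, 880, 48.8),   # 48.75 rounds half-up
    (344, 880, 39.1),
    (306, 880, 34.8),
    (502, 917, 54.7),
    (460, 917, 50.2),
    (162, 258, 62.8),
    (93, 261, 35.6),
    (398, 725, 54.9),
    (30, 153, 19.6),
    (58, 137, 42.3),
])
def test_percent_round_half_up(n, total, expected):
    assert percent(n, total) == expected


def test_round_half_up_integers():
    assert round_half_up(138.8) == 139.0
    assert round_half_up(31.5) == 32.0
    assert round_half_up(31.44, 1) == 31.4


class TestBuildCohort:
    def test_empty_corpus(self, glossary, synonyms):
        from napcensus import Corpus

        ledger, cache = build_cohort(Corpus(()), Category.METABOLITE,
                                     glossary, synonyms)
        assert ledger.N == 0 and cache == {} \
            and all(not v for v in ledger.excluded.values())

    def test_pinned_exclusion_arithmetic(self, glossary, synonyms):
        corpus = table1_fixture(seed=5)
        ledger, _ = build_cohort(corpus, Category.METABOLITE, glossary,
                                 synonyms)
        assert ledger.N == 465
        assert ledger.exclusion_counts() == {
            "single_compound_study": 305, "no_matching_heading": 259,
            "exceeds_threshold": 8, "incomplete_data": 1,
        }

    def test_matches_straight_line_oracle(self, random_corpus_factory,
                                          glossary, synonyms):
        """The ledger equals an independent per-record classification."""
        corpus, _ = random_corpus_factory(21, n=200)
        for category in Category:
            ledger, cache = build_cohort(corpus, category, glossary, synonyms,
                                         max_items=10)
            for record in corpus:
                out = extract_study_findings(record, glossary, synonyms,
                                             max_items=10).outcomes[category]
                if isinstance(out, Exclusion):
                    assert record.article_id in ledger.excluded[out.reason]
                else:
                    assert record.article_id in ledger.included_ids
                    assert cache[record.article_id] == out

    def test_ledger_conservation(self, random_corpus_factory, glossary,
                                 synonyms):
        corpus, _ = random_corpus_factory(31, n=80)
        for category in Category:
            ledger, _ = build_cohort(corpus, category, glossary, synonyms,
                                     max_items=10)
            ledger.check_partition(corpus.ids)
            assert ledger.total == len(corpus)


class TestPrevalence:
    def test_printed_top_row(self, glossary, synonyms):
        corpus = table1_fixture(seed=5)
        ledger, cache = build_cohort(corpus, Category.METABOLITE, glossary,
                                     synonyms)
        row = prevalence(cache, ledger).row_for("Quercetin")
        assert (row.n, row.N, row.percent, row.rank) == (294, 465, 63.2, 1)

    def test_zero_count_elements_never_emitted(self, glossary, synonyms):
        corpus = table1_fixture(seed=5)
        ledger, cache = build_cohort(corpus, Category.TARGET, glossary,
                                     synonyms)
        table = prevalence(cache, ledger)
        assert all(r.n > 0 for r in table.rows)

    def test_counts_each_study_once_and_orders_deterministically(
            self, random_corpus_factory, glossary, synonyms):
        """Nested-loop counting oracle on a ≤50-study corpus."""
        corpus, _ = random_corpus_factory(41, n=50)
        for category in Category:
            ledger, cache = build_cohort(corpus, category, glossary, synonyms,
                                         max_items=10)
            table = prevalence(cache, ledger)
            oracle = Counter()
            for aid in ledger.included_ids:
                for element in set(cache[aid]):
                    oracle[element] += 1
            assert {r.element: r.n for r in table.rows} == dict(oracle)
            # ordering: count desc, name asc; ranks strictly increasing
            keys = [(-r.n, r.element) for r in table.rows]
            assert keys == sorted(keys)
            assert [r.rank for r in table.rows] \
                == list(range(1, len(table.rows) + 1))
            assert all(0 <= r.percent <= 100 for r in table.rows)


class TestSensitivity:
    def test_pinned_top5_values(self, glossary, synonyms):
        corpus = top5_fixture(seed=5)
        rep = sensitivity(corpus, Category.METABOLITE, glossary, synonyms)
        row = rep.tables[5].row_for("Quercetin")
        assert (row.n, row.N, row.percent) == (162, 258, 62.8)
        rep = sensitivity(corpus, Category.TARGET, glossary, synonyms)
        row = rep.tables[5].row_for("AKT1")
        assert (row.n, row.N, row.percent) == (93, 261, 35.6)

    def test_cohorts_nest_across_thresholds(self, random_corpus_factory,
                                            glossary, synonyms):
        corpus, _ = random_corpus_factory(51, n=120)
        rep = sensitivity(corpus, Category.TARGET, glossary, synonyms,
                          thresholds=(10, 7, 4, 2))
        for t_small, t_big in [(2, 4), (4, 7), (7, 10)]:
            assert rep.ledgers[t_small].included_ids \
                <= rep.ledgers[t_big].included_ids
            assert rep.ledgers[t_small].total == len(corpus)

    def test_all_singleton_lists_identical_tables(self, glossary, synonyms):
        corpus = table1_fixture(seed=7)  # every included list has <=4 items
        rep = sensitivity(corpus, Category.METABOLITE, glossary, synonyms,
                          thresholds=(30, 20, 10, 5))
        frames = [rep.tables[t].to_frame() for t in (30, 20, 10, 5)]
        for frame in frames[1:]:
            assert frame.equals(frames[0])

    def test_rank_stability_matrix_matches_tables(self, glossary, synonyms):
        corpus = top5_fixture(seed=5)
        rep = sensitivity(corpus, Category.METABOLITE, glossary, synonyms)
        assert rep.rank_stability.loc["Quercetin", 30] == 1
        assert rep.rank_stability.loc["Quercetin", 5] == 1

    def test_invalid_thresholds_rejected(self, glossary, synonyms):
        corpus = table1_fixture(seed=5)
        with pytest.raises(ValueError):
            sensitivity(corpus, Category.TARGET, glossary, synonyms,
                        thresholds=(30, 30))


class TestStratify:
    def test_pinned_contrast(self, glossary, synonyms):
        corpus = table2_fixture(seed=5)
        rep = stratify(corpus, Category.TARGET, "target_method", glossary,
                       synonyms)
        db = rep.tables["database_dependent"].row_for("AKT1")
        integ = rep.tables["integrated"].row_for("AKT1")
        assert (db.n, db.N, db.percent) == (398, 725, 54.9)
        assert (integ.n, integ.N, integ.percent) == (30, 153, 19.6)
        assert rep.n_unknown == 2
        assert rep.prevalence_difference["AKT1"] == pytest.approx(35.3)

    def test_unknown_flag_omitted_but_in_overall(self, glossary, synonyms):
        corpus = table2_fixture(seed=5)
        ledger, _ = build_cohort(corpus, Category.TARGET, glossary, synonyms)
        rep = stratify(corpus, Category.TARGET, "target_method", glossary,
                       synonyms)
        assert rep.tables["database_dependent"].N \
            + rep.tables["integrated"].N + rep.n_unknown == ledger.N == 880

    def test_recombines_to_overall_counts(self, random_corpus_factory,
                                          glossary, synonyms):
        """Split-and-recount oracle: per element, the stratum counts sum to
        the overall count over flagged studies."""
        corpus, _ = random_corpus_factory(61, n=150)
        rep = stratify(corpus, Category.METABOLITE, "metabolite_method",
                       glossary, synonyms, max_items=10)
        ledger, cache = build_cohort(corpus, Category.METABOLITE, glossary,
                                     synonyms, max_items=10)
        flags = {r.article_id: r.metabolite_method for r in corpus}
        flagged = {aid for aid in ledger.included_ids
                   if flags[aid] != MetaboliteMethod.UNKNOWN}
        oracle = Counter()
        for aid in flagged:
            for element in set(cache[aid]):
                oracle[element] += 1
        combined = Counter()
        for table in rep.tables.values():
            for row in table.rows:
                combined[row.element] += row.n
        assert combined == oracle

    def test_wrong_flag_field_and_pathways_rejected(self, glossary, synonyms):
        corpus = table2_fixture(seed=5)
        with pytest.raises(ValueError):
            stratify(corpus, Category.PATHWAY, "target_method", glossary,
                     synonyms)
        with pytest.raises(ValueError):
            stratify(corpus, Category.METABOLITE, "target_method", glossary,
                     synonyms)

    def test_empty_stratum_has_no_rows(self, glossary, synonyms):
        corpus = table1_fixture(seed=5)  # builder default: all database_only
        rep = stratify(corpus, Category.TARGET, "target_method", glossary,
                       synonyms)
        assert rep.tables["integrated"].N == 0
        assert rep.tables["integrated"].rows == ()


class TestClassShare:
    def test_direct_count(self, glossary, synonyms, classmap):
        corpus = table2_fixture(seed=5)
        ledger, cache = build_cohort(corpus, Category.METABOLITE, glossary,
                                     synonyms)
        table = prevalence(cache, ledger, top_n=7)
        share = class_share(table, classmap, "flavonoid", top_k=7)
        # pinned top-7: five flavonoids + two phytosterols
        assert share.share == pytest.approx(5 / 7)
        assert share.counts["phytosterol"] == 2

    def test_empty_classmap_gives_zero(self, glossary, synonyms):
        corpus = table1_fixture(seed=5)
        ledger, cache = build_cohort(corpus, Category.METABOLITE, glossary,
                                     synonyms)
        table = prevalence(cache, ledger, top_n=20)
        share = class_share(table, ClassMap({}), "flavonoid", top_k=20)
        assert share.share == 0.0

    def test_filter_and_count_oracle(self, random_corpus_factory, glossary,
                                     synonyms, classmap):
        corpus, _ = random_corpus_factory(71, n=60)
        ledger, cache = build_cohort(corpus, Category.METABOLITE, glossary,
                                     synonyms, max_items=10)
        table = prevalence(cache, ledger)
        share = class_share(table, classmap, "flavonoid", top_k=10)
        top = table.rows[:10]
        expected = sum(classmap.class_of(r.element) == "flavonoid"
                       for r in top) / min(10, len(table.rows))
        assert share.share == pytest.approx(expected)


class TestRenderReport:
    def test_bundle_round_trips(self, tmp_path, glossary, synonyms):
        import pandas as pd

        corpus = table1_fixture(seed=5)
        tables, ledgers = [], {}
        for category in Category:
            ledger, cache = build_cohort(corpus, category, glossary, synonyms)
            ledgers[category] = ledger
            tables.append(prevalence(cache, ledger, top_n=3))
        summary = render_report(tables, ledgers, tmp_path, seed=5)
        reloaded = json.loads((tmp_path / "summary.json").read_text())
        assert reloaded == json.loads(json.dumps(summary))
        assert reloaded["cohorts"]["metabolite"]["N"] == 465
        frame = pd.read_csv(tmp_path / "prevalence_metabolite_overall_30.csv")
        assert frame.iloc[0]["element"] == "Quercetin"
        assert frame.iloc[0]["percent"] == 63.2
        ledger_frame = pd.read_csv(tmp_path / "ledger_target.csv")
        assert (ledger_frame["status"] == "included").sum() == 880

    def test_empty_analysis_set_is_valid(self, tmp_path):
        summary = render_report([], {}, tmp_path, seed=0)
        reloaded = json.loads((tmp_path / "summary.json").read_text())
        assert reloaded["tables"] == [] and summary["cohorts"] == {}
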