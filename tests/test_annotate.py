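"""The tiering pipeline: level-1 matching, library search, structure
ranking, level assignment, quasi-reference promotion and batch runs."""

from dataclasses import replace

import pytest

from flavotier.annotate import (
    EvidenceBundle,
    Hit2a,
    PipelineConfig,
    assign_level,
    gather_evidence,
    match_level1,
    promote_quasi_reference,
    rank_level2b,
    run_pipeline,
    search_level2a,
)
from flavotier.flavochem import CompoundTemplate, compound_formula, \
    theoretical_spectrum
from flavotier.similarity import SimilarityScore
from flavotier.spectra import LibraryRecord
from flavotier.synthetic import SimulationConfig, simulate_dataset, \
    simulate_spectrum

CFG = PipelineConfig()


def _record(t, rt=10.0, provenance="reference"):
    sp = replace(theoretical_spectrum(t), retention_time=rt)
    return LibraryRecord(sp, t.name, formula=compound_formula(t),
                         subclass=t.skeleton, provenance=provenance)


@pytest.fixture(scope="module")
def daidzein():
    return CompoundTemplate("daidzein", "isoflavone",
                            {"hydroxyl": 1}, {"hydroxyl": 1})


@pytest.fixture(scope="module")
def daidzein_std(daidzein):
    return _record(daidzein, rt=10.0)


class TestLevel1:
    def test_identical_spectrum_and_rt_matches(self, daidzein, daidzein_std):
        q = replace(theoretical_spectrum(daidzein), retention_time=10.0)
        m = match_level1(q, [daidzein_std], CFG)
        assert m is not None and m.record.name == "daidzein"
        assert m.n_matched_fragments >= CFG.min_matched_fragments

    def test_rt_window_is_hard(self, daidzein, daidzein_std):
        q = replace(theoretical_spectrum(daidzein), retention_time=10.06)
        assert match_level1(q, [daidzein_std], CFG) is None

    def test_precursor_error_window_is_hard(self, daidzein, daidzein_std):
        sp = theoretical_spectrum(daidzein)
        q = replace(sp, retention_time=10.0,
                    precursor_mz=sp.precursor_mz + 0.0051)
        assert match_level1(q, [daidzein_std], CFG) is None

    def test_missing_rt_skips_level1_with_warning(self, daidzein,
                                                  daidzein_std, caplog):
        q = theoretical_spectrum(daidzein)  # no RT
        with caplog.at_level("WARNING", logger="flavotier"):
            assert match_level1(q, [daidzein_std], CFG) is None
        assert "level 1 skipped" in caplog.text


class TestLevel2a:
    def test_self_search_scores_100(self, daidzein, daidzein_std):
        q = theoretical_spectrum(daidzein)
        hits = search_level2a(q, [daidzein_std], CFG)
        assert hits and hits[0].score.percent == pytest.approx(100.0)

    def test_out_of_window_precursor_excluded(self, daidzein, daidzein_std):
        q = theoretical_spectrum(daidzein)
        q = replace(q, precursor_mz=q.precursor_mz + 1.0,
                    peaks=tuple(q.peaks))
        assert search_level2a(q, [daidzein_std], CFG) == ()

    def test_jittered_query_finds_its_generator(self, fixture_library):
        library = [rec for rec, _ in fixture_library]
        _, t = next(
            (rec, t) for rec, t in fixture_library if t.name == "daidzein"
        )
        q = simulate_spectrum(t, SimulationConfig(seed=21))
        hits = search_level2a(q, library, CFG)
        assert hits and hits[0].record.name == "daidzein"


class TestLevel2b:
    def test_generator_ranks_first_and_explains_most(self, daidzein):
        q = simulate_spectrum(daidzein, SimulationConfig(seed=3))
        decoy = CompoundTemplate("genistein-like", "isoflavone",
                                 {"hydroxyl": 2}, {"hydroxyl": 1})
        ranked = rank_level2b(q, [daidzein, decoy], CFG)
        assert ranked[0].template.name == "daidzein"
        assert ranked[0].explained_fraction >= 0.9
        assert ranked[0].verdict.passed

    def test_positional_isomers_flagged_indistinguishable(self):
        a = CompoundTemplate("formononetin", "isoflavone",
                             {"hydroxyl": 1}, {"methoxyl": 1})
        b = CompoundTemplate("isoformononetin", "isoflavone",
                             {"hydroxyl": 1}, {"methoxyl": 1})
        q = theoretical_spectrum(a)
        ranked = rank_level2b(q, [a, b], CFG)
        assert len(ranked) == 2
        assert all(c.tied for c in ranked)

    def test_wrong_formula_excluded_at_precursor_filter(self, daidzein):
        q = theoretical_spectrum(daidzein)
        wrong = CompoundTemplate("apigenin", "flavone",
                                 {"hydroxyl": 2}, {"hydroxyl": 1})
        assert rank_level2b(q, [wrong], CFG) == ()


class TestAssignLevel:
    def test_level1_takes_precedence_over_2a(self, daidzein, daidzein_std):
        q = replace(theoretical_spectrum(daidzein), retention_time=10.0)
        ev = gather_evidence(q, [daidzein_std], [daidzein_std], [], CFG)
        res = assign_level(ev, CFG)
        assert res.level == "1"

    def test_only_2a_hit_gives_2a(self, daidzein, daidzein_std):
        q = theoretical_spectrum(daidzein)
        ev = gather_evidence(q, [], [daidzein_std], [], CFG)
        res = assign_level(ev, CFG)
        assert res.level == "2a"
        assert res.best_candidate == "daidzein"

    def test_formula_tree_and_ranking_give_level3(self, daidzein):
        q = theoretical_spectrum(daidzein)
        ev = gather_evidence(q, [], [], [], CFG)
        res = assign_level(ev, CFG)
        assert res.level == "3"
        assert ev.tree is not None
        assert ev.classification is not None and ev.classification.ranking

    def test_empty_evidence_is_level5(self, daidzein):
        q = theoretical_spectrum(daidzein)
        ev = EvidenceBundle(query=q)
        assert assign_level(ev, CFG).level == "5"


class TestPromotion:
    def _result_with_score(self, daidzein, daidzein_std, percent):
        q = theoretical_spectrum(daidzein)
        hit = Hit2a(daidzein_std,
                    SimilarityScore(percent / 100.0, "dot_product"))
        ev = EvidenceBundle(query=q, hits_2a=(hit,))
        return assign_level(ev, CFG)

    def test_promoted_above_90(self, daidzein, daidzein_std):
        res = self._result_with_score(daidzein, daidzein_std, 96.6)
        promoted = promote_quasi_reference([res], CFG)
        assert len(promoted) == 1
        assert promoted[0].provenance == "quasi-reference-2a"

    def test_exactly_90_not_promoted(self, daidzein, daidzein_std):
        res = self._result_with_score(daidzein, daidzein_std, 90.0)
        assert promote_quasi_reference([res], CFG) == []

    def test_level1_results_never_promoted(self, daidzein, daidzein_std):
        q = replace(theoretical_spectrum(daidzein), retention_time=10.0)
        ev = gather_evidence(q, [daidzein_std], [daidzein_std], [], CFG)
        res = assign_level(ev, CFG)
        assert res.level == "1"
        assert promote_quasi_reference([res], CFG) == []


class TestRunPipeline:
    def test_designated_standards_reach_level1(self, fixture_library):
        """Seven compounds given reference standards all resolve to level 1."""
        chosen = fixture_library[:7]
        standards = [rec for rec, _ in chosen]
        queries = [
            simulate_spectrum(t, SimulationConfig(seed=100 + i),
                              rt=rec.spectrum.retention_time,
                              identifier=f"q{i}")
            for i, (rec, t) in enumerate(chosen)
        ]
        results, report = run_pipeline(queries, standards, [], [], CFG)
        assert [r.level for r in results] == ["1"] * 7
        assert list(report["level"]) == ["1"] * 7

    def test_withheld_library_queries_fall_to_2b_or_3(self, fixture_library):
        rec, t = fixture_library[10]
        q = simulate_spectrum(t, SimulationConfig(seed=55), identifier="q0")
        results, _ = run_pipeline([q], [], [], [t], CFG)
        assert results[0].level == "2b"
        results, _ = run_pipeline([q], [], [], [], CFG)
        assert results[0].level == "3"

    def test_empty_query_set_gives_empty_report(self):
        results, report = run_pipeline([], [], [], [], CFG)
        assert results == [] and len(report) == 0

    def test_reports_are_byte_identical_across_reruns(self, tmp_path):
        ds = simulate_dataset(25, cfg=SimulationConfig(seed=31))
        out = []
        for run in range(2):
            _, report = run_pipeline(ds.queries, ds.standards, ds.library,
                                     ds.candidates, CFG)
            path = tmp_path / f"report{run}.tsv"
            report.to_csv(path, sep="\t", index=False)
            out.append(path.read_bytes())
        assert out[0] == out[1]
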