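import numpy as np
import pytest

from collotopics.synthetic_data import (
    GeneratorSpec,
    generate,
    sample_lda_corpus,
    signature_theme_mapping,
)
from collotopics.pipeline import PipelineConfig, run_pipeline
from collotopics.themes import (
    ThemeMapping,
    labeling_report,
    load_theme_mapping,
    pooled_prevalence,
    prevalence_table,
    save_theme_mapping,
    theme_prevalence,
)
from collotopics.topic_model import fit_lda


@pytest.fixture(scope="module")
def fitted():
    bags, _, theta = sample_lda_corpus(K=4, V=40, D=30, doc_length_mean=20, seed=40)
    return fit_lda(bags, K=4, alpha=0.2, n_iter=60, burn_in=20, seed=41), theta


class TestThemePrevalence:
    def test_degenerate_mapping_gives_single_theme_everything(self, fitted):
        res, _ = fitted
        mapping = ThemeMapping("ALL", {k: "crime" for k in range(4)})
        rows = {r.theme: r for r in theme_prevalence(res, mapping)}
        assert rows["crime"].share == pytest.approx(100.0)
        assert rows["other"].share == 0.0
        assert rows["crime"].token_count == int(res.n_k.sum())

    def test_shares_sum_to_100(self, fitted):
        res, _ = fitted
        mapping = ThemeMapping("ALL", {0: "crime", 1: "celebration", 2: "other", 3: "crime"})
        rows = theme_prevalence(res, mapping)
        assert sum(r.share for r in rows) == pytest.approx(100.0, abs=1e-9)

    def test_missing_topic_error_lists_uncovered_ids(self, fitted):
        res, _ = fitted
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            theme_prevalence(res, ThemeMapping("ALL", {0: "crime", 1: "crime"}))

    def test_complete_fills_other(self):
        m = ThemeMapping("Asia", {0: "crime"}).complete(3)
        assert m.entries == {0: "crime", 1: "other", 2: "other"}

    def test_document_unit_alternative(self, fitted):
        res, _ = fitted
        mapping = ThemeMapping("ALL", {k: "crime" if k < 2 else "other" for k in range(4)})
        rows = {r.theme: r for r in theme_prevalence(res, mapping, unit="documents")}
        assert rows["crime"].token_count + rows["other"].token_count == len(
            res.model.bags.nonempty()
        )
        assert sum(r.share for r in rows.values()) == pytest.approx(100.0, abs=1e-9)

    def test_recovers_generating_theme_weights(self):
        """Single-stratum corpus with theme weights (.40,.20,.15,.15,.10):
        recovered token shares stay within 5 points of truth (median of
        10 seeds)."""
        weights = {
            "complications_risk": 0.40, "crime": 0.20, "celebration": 0.15,
            "celebrity_births": 0.15, "contraception": 0.10,
        }
        errs = []
        for seed in range(10):
            spec = GeneratorSpec(
                region_theme_weights={"Asia": weights},
                docs_per_region=120,
                target_insertion_rate=1.0,
                seed=seed,
            )
            docs, truth = generate(spec)
            res = run_pipeline(
                docs,
                PipelineConfig(n_topics=10, alpha=0.1, n_iter=150, burn_in=50,
                               seed=seed, stratify=False),
            )
            mapping = signature_theme_mapping(res.lda["ALL"], "ALL")
            est = {r.theme: r.share for r in theme_prevalence(res.lda["ALL"], mapping)}
            errs.append(max(abs(est.get(t, 0.0) - 100 * w) for t, w in weights.items()))
        assert np.median(errs) <= 5.0


class TestPrevalenceTable:
    def _rows(self, stratum, shares):
        from collotopics.themes import ThemePrevalence

        total = sum(shares.values())
        return [
            ThemePrevalence(stratum, t, 100.0 * c / total, c) for t, c in shares.items()
        ]

    def test_structural_shape(self):
        strata = [
            self._rows(s, {t: 10 for t in ["crime", "celebration", "other"]})
            for s in ["Africa", "Asia", "Europe", "NorthAmerica", "Oceania"]
        ]
        table = prevalence_table(strata)
        assert len(table) == 15
        assert set(table.columns) == {"stratum", "theme", "share_pct", "token_count"}

    def test_swapped_dominant_themes_change_rank_order(self):
        a = self._rows("Africa", {"crime": 70, "celebration": 30})
        b = self._rows("Asia", {"crime": 30, "celebration": 70})
        table = prevalence_table([a, b])
        top = table.loc[table.groupby("stratum")["share_pct"].idxmax()]
        assert set(zip(top["stratum"], top["theme"])) == {
            ("Africa", "crime"), ("Asia", "celebration")
        }

    def test_pooled_equals_token_weighted_average(self):
        a = self._rows("Africa", {"crime": 30, "celebration": 10})
        b = self._rows("Asia", {"crime": 10, "celebration": 50})
        pooled = {r.theme: r for r in pooled_prevalence([a, b])}
        assert pooled["crime"].share == pytest.approx(100 * 40 / 100)
        assert pooled["crime"].token_count == 40
        assert sum(r.share for r in pooled.values()) == pytest.approx(100.0, abs=1e-9)


class TestLabelingReport:
    def test_structure(self, fitted):
        res, _ = fitted
        rep = labeling_report(res, top_k=20, n_exemplars=10)
        assert set(rep) == {0, 1, 2, 3}
        for entry in rep.values():
            assert len(entry["top_words"]) == 20
            assert 0 < len(entry["exemplars"]) <= 10

    def test_exemplars_sorted_by_topic_share(self, fitted):
        res, _ = fitted
        rep = labeling_report(res)
        for entry in rep.values():
            shares = [e["topic_share"] for e in entry["exemplars"]]
            assert shares == sorted(shares, reverse=True)

    def test_empty_bag_documents_never_exemplars(self):
        from collotopics.topic_model import BagCorpus

        bags = BagCorpus(
            ["a", "b"],
            [[0, 1], [], [0, 0]],
            [{"doc_id": "x"}, {"doc_id": "empty"}, {"doc_id": "y"}],
        )
        res = fit_lda(bags, K=2, n_iter=10, burn_in=2, seed=1)
        rep = labeling_report(res)
        for entry in rep.values():
            assert "empty" not in {e["doc_id"] for e in entry["exemplars"]}

    def test_exemplars_match_generating_theme(self):
        """Documents listed as a topic's exemplars were generated with that
        topic's theme dominant."""
        spec = GeneratorSpec(docs_per_region=60, target_insertion_rate=1.0, seed=5)
        docs, truth = generate(spec)
        res = run_pipeline(
            docs,
            PipelineConfig(n_topics=10, alpha=0.1, n_iter=150, burn_in=50,
                           seed=5, stratify=False),
        )
        result = res.lda["ALL"]
        mapping = signature_theme_mapping(result, "ALL")
        rep = labeling_report(result, n_exemplars=10)
        agree = total = 0
        for k, entry in rep.items():
            for e in entry["exemplars"]:
                total += 1
                agree += truth.doc_themes[e["doc_id"]] == mapping.entries[k]
        assert agree / total >= 0.9


class TestMappingIO:
    def test_yaml_round_trip(self, tmp_path):
        m1 = ThemeMapping("Africa", {0: "crime", 1: "other"})
        m2 = ThemeMapping("ALL", {0: "celebration", 1: "contraception"})
        path = tmp_path / "mapping.yaml"
        save_theme_mapping([m1, m2], path)
        loaded = load_theme_mapping(path)
        assert loaded["Africa"].entries == m1.entries
        assert loaded["ALL"].entries == m2.entries

    def test_load_with_n_topics_completes(self, tmp_path):
        path = tmp_path / "mapping.yaml"
        save_theme_mapping([ThemeMapping("ALL", {0: "crime"})], path)
        loaded = load_theme_mapping(path, n_topics=3)
        assert loaded["ALL"].entries == {0: "crime", 1: "other", 2: "other"}
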