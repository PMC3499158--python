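"""The QA engine: store, extraction, grouping, and the check dispatcher."""

import numpy as np
import pandas as pd
import pytest

from flowqa.errors import MetadataError
from flowqa.formula import parse_formula
from flowqa.gating import GatingSet
from flowqa.qa import (
    StatsStore,
    extract_stats,
    make_groups,
    qa_check,
    qa_preprocess,
    resolve_population,
)
from flowqa.simulate import StudyConfig, generate_study

from conftest import write_study_inputs


class TestStore:
    def test_extract_is_idempotent(self, small_gated, small_study):
        store = StatsStore()
        t1 = extract_stats(small_gated, small_study.metadata, store=store)
        n1 = len(store.stats())
        t2 = extract_stats(small_gated, small_study.metadata, store=store)
        assert len(store.stats()) == n1
        pd.testing.assert_frame_equal(t1, t2)

    def test_record_cardinalities(self, small_gated, small_study):
        store = StatsStore()
        table = extract_stats(small_gated, small_study.metadata, store=store)
        S = len(small_gated)
        P = len(small_study.template.gates) + 1  # + root
        assert (table["statistic"] == "proportion").sum() == S * P
        assert (table["statistic"] == "count").sum() == S * P
        assert (table["statistic"] == "spike").sum() == S * 5

    def test_accumulation_across_experiments(self, small_study):
        """A second gated batch appends; a task spanning both flags like a
        single merged extraction."""
        cfg2 = StudyConfig(seed=12, n_subjects=1, events_per_sample=4000)
        study2 = generate_study(cfg2, [])
        # disjoint sample ids: rename batch 2
        tpl = small_study.template
        gs1 = GatingSet(tpl)
        for s in small_study.samples[:6]:
            gs1.gate(s)
        gs2 = GatingSet(tpl)
        for s in study2.samples:
            s.sample_id = "x_" + s.sample_id
            gs2.gate(s)
        meta2 = study2.metadata.copy()
        meta2["sample_id"] = "x_" + meta2["sample_id"]
        store = StatsStore()
        extract_stats(gs1, small_study.metadata.iloc[:6], store=store)
        extract_stats(gs2, meta2, store=store)
        merged = store.joined()
        assert set(merged["sample_id"]) == (
            set(small_study.metadata["sample_id"].iloc[:6])
            | set(meta2["sample_id"]))

    def test_orphan_sample_is_error(self, small_gated, small_study):
        meta = small_study.metadata.iloc[:2]
        with pytest.raises(MetadataError, match="missing from metadata"):
            extract_stats(small_gated, meta)

    def test_persistent_store_roundtrip(self, small_gated, small_study, tmp_path):
        p = tmp_path / "qa.db"
        store = StatsStore(p)
        extract_stats(small_gated, small_study.metadata, store=store)
        store.close()
        back = StatsStore(p)
        assert len(back.stats()) > 0
        meta = back.metadata()
        assert pd.api.types.is_datetime64_any_dtype(meta["RecdDt"])


class TestGroups:
    def make_table(self):
        rng = np.random.default_rng(0)
        rows = []
        i = 0
        for ch in "ABCDEFGH":
            for st_ in ("s1", "s2"):
                if (ch, st_) in (("G", "s2"), ("H", "s2")):
                    continue  # unobserved combinations
                rows.append(dict(record_id=f"r{i}", sample_id=f"smp{i}",
                                 population="/p", channel=ch, stain=st_,
                                 statistic="MFI", value=rng.normal()))
                i += 1
        return pd.DataFrame(rows)

    def test_observed_cross_product_only(self):
        table = self.make_table()
        f = parse_formula("MFI~x|channel*stain")
        groups = make_groups(table, f, ["/p"])
        assert len(groups) == 14  # not 16

    def test_empty_conditioning_single_group(self):
        table = self.make_table()
        f = parse_formula("MFI~x")
        groups = make_groups(table, f, ["/p"])
        assert list(groups) == [()]
        assert len(groups[()]) == len(table)

    def test_partition_exhaustive_disjoint_and_order_independent(self):
        table = self.make_table()
        f = parse_formula("MFI~x|channel")
        g1 = make_groups(table, f, ["/p"])
        shuffled = table.sample(frac=1, random_state=5)
        g2 = make_groups(shuffled, f, ["/p"])
        all_ids = sorted(rid for g in g1.values() for rid in g["record_id"])
        assert all_ids == sorted(table["record_id"])
        assert set(g1) == set(g2)
        for k in g1:
            assert g1[k]["record_id"].tolist() == g2[k]["record_id"].tolist()


class TestQaCheck:
    def test_rbc_lysis_flags_exactly_low_samples(self, default_pipeline):
        study = default_pipeline["study"]
        flagged = {c.sample_id for c in default_pipeline["calls"]["RBCLysis"]
                   if c.flagged}
        truth = set(study.truth.loc[study.truth["kind"] == "low_lysis",
                                    "sample_id"])
        assert flagged == truth

    def test_never_flags_outside_task_filter(self, default_pipeline):
        table = default_pipeline["table"]
        for name, calls in default_pipeline["calls"].items():
            task = next(t for t in default_pipeline["tasks"]
                        if t.definition.qaName == name)
            in_scope = set(
                table[(table["statistic"] == task.formula.outcome)
                      & table["population"].isin(task.populations)]["record_id"])
            for c in calls:
                if c.kind == "within_group":
                    assert c.target in in_scope

    def test_rerun_is_deterministic_and_replaces(self, default_pipeline):
        store = default_pipeline["store"]
        task = default_pipeline["tasks"][0]
        before = store.calls(task.qaID)
        calls2 = qa_check(task, store, table=default_pipeline["table"])
        after = store.calls(task.qaID)
        pd.testing.assert_frame_equal(before, after)
        assert len(calls2) == len(before)

    def test_all_identical_values_norm_zero_flags(self):
        store = StatsStore()
        rows = [dict(record_id=f"r{i}", sample_id=f"s{i}", population="/p",
                     channel="", stain="", statistic="proportion", value=0.5)
                for i in range(8)]
        store.upsert_stats(pd.DataFrame(rows))
        store.upsert_metadata(pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(8)],
             "Tube": ["T"] * 8}))
        from flowqa.qa import QaTask
        from flowqa.workspace import QaTaskDef
        d = QaTaskDef(qaID=9, qaName="flat", description="", qaLevel="Tube",
                      pop="/p", pop_mode="path",
                      formula=parse_formula("proportion~Tube"),
                      plotType="xyplot", outlier_func="norm", params={})
        calls = qa_check(QaTask(definition=d, populations=["/p"]), store)
        assert not any(c.flagged for c in calls)

    def test_bwplot_two_level_scheme(self, default_pipeline):
        calls = default_pipeline["calls"]["MNCConsistency"]
        kinds = {c.kind for c in calls}
        assert "within_group" in kinds and "between_group" in kinds
        n_groups = len({c.target for c in calls if c.kind == "between_group"})
        assert n_groups == 8  # one per coresampleid


class TestPreprocess:
    def test_missing_formula_variable_names_task(self, small_gated, small_study,
                                                 tmp_path):
        meta_csv, tasks_csv = write_study_inputs(small_study, tmp_path)
        bad = tasks_csv.read_text().replace("RecdDt|Tube", "Dose|Tube", 1)
        tasks_csv.write_text(bad)
        with pytest.raises(MetadataError, match="Dose"):
            qa_preprocess(small_gated, tasks_csv, meta_csv, StatsStore())

    def test_unmatched_population_names_task(self, small_gated, small_study,
                                             tmp_path):
        meta_csv, tasks_csv = write_study_inputs(small_study, tmp_path)
        bad = tasks_csv.read_text().replace("WBC_perct", "NoSuchGate")
        tasks_csv.write_text(bad)
        with pytest.raises(MetadataError, match="qaID=1"):
            qa_preprocess(small_gated, tasks_csv, meta_csv, StatsStore())

    def test_aggregate_pop_resolution(self, small_gated):
        assert len(resolve_population(small_gated, "MFI", "auto")) == 5
        assert resolve_population(small_gated, "WBC_perct", "auto") == ["/WBC_perct"]
        assert resolve_population(small_gated, "/WBC_perct/MNC", "auto") == [
            "/WBC_perct/MNC"]
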