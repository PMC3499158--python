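import numpy as np
import pandas as pd
import pytest

from flowqa.gating import GatingSet
from flowqa.qa import StatsStore, qa_check, qa_preprocess
from flowqa.simulate import (
    StudyConfig,
    default_anomalies,
    generate_study,
    write_default_tasks,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced study for unit tests: 2 subjects, 4k events."""
    return StudyConfig(seed=11, n_subjects=2, events_per_sample=4000)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg, [])


@pytest.fixture(scope="session")
def small_gated(small_study):
    gs = GatingSet(small_study.template)
    for s in small_study.samples:
        gs.gate(s)
    return gs


@pytest.fixture(scope="session")
def default_study():
    cfg = StudyConfig(seed=1)
    return cfg, generate_study(cfg, default_anomalies(StudyConfig(seed=1)))


@pytest.fixture(scope="session")
def default_pipeline(default_study, tmp_path_factory):
    """Default anomaly study run through the full pipeline once per session."""
    cfg, study = default_study
    gs = GatingSet(study.template)
    for s in study.samples:
        gs.gate(s)
    d = tmp_path_factory.mktemp("pipe")
    tasks_csv = d / "tasks.csv"
    write_default_tasks(tasks_csv)
    meta_csv = d / "meta.csv"
    meta = study.metadata.copy()
    meta["RecdDt"] = meta["RecdDt"].dt.date.astype(str)
    meta.to_csv(meta_csv, index=False)
    store = StatsStore()
    table, tasks = qa_preprocess(gs, tasks_csv, meta_csv, store)
    joined = store.joined()
    calls = {t.definition.qaName: qa_check(t, store, table=joined) for t in tasks}
    return dict(cfg=cfg, study=study, gs=gs, store=store, tasks=tasks,
                table=joined, calls=calls)


def write_study_inputs(study, d):
    """Write metadata/tasks CSVs for a study into directory d."""
    tasks_csv = d / "tasks.csv"
    write_default_tasks(tasks_csv)
    meta_csv = d / "meta.csv"
    meta = study.metadata.copy()
    meta["RecdDt"] = meta["RecdDt"].dt.date.astype(str)
    meta.to_csv(meta_csv, index=False)
    return meta_csv, tasks_csv
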