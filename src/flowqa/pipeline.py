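"""End-to-end pipeline stages shared by the command-line interface.

gate -> extract statistics -> check tasks -> report, each idempotent on
unchanged inputs. The flag summary is a plain dict (JSON-serializable):
per task, the distinct flagged sample ids and flagged group labels.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

from .fcs import read_fcs
from .gating import GatingSet
from .qa import QaTask, StatsStore, qa_check, qa_preprocess
from .report import ReportSpec, qa_report
from .spike import SpikeConfig
from .workspace import read_gating_template

__all__ = ["gate_directory", "run_pipeline", "flag_summary"]

log = logging.getLogger("flowqa.pipeline")


def gate_directory(fcs_dir: str | Path, template_path: str | Path,
                   quantize_bins: int | None = None) -> GatingSet:
    """Gate every .fcs file in a directory through the template."""
    template = read_gating_template(template_path)
    gs = GatingSet(template)
    files = sorted(Path(fcs_dir).glob("*.fcs"))
    if not files:
        raise FileNotFoundError(f"no .fcs files in {fcs_dir}")
    t0 = time.perf_counter()
    for f in files:
        gs.gate(read_fcs(f), quantize_bins=quantize_bins)
    log.info("gated %d samples in %.1fs", len(files), time.perf_counter() - t0)
    return gs


def flag_summary(store: StatsStore, tasks: list[QaTask]) -> dict:
    """Machine-readable flag summary: per task, flagged samples and groups."""
    out: dict = {"tasks": {}}
    for task in sorted(tasks, key=lambda t: t.qaID):
        calls = store.calls(task.qaID)
        flagged = calls[calls["flagged"]]
        out["tasks"][str(task.qaID)] = {
            "qaName": task.definition.qaName,
            "n_calls": int(len(calls)),
            "flagged_samples": sorted(set(flagged["sample_id"].dropna())),
            "flagged_groups": sorted(
                flagged.loc[flagged["kind"] == "between_group", "target"]
            ),
        }
    return out


def run_pipeline(
    fcs_dir: str | Path,
    template_path: str | Path,
    meta_csv: str | Path,
    tasks_csv: str | Path,
    store_path: str | Path = ":memory:",
    report_dir: str | Path | None = None,
    mfi_stat: str = "median",
    spike_config: SpikeConfig = SpikeConfig(),
    quantize_bins: int | None = None,
) -> tuple[GatingSet, StatsStore, list[QaTask], dict]:
    """All stages in order; returns (gating set, store, tasks, flag summary)."""
    gs = gate_directory(fcs_dir, template_path, quantize_bins=quantize_bins)
    store = StatsStore(store_path)
    _, tasks = qa_preprocess(gs, tasks_csv, meta_csv, store,
                             mfi_stat=mfi_stat, spike_config=spike_config)
    table = store.joined()
    for task in tasks:
        qa_check(task, store, table=table)
    summary = flag_summary(store, tasks)
    if report_dir is not None:
        qa_report(ReportSpec(tasks=tasks, store=store, out_dir=Path(report_dir),
                             gating_set=gs))
    return gs, store, tasks, summary
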