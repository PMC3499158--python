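"""The quality-assessment engine.

Statistics from gated samples are written to a small relational store
(single-file sqlite, or in-memory), joined with study metadata, stratified
by the task formula's conditioning variables, and passed to the outlier
functions. Outlier calls are recorded back into the store, keyed by task.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GatingError, MetadataError
from .formula import Formula
from .gating import GatingSet, match_populations, population_stats
from .outliers import (
    OUTLIER_REGISTRY,
    between_group_outliers,
    outlier_cutoff,
    outlier_norm,
    qoutlier,
    residual_outliers,
    robust_regression,
)
from .spike import SpikeConfig, spike_statistic
from .transforms import LinearTransform
from .workspace import QaTaskDef, read_metadata, read_task_defs

__all__ = [
    "StatsStore",
    "QaTask",
    "OutlierCall",
    "extract_stats",
    "qa_preprocess",
    "make_groups",
    "qa_check",
    "MIN_GROUP_SIZE",
]

log = logging.getLogger(__name__)

MIN_GROUP_SIZE = 3  # robust scale estimates need at least 3 points

STAT_COLUMNS = ["record_id", "sample_id", "population", "channel", "stain",
                "statistic", "value"]


@dataclass(frozen=True)
class OutlierCall:
    """One outlier decision: a record (within-group) or a group (between)."""

    qaID: int
    target: str  # record_id, or the subgroup label for between-group calls
    kind: str  # "within_group" | "between_group"
    flagged: bool
    score: float
    group_key: dict = field(default_factory=dict)
    sample_id: str | None = None


@dataclass
class QaTask:
    """A fully resolved QA task: definition plus matched population paths."""

    definition: QaTaskDef
    populations: list[str]

    @property
    def qaID(self) -> int:
        return self.definition.qaID

    @property
    def formula(self) -> Formula:
        return self.definition.formula

    def __repr__(self) -> str:
        d = self.definition
        return (f"QaTask({d.qaID}: {d.qaName}, pop={d.pop!r}, "
                f"formula={d.formula}, plot={d.plotType})")


class StatsStore:
    """Embedded store for statistics, metadata, tasks and outlier calls.

    Backed by sqlite3 — a path gives a persistent single-file database,
    ":memory:" an ephemeral one. Statistics are keyed by record_id
    (sample|population|channel|statistic) so re-extraction is idempotent
    and a second imported experiment appends rather than duplicates.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.con = sqlite3.connect(self.path)
        cur = self.con.cursor()
        cur.execute(
            "CREATE TABLE IF NOT EXISTS stats ("
            "record_id TEXT PRIMARY KEY, sample_id TEXT, population TEXT,"
            "channel TEXT, stain TEXT, statistic TEXT, value REAL)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS metadata (sample_id TEXT PRIMARY KEY, doc TEXT)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS tasks (qaID INTEGER PRIMARY KEY, doc TEXT)"
        )
        cur.execute(
            "CREATE TABLE IF NOT EXISTS outlier_calls ("
            "qaID INTEGER, target TEXT, kind TEXT, flagged INTEGER,"
            "score REAL, group_key TEXT, sample_id TEXT)"
        )
        self.con.commit()

    def close(self) -> None:
        self.con.close()

    # -- statistics ----------------------------------------------------
    def upsert_stats(self, records: pd.DataFrame) -> None:
        rows = records[STAT_COLUMNS].itertuples(index=False)
        self.con.executemany(
            "INSERT OR REPLACE INTO stats VALUES (?,?,?,?,?,?,?)", list(rows)
        )
        self.con.commit()

    def stats(self) -> pd.DataFrame:
        return pd.read_sql_query("SELECT * FROM stats ORDER BY record_id", self.con)

    # -- metadata ------------------------------------------------------
    def upsert_metadata(self, meta: pd.DataFrame) -> None:
        docs = []
        for _, row in meta.iterrows():
            d = {}
            for k, v in row.items():
                if isinstance(v, pd.Timestamp):
                    d[k] = {"__date__": v.isoformat()}
                elif pd.isna(v):
                    d[k] = None
                else:
                    d[k] = v
            docs.append((str(row["sample_id"]), json.dumps(d, sort_keys=True)))
        self.con.executemany(
            "INSERT OR REPLACE INTO metadata VALUES (?,?)", docs
        )
        self.con.commit()

    def metadata(self) -> pd.DataFrame:
        rows = self.con.execute(
            "SELECT doc FROM metadata ORDER BY sample_id"
        ).fetchall()
        records = []
        for (doc,) in rows:
            d = json.loads(doc)
            records.append(
                {k: (pd.Timestamp(v["__date__"])
                     if isinstance(v, dict) and "__date__" in v else v)
                 for k, v in d.items()}
            )
        return pd.DataFrame(records)

    def joined(self) -> pd.DataFrame:
        """Statistics long table with metadata columns merged on sample_id."""
        stats = self.stats()
        meta = self.metadata()
        if stats.empty:
            return stats
        if meta.empty:
            return stats
        return stats.merge(meta, on="sample_id", how="left")

    # -- tasks ---------------------------------------------------------
    def upsert_task(self, task: QaTask) -> None:
        d = task.definition
        doc = {
            "qaID": d.qaID, "qaName": d.qaName, "description": d.description,
            "qaLevel": d.qaLevel, "pop": d.pop, "pop_mode": d.pop_mode,
            "formula": str(d.formula), "plotType": d.plotType,
            "outlier_func": d.outlier_func, "params": d.params, "rFunc": d.rFunc,
            "populations": task.populations,
        }
        self.con.execute(
            "INSERT OR REPLACE INTO tasks VALUES (?,?)",
            (d.qaID, json.dumps(doc, sort_keys=True)),
        )
        self.con.commit()

    def tasks(self) -> list[dict]:
        rows = self.con.execute("SELECT doc FROM tasks ORDER BY qaID").fetchall()
        return [json.loads(doc) for (doc,) in rows]

    # -- outlier calls -------------------------------------------------
    def replace_calls(self, qaID: int, calls: list[OutlierCall]) -> None:
        self.con.execute("DELETE FROM outlier_calls WHERE qaID = ?", (qaID,))
        self.con.executemany(
            "INSERT INTO outlier_calls VALUES (?,?,?,?,?,?,?)",
            [
                (c.qaID, c.target, c.kind, int(c.flagged), c.score,
                 json.dumps(c.group_key, sort_keys=True, default=str), c.sample_id)
                for c in calls
            ],
        )
        self.con.commit()

    def calls(self, qaID: int | None = None) -> pd.DataFrame:
        q = "SELECT * FROM outlier_calls"
        params: tuple = ()
        if qaID is not None:
            q += " WHERE qaID = ?"
            params = (qaID,)
        df = pd.read_sql_query(q + " ORDER BY qaID, kind, target", self.con,
                               params=params)
        df["flagged"] = df["flagged"].astype(bool)
        return df


def record_id(sample_id: str, population: str, channel: str, statistic: str) -> str:
    return f"{sample_id}|{population}|{channel}|{statistic}"


def _fluorescence_channels(gs: GatingSet) -> list[str]:
    """Channels with a non-linear display transform, excluding time/scatter."""
    return [ch for ch, tr in gs.template.transforms.items()
            if not isinstance(tr, LinearTransform)]


def extract_stats(
    gs: GatingSet,
    meta: pd.DataFrame,
    mfi_stat: str = "median",
    spike_config: SpikeConfig = SpikeConfig(),
    store: StatsStore | None = None,
) -> pd.DataFrame:
    """Extract per-population statistics for every gated sample.

    Emits one proportion and one count record per node, one MFI record per
    (node, gate-dimension channel), and one spike record per (sample,
    fluorescence channel); joins the study metadata by sample_id and
    persists to *store* when given. Returns the joined long table.
    """
    known = set(meta["sample_id"].astype(str))
    orphans = sorted(set(gs.hierarchies) - known)
    if orphans:
        raise MetadataError(f"samples missing from metadata: {orphans}")

    rows: list[dict] = []
    fluor = _fluorescence_channels(gs)
    for sid in sorted(gs.hierarchies):
        h = gs.hierarchies[sid]
        sample = h.sample
        for rec in population_stats(h, mfi_stat=mfi_stat):
            pop = rec["population"]
            rows.append(dict(
                record_id=record_id(sid, pop, "", "proportion"), sample_id=sid,
                population=pop, channel="", stain="", statistic="proportion",
                value=rec["proportion"],
            ))
            rows.append(dict(
                record_id=record_id(sid, pop, "", "count"), sample_id=sid,
                population=pop, channel="", stain="", statistic="count",
                value=float(rec["count"]),
            ))
            for ch, mfi in rec["mfi"].items():
                rows.append(dict(
                    record_id=record_id(sid, pop, ch, "MFI"), sample_id=sid,
                    population=pop, channel=ch, stain=sample.stain_for(ch),
                    statistic="MFI", value=mfi,
                ))
        if sample.time_channel is not None:
            for ch in fluor:
                if ch not in sample.channel_names:
                    continue
                # compensated + transformed values, as the gates see them
                res = spike_statistic(sample, ch, spike_config,
                                      values=h.channel_values(ch))
                rows.append(dict(
                    record_id=record_id(sid, "/", ch, "spike"), sample_id=sid,
                    population="/", channel=ch, stain=sample.stain_for(ch),
                    statistic="spike", value=res.statistic,
                ))
    table = pd.DataFrame(rows, columns=STAT_COLUMNS)
    if store is not None:
        store.upsert_stats(table)
        store.upsert_metadata(meta)
    return table.merge(meta, on="sample_id", how="left")


def resolve_population(gs_or_paths, pattern: str, mode: str = "auto") -> list[str]:
    """Resolve a task's population pattern, honouring the declared mode.

    ``auto``: a leading "/" means a full path; otherwise try the unique
    terminal name first and fall back to substring matching (how aggregate
    patterns like "MFI" select all per-channel MFI gates).
    """
    if mode != "auto":
        return match_populations(gs_or_paths, pattern, mode)
    if pattern.startswith("/"):
        return match_populations(gs_or_paths, pattern, "path")
    try:
        return match_populations(gs_or_paths, pattern, "exact")
    except GatingError:
        return match_populations(gs_or_paths, pattern, "substring")


def qa_preprocess(
    gs: GatingSet,
    task_csv: str | Path,
    meta_csv: str | Path,
    store: StatsStore,
    mfi_stat: str = "median",
    spike_config: SpikeConfig = SpikeConfig(),
) -> tuple[pd.DataFrame, list[QaTask]]:
    """Read tasks + metadata, extract statistics, validate and build tasks."""
    defs = read_task_defs(task_csv)
    meta = read_metadata(meta_csv)
    table = extract_stats(gs, meta, mfi_stat=mfi_stat, spike_config=spike_config,
                          store=store)
    tasks: list[QaTask] = []
    for d in defs:
        if d.formula.outcome == "spike":
            pops = ["/"]
        else:
            try:
                pops = resolve_population(gs, d.pop, d.pop_mode)
            except GatingError as exc:
                raise MetadataError(f"task qaID={d.qaID} ({d.qaName}): {exc}") from exc
            if not pops:
                raise MetadataError(
                    f"task qaID={d.qaID} ({d.qaName}): population pattern "
                    f"{d.pop!r} matches no nodes"
                )
        for var in (d.formula.x_var, *d.formula.conditioning):
            if var not in table.columns:
                raise MetadataError(
                    f"task qaID={d.qaID} ({d.qaName}): formula variable {var!r} "
                    f"not found in statistics/metadata columns"
                )
        task = QaTask(definition=d, populations=pops)
        tasks.append(task)
        store.upsert_task(task)
    return table, tasks


def task_records(table: pd.DataFrame, task: QaTask) -> pd.DataFrame:
    """Rows of the joined table within the task's population/outcome filter.

    Aggregate MFI patterns additionally restrict spike/MFI records to the
    matched populations; the task's channel filter is implied by population
    membership (each per-channel gate is its own node).
    """
    f = task.formula
    sel = table[table["statistic"] == f.outcome]
    sel = sel[sel["population"].isin(task.populations)]
    return sel.dropna(subset=["value"])


def make_groups(
    table: pd.DataFrame, formula: Formula, pop_nodes: list[str] | None = None
) -> dict[tuple, pd.DataFrame]:
    """Partition filtered records by the observed conditioning cross product.

    Empty conditioning gives a single group of everything; combinations not
    observed in the data are simply absent. The partition is exhaustive and
    disjoint over the filtered records, and independent of record order.
    """
    sel = table
    if pop_nodes is not None:
        sel = sel[sel["population"].isin(pop_nodes)]
    sel = sel[sel["statistic"] == formula.outcome].dropna(subset=["value"])
    if not formula.conditioning:
        return {(): sel.sort_values("record_id").reset_index(drop=True)}
    out: dict[tuple, pd.DataFrame] = {}
    for key, grp in sel.groupby(list(formula.conditioning), observed=True,
                                dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        out[key] = grp.sort_values("record_id").reset_index(drop=True)
    return out


def _numeric_x(series: pd.Series) -> np.ndarray:
    """Regression abscissa: dates become days since 1970-01-01."""
    if pd.api.types.is_datetime64_any_dtype(series):
        return ((series - pd.Timestamp("1970-01-01")) / pd.Timedelta(days=1)).to_numpy()
    return pd.to_numeric(series).to_numpy(dtype=float)


def _group_key_dict(formula: Formula, key: tuple) -> dict:
    return {var: lvl for var, lvl in zip(formula.conditioning, key)}


def qa_check(
    task: QaTask,
    store: StatsStore,
    table: pd.DataFrame | None = None,
) -> list[OutlierCall]:
    """Run one task's outlier detection and record the calls in the store.

    Dispatch follows the plot type: ``xyplot`` makes per-record calls
    (threshold/robust-normal on the values, or residual calls against a
    Huber regression when rFunc is set); ``bwplot``/``densityplot`` run the
    two-level scheme — the boxplot rule within each level of the x variable
    and the log-IQR robust-normal test across levels. Re-running a task
    replaces its previous calls.
    """
    d = task.definition
    f = task.formula
    if table is None:
        table = store.joined()
    sel = task_records(table, task)
    groups = make_groups(sel, f)
    calls: list[OutlierCall] = []
    params = dict(d.params)
    z_cutoff = float(params.pop("z_cutoff", 3.0))

    for key, grp in groups.items():
        gdict = _group_key_dict(f, key)
        values = grp["value"].to_numpy(dtype=float)
        if d.plotType in ("bwplot", "densityplot"):
            calls.extend(_two_level_calls(task, grp, gdict, z_cutoff))
            continue
        if d.rFunc:
            if d.rFunc != "rlm":
                raise MetadataError(f"task qaID={d.qaID}: unknown rFunc {d.rFunc!r}")
            if len(grp) < 4:
                log.info("task %s: group %s too small for regression (n=%d)",
                         d.qaName, gdict, len(grp))
                continue
            x = _numeric_x(grp[f.x_var])
            if np.ptp(x) == 0:
                log.info("task %s: group %s has constant x; skipped", d.qaName, gdict)
                continue
            fit = robust_regression(x, values)
            res = residual_outliers(fit, x, values, z_cutoff=z_cutoff)
        elif d.outlier_func == "cutoff":
            res = outlier_cutoff(values, **params)
        elif d.outlier_func in ("norm", "qoutlier"):
            if len(grp) < MIN_GROUP_SIZE:
                log.info("task %s: group %s smaller than %d; skipped",
                         d.qaName, gdict, MIN_GROUP_SIZE)
                continue
            if d.outlier_func == "norm":
                res = outlier_norm(values, z_cutoff=z_cutoff,
                                   alpha=params.get("alpha"),
                                   sides=params.get("sides", "two"))
            else:
                res = qoutlier(values)
        else:
            raise MetadataError(
                f"task qaID={d.qaID}: unknown outlier function {d.outlier_func!r} "
                f"(registry: {sorted(OUTLIER_REGISTRY)})"
            )
        for i, row in enumerate(grp.itertuples(index=False)):
            calls.append(OutlierCall(
                qaID=d.qaID, target=row.record_id, kind="within_group",
                flagged=bool(res.flags[i]), score=float(res.scores[i]),
                group_key=gdict, sample_id=row.sample_id,
            ))
    store.replace_calls(d.qaID, calls)
    return calls


def _two_level_calls(task: QaTask, grp: pd.DataFrame, gdict: dict,
                     z_cutoff: float) -> list[OutlierCall]:
    """bwplot scheme: qoutlier within x-levels, log-IQR across x-levels."""
    d = task.definition
    f = task.formula
    calls: list[OutlierCall] = []
    sub_values: dict = {}
    for lvl, sub in grp.groupby(f.x_var, observed=True, sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        sub_values[lvl] = vals
        if len(sub) < MIN_GROUP_SIZE:
            log.info("task %s: level %s=%r has n=%d (<%d); within-group calls skipped",
                     d.qaName, f.x_var, lvl, len(sub), MIN_GROUP_SIZE)
            continue
        res = qoutlier(vals)
        for i, row in enumerate(sub.itertuples(index=False)):
            calls.append(OutlierCall(
                qaID=d.qaID, target=row.record_id, kind="within_group",
                flagged=bool(res.flags[i]), score=float(res.scores[i]),
                group_key={**gdict, f.x_var: lvl}, sample_id=row.sample_id,
            ))
    between = between_group_outliers(sub_values, z_cutoff=z_cutoff)
    for lvl, res in sorted(between.items(), key=lambda kv: str(kv[0])):
        calls.append(OutlierCall(
            qaID=d.qaID, target=f"{f.x_var}={lvl}", kind="between_group",
            flagged=res["flagged"], score=res["score"],
            group_key={**gdict, f.x_var: lvl}, sample_id=None,
        ))
    return calls
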