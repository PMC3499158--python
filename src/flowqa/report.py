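"""Static HTML/SVG quality-assessment report.

The report is a pure function of the statistics store and the task list:
an index page groups tasks by QA level with per-task failure counts and
tables of failing files; each task gets a summary plot (scatter, box or
density, matching its plot type) with flagged points drawn in red and
hyperlinked to per-sample detail plots (gate plots when the gated data is
available, otherwise the sample highlighted against its group).

All SVG output is deterministic (fixed matplotlib hash salt, no creation
dates), so regenerating a report from the same store is byte-identical.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Polygon as MplPolygon, Rectangle  # noqa: E402

from .gating import GatingHierarchy, GatingSet  # noqa: E402
from .qa import QaTask, StatsStore, task_records  # noqa: E402

__all__ = ["ReportSpec", "qa_report", "plot_task", "plot_gate"]

_SVG_RC = {
    "svg.hashsalt": "flowqa-report",
    "svg.fonttype": "none",
    "figure.max_open_warning": 0,
}
FLAG_COLOR = "#cc2222"
BASE_COLOR = "#33557a"


@dataclass
class ReportSpec:
    tasks: list[QaTask]
    store: StatsStore
    out_dir: Path
    gating_set: GatingSet | None = None
    title: str = "Quality assessment report"
    subset: dict = field(default_factory=dict)  # qaID -> display subset query


def _save_svg(fig, path: Path, data_payload: dict | None = None) -> None:
    """Write a deterministic SVG, embedding data coordinates as metadata."""
    buf = io.StringIO()
    with plt.rc_context(_SVG_RC):
        fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    if data_payload is not None:
        blob = json.dumps(data_payload, sort_keys=True, default=str)
        insert_at = svg.index(">", svg.index("<svg")) + 1
        svg = (svg[:insert_at]
               + f'\n<metadata id="flowqa-data">{blob}</metadata>'
               + svg[insert_at:])
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(svg)


def _x_positions(series: pd.Series) -> tuple[np.ndarray, list, list]:
    """Numeric plotting positions plus tick positions/labels."""
    if pd.api.types.is_datetime64_any_dtype(series):
        x = ((series - pd.Timestamp("1970-01-01")) / pd.Timedelta(days=1)).to_numpy()
        levels = sorted(series.dropna().unique())
        ticks = [(lvl - pd.Timestamp("1970-01-01")) / pd.Timedelta(days=1)
                 for lvl in levels]
        labels = [pd.Timestamp(lvl).date().isoformat() for lvl in levels]
        return x, ticks, labels
    try:
        x = pd.to_numeric(series).to_numpy(dtype=float)
        return x, [], []
    except (ValueError, TypeError):
        levels = sorted(series.astype(str).unique())
        lookup = {lvl: i for i, lvl in enumerate(levels)}
        x = series.astype(str).map(lookup).to_numpy(dtype=float)
        return x, list(range(len(levels))), levels


def _flag_lookup(store: StatsStore, qaID: int) -> pd.DataFrame:
    calls = store.calls(qaID)
    return calls[calls["kind"] == "within_group"].set_index("target")


def _group_label(row: pd.Series, cond: tuple) -> str:
    return ", ".join(f"{c}={row[c]}" for c in cond) if cond else "all samples"


def plot_task(task: QaTask, store: StatsStore, subset: str | None = None,
              table: pd.DataFrame | None = None,
              sample_url: dict | None = None):
    """Summary figure for one task; returns (figure, data payload).

    ``subset`` is a pandas query string restricting *display* only — it
    never changes which records were flagged. ``sample_url`` maps sample_id
    to a relative hyperlink target for flagged points.
    """
    d = task.definition
    f = task.formula
    if table is None:
        table = store.joined()
    sel = task_records(table, task)
    if subset:
        sel = sel.query(subset)
    flags = _flag_lookup(store, d.qaID)
    sel = sel.copy()
    sel["flagged"] = [
        bool(flags.loc[rid, "flagged"]) if rid in flags.index else False
        for rid in sel["record_id"]
    ]
    cond = f.conditioning
    if cond and d.plotType == "xyplot":
        keys = sorted(sel.groupby(list(cond), observed=True).groups)
    else:
        keys = [()]
    n_panel = max(len(keys), 1)
    ncols = min(n_panel, 3)
    nrows = -(-n_panel // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows),
                             squeeze=False)
    payload: dict = {"task": d.qaName, "formula": str(f), "panels": {}}

    for i, key in enumerate(keys):
        ax = axes[i // ncols][i % ncols]
        if key == ():
            panel = sel
            label = "all samples"
        else:
            key_t = key if isinstance(key, tuple) else (key,)
            m = np.ones(len(sel), dtype=bool)
            for c, lvl in zip(cond, key_t):
                m &= (sel[c] == lvl).to_numpy()
            panel = sel[m]
            label = ", ".join(str(k) for k in key_t)
        if d.plotType == "xyplot":
            _draw_xy(ax, panel, f, d, sample_url)
        elif d.plotType == "bwplot":
            _draw_box(ax, panel, f, store, d)
        else:
            _draw_density(ax, panel, f)
        ax.set_title(label, fontsize=9)
        payload["panels"][label] = {
            "sample_id": panel["sample_id"].tolist(),
            "value": panel["value"].tolist(),
            "flagged": panel["flagged"].tolist(),
        }
    for j in range(len(keys), nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.suptitle(f"{d.qaName}: {d.description}", fontsize=11)
    fig.tight_layout(rect=(0, 0, 1, 0.95))
    return fig, payload


def _draw_xy(ax, panel, f, d, sample_url):
    from .outliers import robust_regression

    x, ticks, labels = _x_positions(panel[f.x_var])
    y = panel["value"].to_numpy(dtype=float)
    flagged = panel["flagged"].to_numpy(dtype=bool)
    pts = ax.scatter(x[~flagged], y[~flagged], s=16, color=BASE_COLOR, zorder=2)
    del pts
    if flagged.any():
        fp = ax.scatter(x[flagged], y[flagged], s=26, color=FLAG_COLOR, zorder=3)
        if sample_url:
            fp.set_urls([sample_url.get(sid)
                         for sid in panel["sample_id"][flagged]])
    if d.rFunc and len(panel) >= 4 and np.ptp(x) > 0:
        fit = robust_regression(x, y)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, fit.predict(xs), color="#444444", lw=1, zorder=1)
    if ticks:
        ax.set_xticks(ticks[:: max(1, len(ticks) // 5)])
        ax.set_xticklabels(labels[:: max(1, len(labels) // 5)],
                           rotation=30, fontsize=7)
    ax.set_xlabel(f.x_var, fontsize=8)
    ax.set_ylabel(f.outcome, fontsize=8)


def _draw_box(ax, panel, f, store, d):
    calls = store.calls(d.qaID)
    between = calls[calls["kind"] == "between_group"].set_index("target")
    levels = sorted(panel[f.x_var].astype(str).unique())
    data, flagged_box = [], []
    for lvl in levels:
        sub = panel[panel[f.x_var].astype(str) == lvl]
        data.append(sub["value"].to_numpy(dtype=float))
        target = f"{f.x_var}={lvl}"
        flagged_box.append(bool(between.loc[target, "flagged"])
                           if target in between.index else False)
    if not data:
        ax.text(0.5, 0.5, "no records", ha="center", va="center")
        return
    bp = ax.boxplot(data, tick_labels=levels, patch_artist=True)
    for patch, bad in zip(bp["boxes"], flagged_box):
        patch.set_facecolor(FLAG_COLOR if bad else "#ccd8e8")
    for i, lvl in enumerate(levels):
        sub = panel[panel[f.x_var].astype(str) == lvl]
        bad = sub[sub["flagged"]]
        if len(bad):
            ax.scatter(np.full(len(bad), i + 1), bad["value"], s=24,
                       color=FLAG_COLOR, zorder=3)
    ax.tick_params(axis="x", labelrotation=60, labelsize=6)
    ax.set_ylabel(f.outcome, fontsize=8)


def _draw_density(ax, panel, f):
    for lvl, sub in panel.groupby(f.x_var, observed=True, sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            continue
        color = FLAG_COLOR if sub["flagged"].any() else None
        ax.hist(vals, bins=20, density=True, histtype="step",
                label=str(lvl), color=color)
    ax.legend(fontsize=6)
    ax.set_xlabel(f.outcome, fontsize=8)


def plot_gate(h: GatingHierarchy, node_path: str, max_points: int = 4000):
    """Dot/density plot of one gated population with the boundary overlaid.

    2D gates draw parent events with the rectangle/polygon boundary; 1D
    gates draw the parent density with interval markers. The annotation is
    the node name and its percent of parent (one source of truth: the mask
    counts).
    """
    node = h.node(node_path)
    fig, ax = plt.subplots(figsize=(4.0, 3.4))
    parent = node.parent
    parent_mask = parent.mask if parent is not None else np.ones(
        h.sample.n_events, dtype=bool)
    n_parent = int(parent_mask.sum())
    pct = 100.0 * node.count / n_parent if n_parent else float("nan")
    title = f"{node.name}: {pct:.1f}%" if n_parent else f"{node.name}: 0 events"

    gate = node.gate
    if gate is None or gate.kind == "bool":
        ax.set_title(title, fontsize=10)
        return fig
    if len(gate.dims) == 2:
        xs = h.channel_values(gate.dims[0])[parent_mask]
        ys = h.channel_values(gate.dims[1])[parent_mask]
        if len(xs) > max_points:  # deterministic thinning
            step = len(xs) // max_points + 1
            xs, ys = xs[::step], ys[::step]
        ax.scatter(xs, ys, s=2, color="#999999", rasterized=False)
        if gate.kind == "rect":
            (xlo, xhi), (ylo, yhi) = gate.geometry
            x0 = xlo if np.isfinite(xlo) else (xs.min() if len(xs) else 0)
            x1 = xhi if np.isfinite(xhi) else (xs.max() if len(xs) else 1)
            y0 = ylo if np.isfinite(ylo) else (ys.min() if len(ys) else 0)
            y1 = yhi if np.isfinite(yhi) else (ys.max() if len(ys) else 1)
            ax.add_patch(Rectangle((x0, y0), x1 - x0, y1 - y0, fill=False,
                                   edgecolor=FLAG_COLOR, lw=1.5))
        else:
            ax.add_patch(MplPolygon(np.asarray(gate.geometry), closed=True,
                                    fill=False, edgecolor=FLAG_COLOR, lw=1.5))
        ax.set_xlabel(gate.dims[0], fontsize=8)
        ax.set_ylabel(gate.dims[1], fontsize=8)
    else:
        vals = h.channel_values(gate.dims[0])[parent_mask]
        if len(vals):
            ax.hist(vals, bins=64, density=True, color="#8899bb")
        else:
            ax.text(0.5, 0.5, "0 events", ha="center", va="center",
                    transform=ax.transAxes)
        lo, hi = gate.geometry
        for edge in (lo, hi):
            if np.isfinite(edge):
                ax.axvline(edge, color=FLAG_COLOR, lw=1.5)
        ax.set_xlabel(gate.dims[0], fontsize=8)
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    return fig


def _detail_plot(task: QaTask, store: StatsStore, sample_id: str,
                 gs: GatingSet | None, table: pd.DataFrame):
    if gs is not None and sample_id in gs.hierarchies:
        pop = task.populations[0]
        h = gs[sample_id]
        try:
            return plot_gate(h, pop)
        except Exception:  # fall through to the store-only view
            pass
    sel = task_records(table, task)
    fig, ax = plt.subplots(figsize=(4.0, 3.0))
    vals = sel["value"].to_numpy(dtype=float)
    own = sel[sel["sample_id"] == sample_id]["value"].to_numpy(dtype=float)
    if len(vals) > 1:
        ax.hist(vals, bins=24, density=True, color="#ccd8e8")
    for v in own:
        ax.axvline(v, color=FLAG_COLOR, lw=1.5)
    ax.set_title(f"{sample_id}: {task.definition.qaName}", fontsize=10)
    fig.tight_layout()
    return fig


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; color: #222; }}
h2 {{ border-bottom: 2px solid #33557a; padding-bottom: 0.2em; }}
table {{ border-collapse: collapse; margin: 0.6em 0; }}
td, th {{ border: 1px solid #bbb; padding: 2px 8px; font-size: 0.85em; }}
.fail {{ color: #cc2222; font-weight: bold; }}
.ok {{ color: #227722; }}
details {{ margin: 0.8em 0; }}
</style></head><body>
<h1>{title}</h1>
{body}
</body></html>
"""


def qa_report(spec: ReportSpec) -> Path:
    """Render the report directory; returns the path to index.html."""
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = spec.store.joined()
    sections: dict[str, list[str]] = {}
    for task in sorted(spec.tasks, key=lambda t: t.qaID):
        d = task.definition
        calls = spec.store.calls(d.qaID)
        flagged = calls[calls["flagged"]]
        failing = sorted(set(flagged["sample_id"].dropna()))
        task_dir = out / "tasks" / str(d.qaID)

        sample_url: dict[str, str] = {}
        for sid in failing:
            rel = f"tasks/{d.qaID}/samples/{sid}.svg"
            sample_url[sid] = f"samples/{sid}.svg"  # relative to summary.svg
            fig = _detail_plot(task, spec.store, sid, spec.gating_set, table)
            _save_svg(fig, out / rel)

        sel = task_records(table, task)
        if len(sel):
            fig, payload = plot_task(task, spec.store,
                                     subset=spec.subset.get(d.qaID),
                                     table=table, sample_url=sample_url)
            _save_svg(fig, task_dir / "summary.svg", data_payload=payload)
            plot_html = (f'<object type="image/svg+xml" '
                         f'data="tasks/{d.qaID}/summary.svg" '
                         f'width="820"></object>')
        else:
            plot_html = "<p><em>No records for this task.</em></p>"

        n_fail = len(failing)
        cls = "fail" if n_fail else "ok"
        rows = []
        for _, c in flagged.iterrows():
            link = (f'<a href="tasks/{d.qaID}/samples/{c["sample_id"]}.svg">'
                    f'{c["sample_id"]}</a>' if c["sample_id"] else c["target"])
            rows.append(f"<tr><td>{link}</td><td>{c['kind']}</td>"
                        f"<td>{c['group_key']}</td><td>{c['score']:.3g}</td></tr>")
        table_html = ""
        if rows:
            table_html = ("<table><tr><th>sample / group</th><th>kind</th>"
                          "<th>group key</th><th>score</th></tr>"
                          + "".join(rows) + "</table>")
        section = (
            f"<details><summary><b>{d.qaName}</b> — {d.description} "
            f"(<span class='{cls}'>{n_fail} failing files</span>)</summary>"
            f"<p><code>{d.formula}</code>, population <code>{d.pop}</code>, "
            f"outliers: <code>{d.outlier_func}</code></p>"
            f"{plot_html}{table_html}</details>"
        )
        sections.setdefault(d.qaLevel, []).append(section)

    body = ""
    for level in sorted(sections):
        body += f"<h2>{level} level</h2>\n" + "\n".join(sections[level])
    (out / "index.html").write_text(_PAGE.format(title=spec.title, body=body))
    return out / "index.html"
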