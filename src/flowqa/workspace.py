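"""Readers for the study-level input files.

Three tabular/structured inputs accompany the FCS files:

* the gating template — a JSON document with the channel universe,
  spillover matrix, per-channel transforms and the gate tree;
* the study metadata CSV — one row per FCS file (subject, date, tube,
  aliquot id, ...), ISO-8601 columns parsed to dates;
* the QA task definition CSV — one row per quality-assessment task.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormulaError, MetadataError, TemplateError
from .formula import Formula, parse_formula
from .gating import GateDef, GatingTemplate
from .transforms import SpilloverMatrix, make_transform

__all__ = ["read_gating_template", "read_metadata", "read_task_defs", "QaTaskDef"]


# ---------------------------------------------------------------- template


def _gate_from_dict(d: dict) -> GateDef:
    name = d.get("name")
    if not name:
        raise TemplateError("gate without a name in template")
    kind = d.get("type")
    if kind not in ("rect", "polygon", "interval", "bool"):
        raise TemplateError(f"gate {name!r}: unknown gate type {kind!r}")
    dims = tuple(d.get("dims", ()))
    geometry: tuple = ()
    if kind == "rect":
        rng = d.get("ranges")
        if rng is None or len(rng) != 2:
            raise TemplateError(f"gate {name!r}: rect requires 'ranges' for both dims")
        geometry = tuple(
            (-math.inf if lo is None else float(lo), math.inf if hi is None else float(hi))
            for lo, hi in rng
        )
    elif kind == "interval":
        rng = d.get("range")
        if rng is None:
            raise TemplateError(f"gate {name!r}: interval requires 'range'")
        lo, hi = rng
        geometry = (
            -math.inf if lo is None else float(lo),
            math.inf if hi is None else float(hi),
        )
    elif kind == "polygon":
        verts = d.get("vertices", ())
        geometry = tuple((float(x), float(y)) for x, y in verts)
    return GateDef(
        name=name,
        parent=d.get("parent"),
        kind=kind,
        dims=dims,
        geometry=geometry,
        bool_op=d.get("bool_op"),
        operands=tuple(d.get("operands", ())),
    )


def template_to_dict(template: GatingTemplate) -> dict:
    """Serialize a template back to the JSON dialect (inverse of the reader)."""
    gates = []
    for g in template.gates:
        d: dict = {"name": g.name, "parent": g.parent, "type": g.kind, "dims": list(g.dims)}
        if g.kind == "rect":
            d["ranges"] = [
                [None if not math.isfinite(lo) else lo, None if not math.isfinite(hi) else hi]
                for lo, hi in g.geometry
            ]
        elif g.kind == "interval":
            lo, hi = g.geometry
            d["range"] = [None if not math.isfinite(lo) else lo,
                          None if not math.isfinite(hi) else hi]
        elif g.kind == "polygon":
            d["vertices"] = [list(v) for v in g.geometry]
        else:
            d["bool_op"] = g.bool_op
            d["operands"] = list(g.operands)
        gates.append(d)
    out: dict = {"channels": list(template.channels), "gates": gates}
    if template.spillover is not None:
        out["spillover"] = {
            "detectors": list(template.spillover.detectors),
            "matrix": template.spillover.matrix.tolist(),
        }
    transforms = {}
    for ch, tr in template.transforms.items():
        kind = type(tr).__name__.replace("Transform", "").lower()
        params = {k: v for k, v in vars(tr).items() if not k.startswith("_")}
        transforms[ch] = {"type": kind, **params}
    out["transforms"] = transforms
    return out


def template_from_dict(doc: dict) -> GatingTemplate:
    channels = list(doc.get("channels", ()))
    if not channels:
        raise TemplateError("template declares no channels")
    spill = None
    if doc.get("spillover"):
        s = doc["spillover"]
        spill = SpilloverMatrix(tuple(s["detectors"]), np.asarray(s["matrix"], dtype=float))
    transforms = {
        ch: make_transform(spec) for ch, spec in (doc.get("transforms") or {}).items()
    }
    for ch in transforms:
        if ch not in channels:
            raise TemplateError(f"transform references unknown channel {ch!r}")
    gates = [_gate_from_dict(d) for d in doc.get("gates", ())]
    roots = [g for g in gates if g.parent is None]
    if len(roots) != 1:
        raise TemplateError(
            f"template must have exactly one root gate, found {len(roots)}"
        )
    return GatingTemplate(channels=channels, gates=gates, spillover=spill,
                          transforms=transforms)


def read_gating_template(path: str | Path) -> GatingTemplate:
    """Read the JSON gating-template dialect into a validated template."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TemplateError(f"{path}: not valid JSON: {exc}") from exc
    return template_from_dict(doc)


def write_gating_template(template: GatingTemplate, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(template_to_dict(template), indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------- metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Study metadata CSV -> DataFrame indexed by unique ``sample_id``.

    Columns whose every non-empty value parses as an ISO-8601 date become
    datetime columns; everything else stays as string/category.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise MetadataError(f"{path}: metadata requires a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise MetadataError(f"{path}: duplicate sample_id rows: {dups}")
    for col in df.columns:
        if col == "sample_id":
            continue
        vals = df[col][df[col] != ""]
        if len(vals) == 0:
            continue
        try:
            parsed = pd.to_datetime(vals, format="ISO8601")
        except (ValueError, TypeError):
            continue
        df[col] = pd.to_datetime(df[col].replace("", pd.NaT), format="ISO8601")
        del parsed
    return df


# ---------------------------------------------------------------- QA tasks

TASK_COLUMNS = ["qaID", "qaName", "description", "qaLevel", "pop", "formula",
                "plotType", "outlier_func", "params"]
PLOT_TYPES = ("xyplot", "bwplot", "densityplot")
POP_MODES = ("auto", "exact", "path", "substring", "regex")


@dataclass(frozen=True)
class QaTaskDef:
    """One parsed row of the task-definition CSV."""

    qaID: int
    qaName: str
    description: str
    qaLevel: str
    pop: str
    pop_mode: str
    formula: Formula
    plotType: str
    outlier_func: str
    params: dict = field(default_factory=dict)
    rFunc: str | None = None


def _parse_params(text: str) -> dict:
    """``lBound=0.8;z.cutoff=3`` -> {"lBound": 0.8, "z_cutoff": 3.0}."""
    out: dict = {}
    if not text or not text.strip():
        return out
    for item in text.replace(",", ";").split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise MetadataError(f"task parameter {item!r} is not key=value")
        k, v = item.split("=", 1)
        k = k.strip().replace(".", "_")
        v = v.strip()
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out


def read_task_defs(path: str | Path) -> list[QaTaskDef]:
    """Read the QA-task CSV; duplicate qaID or an unparsable formula is fatal."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in TASK_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: task CSV missing columns: {missing}")
    if df["qaID"].duplicated().any():
        dups = sorted(set(df.loc[df["qaID"].duplicated(), "qaID"]))
        raise MetadataError(f"{path}: duplicate qaID values: {dups}")
    tasks: list[QaTaskDef] = []
    for i, row in df.iterrows():
        try:
            formula = parse_formula(row["formula"])
        except FormulaError as exc:
            raise MetadataError(
                f"{path}: row {i + 1} (qaID={row['qaID']}): {exc}"
            ) from exc
        plot_type = row["plotType"].strip()
        if plot_type not in PLOT_TYPES:
            raise MetadataError(
                f"{path}: row {i + 1}: unknown plotType {plot_type!r} "
                f"(supported: {', '.join(PLOT_TYPES)})"
            )
        mode = (row.get("popMode") or "auto").strip() or "auto"
        if mode not in POP_MODES:
            raise MetadataError(f"{path}: row {i + 1}: unknown popMode {mode!r}")
        tasks.append(
            QaTaskDef(
                qaID=int(row["qaID"]),
                qaName=row["qaName"],
                description=row["description"],
                qaLevel=row["qaLevel"],
                pop=row["pop"],
                pop_mode=mode,
                formula=formula,
                plotType=plot_type,
                outlier_func=row["outlier_func"].strip(),
                params=_parse_params(row["params"]),
                rFunc=(row.get("rFunc") or "").strip() or None,
            )
        )
    return tasks
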