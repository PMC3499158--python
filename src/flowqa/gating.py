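"""Hierarchical gating: gate geometry, per-node event bit masks, statistics.

A :class:`GatingHierarchy` mirrors the tree of manual gates applied to one
sample. The sample's events are stored once; each node carries a boolean
bit mask over events, with ``child mask ⊆ parent mask`` by construction.
A :class:`GatingSet` applies one shared template to many samples.

Gates are defined in *transformed* (display) coordinates; gating happens
after spillover compensation and per-channel transformation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import GatingError, TemplateError
from .fcs import Sample
from .transforms import (
    QuantizedTransform,
    SpilloverMatrix,
    Transform,
    compensate,
    make_transform,
)

__all__ = [
    "GateDef",
    "GatingTemplate",
    "GatingHierarchy",
    "GatingSet",
    "in_gate",
    "apply_template",
    "match_populations",
    "population_stats",
    "boundary_event_fraction",
    "ROOT_NAME",
]

ROOT_NAME = "root"
GATE_KINDS = ("rect", "polygon", "interval", "bool")
MFI_GATE_MARKER = "MFI"


@dataclass(frozen=True)
class GateDef:
    """One gate: geometry over 1-2 transformed channels, or a boolean combo.

    geometry:
      rect     -> ((xmin, xmax), (ymin, ymax)), +-inf allowed
      interval -> (min, max) over one dim
      polygon  -> list of >= 3 (x, y) vertices
      bool     -> bool_op in {AND, OR, NOT} with operand node names
    """

    name: str
    parent: str | None
    kind: str
    dims: tuple[str, ...] = ()
    geometry: tuple = ()
    bool_op: str | None = None
    operands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise TemplateError(f"gate {self.name!r}: unknown gate type {self.kind!r}")
        if self.kind == "rect":
            if len(self.dims) != 2 or len(self.geometry) != 2:
                raise TemplateError(f"gate {self.name!r}: rect needs 2 dims and 2 ranges")
            for lo, hi in self.geometry:
                if not lo < hi:
                    raise TemplateError(f"gate {self.name!r}: rect range min must be < max")
        elif self.kind == "interval":
            if len(self.dims) != 1:
                raise TemplateError(f"gate {self.name!r}: interval needs exactly 1 dim")
            lo, hi = self.geometry
            if not lo < hi:
                raise TemplateError(f"gate {self.name!r}: interval min must be < max")
        elif self.kind == "polygon":
            if len(self.dims) != 2:
                raise TemplateError(f"gate {self.name!r}: polygon needs 2 dims")
            if len(self.geometry) < 3:
                raise TemplateError(
                    f"gate {self.name!r}: polygon needs >= 3 vertices, got {len(self.geometry)}"
                )
        else:  # bool
            if self.bool_op not in ("AND", "OR", "NOT"):
                raise TemplateError(f"gate {self.name!r}: bool_op must be AND/OR/NOT")
            if self.bool_op == "NOT" and len(self.operands) != 1:
                raise TemplateError(f"gate {self.name!r}: NOT takes exactly one operand")
            if self.bool_op in ("AND", "OR") and len(self.operands) < 2:
                raise TemplateError(f"gate {self.name!r}: {self.bool_op} takes >= 2 operands")


@dataclass
class GatingTemplate:
    """Shared study template: channel universe, compensation, transforms, gates."""

    channels: list[str]
    gates: list[GateDef]
    spillover: SpilloverMatrix | None = None
    transforms: dict[str, Transform] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.channels)
        seen: dict[str | None, set[str]] = {}
        names = {g.name for g in self.gates}
        for g in self.gates:
            sibs = seen.setdefault(g.parent, set())
            if g.name in sibs:
                raise TemplateError(f"duplicate gate name {g.name!r} under {g.parent!r}")
            sibs.add(g.name)
            if g.parent is not None and g.parent not in names:
                raise TemplateError(f"gate {g.name!r}: unknown parent {g.parent!r}")
            for ch in g.dims:
                if ch not in universe:
                    raise TemplateError(f"gate {g.name!r}: channel {ch!r} not in channel universe")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {g.name: g.parent for g in self.gates}
        for name in parent:
            seen = set()
            node: str | None = name
            while node is not None:
                if node in seen:
                    raise TemplateError(f"cyclic parent references at gate {name!r}")
                seen.add(node)
                node = parent.get(node)

    def children_of(self, parent: str | None) -> list[GateDef]:
        return [g for g in self.gates if g.parent == parent]

    def transform_for(self, channel: str) -> Transform:
        tr = self.transforms.get(channel)
        if tr is None:
            raise GatingError(f"no transform defined for channel {channel!r}")
        return tr


# ---------------------------------------------------------------- geometry


def _points_on_segment(px, py, x0, y0, x1, y1) -> np.ndarray:
    cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
    on_line = np.abs(cross) <= 1e-12 * max(1.0, abs(x1 - x0) + abs(y1 - y0)) * (
        np.abs(px) + np.abs(py) + 1.0
    )
    within = (px >= min(x0, x1) - 1e-300) & (px <= max(x0, x1) + 1e-300) & (
        py >= min(y0, y1)
    ) & (py <= max(y0, y1))
    return on_line & within


def _polygon_mask(px: np.ndarray, py: np.ndarray, verts) -> np.ndarray:
    """Even-odd ray casting; points on an edge count as inside.

    Handles self-intersecting polygons (even-odd rule) and vertical edges
    without crossing-count flicker: the horizontal ray crosses an edge when
    one endpoint is strictly above and the other at-or-below the point.
    """
    verts = np.asarray(verts, dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        on_edge |= _points_on_segment(px, py, x0, y0, x1, y1)
        crosses = (y0 > py) != (y1 > py)
        if not crosses.any():
            continue
        # x coordinate where the edge meets the ray
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < x_at)
    return inside | on_edge


def in_gate(points: np.ndarray, gate: GateDef) -> np.ndarray:
    """Membership bit vector for *points* (columns ordered as gate.dims).

    Rect/interval use half-open [min, max) per dimension; polygon edges
    count as inside. Boolean gates are resolved by the hierarchy, not here.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if gate.kind == "interval":
        lo, hi = gate.geometry
        x = points[:, 0]
        return (x >= lo) & (x < hi)
    if gate.kind == "rect":
        (xlo, xhi), (ylo, yhi) = gate.geometry
        x, y = points[:, 0], points[:, 1]
        return (x >= xlo) & (x < xhi) & (y >= ylo) & (y < yhi)
    if gate.kind == "polygon":
        return _polygon_mask(points[:, 0], points[:, 1], gate.geometry)
    raise GatingError(f"boolean gate {gate.name!r} has no geometry of its own")


# ---------------------------------------------------------------- hierarchy


@dataclass
class GateNode:
    gate: GateDef | None  # None for the root
    path: str
    parent: "GateNode | None"
    mask: np.ndarray
    children: list["GateNode"] = field(default_factory=list)

    @property
    def name(self) -> str:
        return ROOT_NAME if self.gate is None else self.gate.name

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.mask))


class GatingHierarchy:
    """One gated sample: the event data plus the per-node bit masks."""

    def __init__(self, sample: Sample, template: GatingTemplate,
                 transformed: np.ndarray, root: GateNode):
        self.sample = sample
        self.template = template
        self.transformed = transformed  # events in display coordinates
        self.root = root
        self._by_path = {n.path: n for n in self.walk()}

    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def nodes(self) -> list[GateNode]:
        return list(self.walk())

    def node(self, path: str) -> GateNode:
        try:
            return self._by_path[path]
        except KeyError:
            raise GatingError(
                f"no node {path!r} in hierarchy for {self.sample.sample_id}"
            ) from None

    def channel_values(self, channel: str, node: GateNode | None = None) -> np.ndarray:
        col = self.sample.channel_index(channel)
        vals = self.transformed[:, col]
        return vals if node is None else vals[node.mask]


def apply_template(
    sample: Sample,
    template: GatingTemplate,
    quantize_bins: int | None = None,
) -> GatingHierarchy:
    """Compensate, transform and gate one sample through the template.

    With ``quantize_bins`` set, each channel transform is replaced by its
    tabulated piecewise-linear interpolation (the mechanism by which manual
    gating software applies display transforms); ``None`` uses the exact
    transform.
    """
    missing = {ch for g in template.gates for ch in g.dims} - set(sample.channel_names)
    if missing:
        raise GatingError(
            f"sample {sample.sample_id}: template channels missing: {sorted(missing)}"
        )
    events = sample.events
    if template.spillover is not None:
        events = compensate(events, template.spillover, sample.channel_names)
    transformed = np.array(events, dtype=float, copy=True)
    for ch, tr in template.transforms.items():
        if ch not in sample.channel_names:
            continue
        if quantize_bins is not None:
            tr = QuantizedTransform(tr, n_bins=quantize_bins)
        transformed[:, sample.channel_index(ch)] = tr.forward(
            events[:, sample.channel_index(ch)]
        )

    n = sample.n_events
    root = GateNode(gate=None, path="/", parent=None, mask=np.ones(n, dtype=bool))
    by_name_under: dict[tuple[str | None, str], GateNode] = {}

    def build(parent_node: GateNode, parent_name: str | None) -> None:
        for g in template.children_of(parent_name):
            if g.kind == "bool":
                member = _eval_bool(g, parent_name)
            else:
                cols = [sample.channel_index(d) for d in g.dims]
                member = in_gate(transformed[:, cols], g)
            mask = parent_node.mask & member
            path = (parent_node.path.rstrip("/") + "/" + g.name) or "/" + g.name
            node = GateNode(gate=g, path=path, parent=parent_node, mask=mask)
            parent_node.children.append(node)
            by_name_under[(parent_name, g.name)] = node
            build(node, g.name)

    def _eval_bool(g: GateDef, parent_name: str | None) -> np.ndarray:
        ops = []
        for ref in g.operands:
            node = by_name_under.get((parent_name, ref))
            if node is None:
                raise GatingError(
                    f"bool gate {g.name!r}: operand {ref!r} not defined among siblings"
                )
            ops.append(node.mask)
        if g.bool_op == "NOT":
            return ~ops[0]
        if g.bool_op == "AND":
            out = ops[0].copy()
            for m in ops[1:]:
                out &= m
            return out
        out = ops[0].copy()
        for m in ops[1:]:
            out |= m
        return out

    build(root, None)
    return GatingHierarchy(sample, template, transformed, root)


class GatingSet:
    """A collection of samples gated through one shared template."""

    def __init__(self, template: GatingTemplate):
        self.template = template
        self.hierarchies: dict[str, GatingHierarchy] = {}

    def gate(self, sample: Sample, quantize_bins: int | None = None) -> GatingHierarchy:
        h = apply_template(sample, self.template, quantize_bins=quantize_bins)
        self.hierarchies[sample.sample_id] = h
        return h

    def __iter__(self):
        return iter(self.hierarchies.values())

    def __len__(self) -> int:
        return len(self.hierarchies)

    def __getitem__(self, sample_id: str) -> GatingHierarchy:
        return self.hierarchies[sample_id]

    @property
    def node_paths(self) -> list[str]:
        if not self.hierarchies:
            tpl_paths = ["/"]
            by_name = {g.name: g for g in self.template.gates}

            def path_of(g: GateDef) -> str:
                parts = [g.name]
                p = g.parent
                while p is not None:
                    parts.append(p)
                    p = by_name[p].parent
                return "/" + "/".join(reversed(parts))

            return tpl_paths + [path_of(g) for g in self.template.gates]
        first = next(iter(self.hierarchies.values()))
        return [n.path for n in first.walk()]


def match_populations(
    gs: GatingSet | list[str], pattern: str, mode: str = "substring"
) -> list[str]:
    """Resolve a population pattern to node paths.

    modes: ``exact`` (unique terminal name; ambiguity is an error), ``path``
    (full "/A/B" path), ``substring`` and ``regex`` (all matching terminal
    names, possibly many).
    """
    if not pattern:
        raise GatingError("empty population pattern")
    paths = gs if isinstance(gs, list) else gs.node_paths
    non_root = [p for p in paths if p != "/"]
    terminal = {p: p.rsplit("/", 1)[-1] for p in non_root}
    if mode == "path":
        if pattern in paths:
            return [pattern]
        raise GatingError(f"no node with path {pattern!r}")
    if mode == "exact":
        hits = [p for p, name in terminal.items() if name == pattern]
        if not hits:
            raise GatingError(f"no node named {pattern!r}")
        if len(hits) > 1:
            raise GatingError(
                f"population name {pattern!r} is ambiguous; matches: {sorted(hits)}"
            )
        return hits
    if mode == "substring":
        return sorted(p for p, name in terminal.items() if pattern in name)
    if mode == "regex":
        rx = re.compile(pattern)
        return sorted(p for p, name in terminal.items() if rx.search(name))
    raise GatingError(f"unknown population match mode {mode!r}")


def population_stats(h: GatingHierarchy, mfi_stat: str = "median") -> list[dict]:
    """Per-node statistics: count, proportion of parent, and per-dim MFI.

    Root proportion is exactly 1; an empty parent makes the proportion
    missing (None); an empty population has MFI missing. MFI is the median
    (default) or mean of each gate-dimension channel on the transformed
    scale, over the node's in-mask events.
    """
    if mfi_stat not in ("median", "mean"):
        raise ValueError("mfi_stat must be 'median' or 'mean'")
    reduce = np.median if mfi_stat == "median" else np.mean
    out: list[dict] = []
    for node in h.walk():
        count = node.count
        if node.parent is None:
            proportion: float | None = 1.0
        else:
            pc = node.parent.count
            proportion = (count / pc) if pc else None
        rec = {
            "population": node.path,
            "count": count,
            "proportion": proportion,
            "mfi": {},
        }
        if node.gate is not None and node.gate.kind != "bool":
            for ch in node.gate.dims:
                vals = h.channel_values(ch, node)
                rec["mfi"][ch] = float(reduce(vals)) if count else None
        out.append(rec)
    return out


def boundary_event_fraction(
    sample: Sample, channel: str, qt: QuantizedTransform
) -> float:
    """Fraction of events clamped at either end of the quantized table domain."""
    if sample.n_events == 0:
        return 0.0
    x = sample.events[:, sample.channel_index(channel)]
    return float(np.count_nonzero(qt.boundary_mask(x)) / sample.n_events)
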