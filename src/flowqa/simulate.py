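"""Synthetic multi-panel longitudinal flow studies with labelled anomalies.

The generator emulates the structure the QA tasks assume: several subjects,
each contributing aliquots that are stained with multiple antibody panels
(tubes) and acquired on calendar dates across a study window. Events are
drawn in *transformed* (display) space — scatter clouds placed relative to
the template's gates, fluorescence as negative/positive mixtures — and
mapped back to the raw instrument scale through the inverse transform, so
the template gates partition known fractions by construction. Spillover is
applied forward so compensation is meaningful.

Injected anomalies, each recorded in a truth table:

* ``low_lysis``            — poor red-cell lysis: the white-cell fraction drops
* ``mfi_drift``            — a channel's fluorescence drifts with calendar date
* ``spike``                — a transient shift in one acquisition-time window
* ``low_count``            — too few events acquired
* ``aliquot_inconsistency``— one sample's staining departs from its aliquot
* ``boundary_excess``      — events piled at the instrument top of scale
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fcs import Sample, write_fcs
from .gating import GateDef, GatingTemplate
from .transforms import LinearTransform, LogicleTransform, SpilloverMatrix
from .workspace import write_gating_template

__all__ = [
    "StudyConfig",
    "AnomalySpec",
    "SyntheticStudy",
    "default_panels",
    "default_template",
    "default_anomalies",
    "generate_study",
    "inject_drift",
    "write_default_tasks",
]

SCATTER_TOP = 262144.0
FLUOR_CHANNELS = ("FITC-A", "PE-A", "PerCP-A", "APC-A", "PE-Cy7-A")
CHANNELS = ("FSC-A", "SSC-A") + FLUOR_CHANNELS + ("Time",)


def default_panels() -> dict[str, dict[str, str]]:
    """Three staining panels with deliberate redundant staining.

    CD3 (APC) is a backbone marker in every tube, and most other stains
    recur in two tubes — mirroring clinical panel design, where shared
    markers let the QA compare staining consistency across tubes and give
    the per-(channel, stain) strata more than one tube's worth of samples.
    """
    return {
        "CD8/CD25/CD4/CD3/CD62": dict(zip(FLUOR_CHANNELS,
                                          ["CD8", "CD25", "CD4", "CD3", "CD62"])),
        "CD8/CD56/CD33/CD3/HLADR": dict(zip(FLUOR_CHANNELS,
                                            ["CD8", "CD56", "CD33", "CD3", "HLADR"])),
        "CD19/CD56/CD4/CD3/HLADR": dict(zip(FLUOR_CHANNELS,
                                            ["CD19", "CD56", "CD4", "CD3", "HLADR"])),
    }


@dataclass(frozen=True)
class StudyConfig:
    """Study design and population geometry.

    The defaults give the standard test study: 4 subjects x 2 aliquots x 3
    panels = 24 FCS files of 10^4 events spanning 120 calendar days. The
    white-cell fraction (~0.95 with small sample-to-sample spread) sits
    well above the 0.8 lysis threshold; fluorescence mixtures put the
    positive component inside the per-channel MFI gates with >5 robust-sd
    clearance from the gate edges.
    """

    seed: int
    n_subjects: int = 4
    aliquots_per_subject: int = 2
    panels: dict[str, dict[str, str]] = field(default_factory=default_panels)
    events_per_sample: int = 10_000
    date_start: str = "2012-01-01"
    date_span_days: int = 120
    wbc_fraction: float = 0.95
    wbc_fraction_sd: float = 0.012
    mnc_fraction: float = 0.85
    positive_fraction: float = 0.35
    neg_mean: float = 0.9
    pos_mean: float = 3.2
    neg_sd: float = 0.22
    pos_sd: float = 0.18
    # per sample x channel level variation, decades: bounded (uniform on
    # +-jitter), modelling an in-control instrument/reagent process; the
    # out-of-control cases are injected explicitly as anomalies
    pos_mean_jitter: float = 0.05
    neg_mean_jitter: float = 0.03

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("StudyConfig: at least one panel required")
        for frac in (self.wbc_fraction, self.mnc_fraction, self.positive_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("StudyConfig: fractions must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_subjects * self.aliquots_per_subject * len(self.panels)


@dataclass(frozen=True)
class AnomalySpec:
    """One injected anomaly; ``samples`` of ("*",) means study-wide."""

    kind: str
    samples: tuple[str, ...]
    channel: str | None = None
    params: dict = field(default_factory=dict)

    _KINDS = ("mfi_drift", "spike", "low_lysis", "low_count",
              "aliquot_inconsistency", "boundary_excess")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if self.channel is not None and self.channel not in CHANNELS:
            raise ValueError(f"anomaly references absent channel {self.channel!r}")


@dataclass
class SyntheticStudy:
    samples: list[Sample]
    template: GatingTemplate
    metadata: pd.DataFrame
    truth: pd.DataFrame
    paths: dict | None = None


def default_spillover() -> SpilloverMatrix:
    k = len(FLUOR_CHANNELS)
    m = np.eye(k)
    # fixed, modest bleed-through between spectrally adjacent detectors
    bleed = [0.06, 0.04, 0.03, 0.02]
    for i in range(k - 1):
        m[i, i + 1] = bleed[i % len(bleed)]
        m[i + 1, i] = 0.5 * bleed[i % len(bleed)]
    return SpilloverMatrix(FLUOR_CHANNELS, m)


def default_template(logicle: LogicleTransform | None = None) -> GatingTemplate:
    """The study QA template: WBC gate, MNC gate, per-channel MFI/margin gates.

    WBC_perct is the root gate (its proportion is of all acquired events —
    the red-cell lysis readout); the mononuclear gate MNC nests inside it,
    and each fluorescence channel carries an "<channel> MFI" interval gate
    over its positive population and an "<channel> margin" interval gate at
    the top of scale for boundary events.
    """
    logicle = logicle or LogicleTransform()
    M = logicle.M
    gates = [
        GateDef(name="WBC_perct", parent=None, kind="rect",
                dims=("FSC-A", "SSC-A"),
                geometry=((80_000.0, math.inf), (-math.inf, math.inf))),
        GateDef(name="MNC", parent="WBC_perct", kind="polygon",
                dims=("FSC-A", "SSC-A"),
                geometry=((100_000.0, 20_000.0), (200_000.0, 20_000.0),
                          (200_000.0, 140_000.0), (100_000.0, 140_000.0))),
    ]
    for ch in FLUOR_CHANNELS:
        gates.append(GateDef(name=f"{ch} MFI", parent="MNC", kind="interval",
                             dims=(ch,), geometry=(2.3, 4.3)))
        gates.append(GateDef(name=f"{ch} margin", parent="MNC", kind="interval",
                             dims=(ch,), geometry=(M - 0.05, math.inf)))
    transforms: dict = {ch: logicle for ch in FLUOR_CHANNELS}
    transforms["FSC-A"] = LinearTransform(T=SCATTER_TOP)
    transforms["SSC-A"] = LinearTransform(T=SCATTER_TOP)
    transforms["Time"] = LinearTransform(T=1e9)
    return GatingTemplate(channels=list(CHANNELS), gates=gates,
                          spillover=default_spillover(), transforms=transforms)


def sample_ids(cfg: StudyConfig) -> list[str]:
    ids = []
    for s in range(1, cfg.n_subjects + 1):
        for a in range(1, cfg.aliquots_per_subject + 1):
            for t in range(1, len(cfg.panels) + 1):
                ids.append(f"s{s:02d}_a{a}_t{t}")
    return ids


def build_metadata(cfg: StudyConfig) -> pd.DataFrame:
    start = pd.Timestamp(cfg.date_start)
    n_aliquots = cfg.n_subjects * cfg.aliquots_per_subject
    rows = []
    k = 0
    for s in range(1, cfg.n_subjects + 1):
        for a in range(1, cfg.aliquots_per_subject + 1):
            frac = k / max(n_aliquots - 1, 1)
            date = start + pd.Timedelta(days=round(cfg.date_span_days * frac))
            for t, tube in enumerate(cfg.panels, start=1):
                rows.append(dict(
                    sample_id=f"s{s:02d}_a{a}_t{t}",
                    subject=f"subj{s:02d}",
                    coresampleid=f"subj{s:02d}-al{a}",
                    Tube=tube,
                    RecdDt=date,
                ))
            k += 1
    return pd.DataFrame(rows)


def default_anomalies(cfg: StudyConfig, drift_slope: float = 0.004,
                      spike_magnitude: float = 2.0,
                      aliquot_offset: float = 0.6) -> list[AnomalySpec]:
    """The standard anomaly panel for the default study.

    Deterministic sample assignments (by position in the sample roster) so
    truth labels are independent of the event-level random stream.
    """
    ids = sample_ids(cfg)

    def pick(i: int) -> str:
        return ids[i % len(ids)]

    return [
        AnomalySpec("mfi_drift", ("*",), "FITC-A", {"slope": drift_slope}),
        AnomalySpec("low_lysis", (pick(1), pick(13)), None, {"target": 0.70}),
        AnomalySpec("spike", (pick(5),), "PE-A",
                    {"magnitude": spike_magnitude, "window": (0.45, 0.50)}),
        AnomalySpec("low_count", (pick(9),), None, {"count": 2500}),
        AnomalySpec("aliquot_inconsistency", (pick(3), pick(16)), "PerCP-A",
                    {"offset": aliquot_offset}),
        AnomalySpec("aliquot_inconsistency", (pick(20),), "PE-Cy7-A",
                    {"offset": aliquot_offset}),
        AnomalySpec("boundary_excess", (pick(7),), "APC-A", {"fraction": 0.05}),
    ]


def inject_drift(samples: list[Sample], channel: str, slope: float,
                 dates: list[pd.Timestamp],
                 transform: LogicleTransform) -> list[Sample]:
    """Shift a channel's fluorescence with calendar date (display units/day).

    The whole mixture is shifted in transformed space by
    ``slope * (date - first date)``, which moves the positive-component
    mean by exactly that amount; slope 0 is the identity.
    """
    if slope == 0:
        return samples
    t0 = min(dates)
    out = []
    for sample, date in zip(samples, dates):
        delta = slope * (date - t0).days
        if delta == 0:
            out.append(sample)
            continue
        col = sample.channel_index(channel)
        events = sample.events.copy()
        events[:, col] = transform.inverse(transform.forward(events[:, col]) + delta)
        out.append(Sample(sample.sample_id, events, sample.channel_names,
                          sample.stain_names, dict(sample.keywords),
                          sample.time_channel))
    return out


def _anomalies_for(anomalies: list[AnomalySpec], sid: str, kind: str):
    return [a for a in anomalies
            if a.kind == kind and (a.samples == ("*",) or sid in a.samples)]


def generate_study(cfg: StudyConfig, anomalies: list[AnomalySpec] | None = None,
                   out_dir: str | Path | None = None) -> SyntheticStudy:
    """Draw the full synthetic study; deterministic given ``cfg.seed``.

    With ``out_dir`` set, writes fcs/<sample_id>.fcs, template.json,
    metadata.csv, tasks.csv and truth.csv.
    """
    anomalies = list(anomalies) if anomalies is not None else []
    for a in anomalies:
        if a.samples != ("*",):
            unknown = set(a.samples) - set(sample_ids(cfg))
            if unknown:
                raise ValueError(f"anomaly {a.kind}: unknown samples {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    template = default_template()
    logicle: LogicleTransform = template.transforms["FITC-A"]  # type: ignore[assignment]
    spill = template.spillover
    meta = build_metadata(cfg)
    dates = dict(zip(meta["sample_id"], meta["RecdDt"]))
    tubes = dict(zip(meta["sample_id"], meta["Tube"]))

    truth_rows: list[dict] = []
    samples: list[Sample] = []
    for sid in sample_ids(cfg):
        n = cfg.events_per_sample
        for a in _anomalies_for(anomalies, sid, "low_count"):
            n = int(a.params["count"])
            truth_rows.append(dict(sample_id=sid, kind="low_count", channel="",
                                   param=float(n)))
        p_wbc = float(np.clip(rng.normal(cfg.wbc_fraction, cfg.wbc_fraction_sd),
                              0.0, 1.0))
        for a in _anomalies_for(anomalies, sid, "low_lysis"):
            p_wbc = float(a.params["target"])
            truth_rows.append(dict(sample_id=sid, kind="low_lysis", channel="",
                                   param=p_wbc))

        # --- scatter: debris / lymphocyte-monocyte (MNC) / granulocyte
        is_wbc = rng.random(n) < p_wbc
        is_mnc = is_wbc & (rng.random(n) < cfg.mnc_fraction)
        is_gran = is_wbc & ~is_mnc
        fsc = np.empty(n)
        ssc = np.empty(n)
        nd = int((~is_wbc).sum())
        fsc[~is_wbc] = rng.normal(20_000, 6_000, nd)
        ssc[~is_wbc] = rng.normal(30_000, 10_000, nd)
        nm = int(is_mnc.sum())
        fsc[is_mnc] = rng.normal(150_000, 12_000, nm)
        ssc[is_mnc] = rng.normal(70_000, 12_000, nm)
        ng = int(is_gran.sum())
        fsc[is_gran] = rng.normal(150_000, 15_000, ng)
        ssc[is_gran] = rng.normal(200_000, 15_000, ng)
        fsc = np.clip(fsc, 0, SCATTER_TOP - 1)
        ssc = np.clip(ssc, 0, SCATTER_TOP - 1)

        # --- fluorescence mixtures in display space
        delta_days = (dates[sid] - meta["RecdDt"].min()).days
        display = {}
        for ch in FLUOR_CHANNELS:
            pos_mu = cfg.pos_mean + rng.uniform(-cfg.pos_mean_jitter,
                                                cfg.pos_mean_jitter)
            neg_mu = cfg.neg_mean + rng.uniform(-cfg.neg_mean_jitter,
                                                cfg.neg_mean_jitter)
            is_pos = rng.random(n) < cfg.positive_fraction
            vals = np.where(is_pos,
                            rng.normal(pos_mu, cfg.pos_sd, n),
                            rng.normal(neg_mu, cfg.neg_sd, n))
            for a in _anomalies_for(anomalies, sid, "aliquot_inconsistency"):
                if a.channel == ch:
                    vals = vals + float(a.params["offset"])
                    truth_rows.append(dict(sample_id=sid,
                                           kind="aliquot_inconsistency",
                                           channel=ch,
                                           param=float(a.params["offset"])))
            for a in _anomalies_for(anomalies, sid, "mfi_drift"):
                if a.channel == ch:
                    vals = vals + float(a.params["slope"]) * delta_days
            for a in _anomalies_for(anomalies, sid, "spike"):
                if a.channel == ch:
                    lo, hi = a.params.get("window", (0.45, 0.50))
                    i0, i1 = int(lo * n), int(hi * n)
                    vals[i0:i1] = vals[i0:i1] + float(a.params["magnitude"])
                    truth_rows.append(dict(sample_id=sid, kind="spike",
                                           channel=ch,
                                           param=float(a.params["magnitude"])))
            display[ch] = vals

        raw_true = np.column_stack(
            [np.asarray(logicle.inverse(display[ch])) for ch in FLUOR_CHANNELS]
        )
        for a in _anomalies_for(anomalies, sid, "boundary_excess"):
            j = FLUOR_CHANNELS.index(a.channel)
            k = int(round(float(a.params["fraction"]) * n))
            idx = rng.choice(n, size=k, replace=False)
            raw_true[idx, j] = logicle.T
            truth_rows.append(dict(sample_id=sid, kind="boundary_excess",
                                   channel=a.channel,
                                   param=float(a.params["fraction"])))
        observed = raw_true @ spill.matrix if spill is not None else raw_true

        time = np.cumsum(rng.uniform(0.5, 1.5, n))
        events = np.column_stack([fsc, ssc, observed, time])
        stains = ["", ""] + [cfg.panels[tubes[sid]][ch] for ch in FLUOR_CHANNELS] + [""]
        samples.append(Sample(
            sample_id=sid, events=events, channel_names=list(CHANNELS),
            stain_names=stains,
            keywords={"$SRC": tubes[sid], "$DATE": dates[sid].date().isoformat()},
        ))

    for a in anomalies:
        if a.kind == "mfi_drift":
            affected = sample_ids(cfg) if a.samples == ("*",) else list(a.samples)
            for sid in affected:
                truth_rows.append(dict(sample_id=sid, kind="mfi_drift",
                                       channel=a.channel,
                                       param=float(a.params["slope"])))

    truth = pd.DataFrame(truth_rows,
                         columns=["sample_id", "kind", "channel", "param"])
    study = SyntheticStudy(samples=samples, template=template, metadata=meta,
                           truth=truth)
    if out_dir is not None:
        study.paths = write_study(study, out_dir)
    return study


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    fcs_dir = out / "fcs"
    fcs_dir.mkdir(parents=True, exist_ok=True)
    for s in study.samples:
        write_fcs(s, fcs_dir / f"{s.sample_id}.fcs")
    tpl = out / "template.json"
    write_gating_template(study.template, tpl)
    meta_csv = out / "metadata.csv"
    meta = study.metadata.copy()
    meta["RecdDt"] = meta["RecdDt"].dt.date.astype(str)
    meta.to_csv(meta_csv, index=False)
    truth_csv = out / "truth.csv"
    study.truth.to_csv(truth_csv, index=False)
    tasks_csv = out / "tasks.csv"
    write_default_tasks(tasks_csv)
    return {"fcs_dir": fcs_dir, "template": tpl, "metadata": meta_csv,
            "tasks": tasks_csv, "truth": truth_csv}


DEFAULT_TASKS = [
    # qaID, qaName, description, qaLevel, pop, formula, plotType,
    # outlier_func, params, rFunc, popMode
    (1, "RBCLysis", "Sufficient RBC lysis", "Tube", "WBC_perct",
     "proportion~RecdDt|Tube", "xyplot", "cutoff", "lBound=0.8", "", ""),
    (2, "MFIvsTime", "Fluorescence stability vs time", "Assay", "MFI",
     "MFI~RecdDt|channel*stain", "xyplot", "norm", "z.cutoff=3", "rlm", ""),
    (3, "MNCConsistency", "Consistency of the MNC gate across aliquots",
     "Assay", "MNC", "proportion~coresampleid", "bwplot", "qoutlier", "", "", ""),
    # 2% off-scale tolerance: brief saturation transients (e.g. during a
    # fluorescence spike) stay below it; persistent pile-up does not.
    (4, "BoundaryEvents", "Excess boundary events", "Channel", "margin",
     "proportion~RecdDt|Tube", "xyplot", "cutoff", "uBound=0.02", "", "substring"),
    (5, "TotalCount", "Sufficient events acquired", "Tube", "/",
     "count~RecdDt|Tube", "xyplot", "cutoff", "lBound=5000", "", "path"),
    # The spike score's null depends on window occupancy (events per bin);
    # 0.85 is the ~99.9th percentile of the null at the nominal 10^4-event
    # acquisition. Sub-nominal event counts inflate the score and are
    # already flagged by TotalCount.
    (6, "SpikeCheck", "Acquisition-time spikes per channel", "Channel", "/",
     "spike~RecdDt|channel", "xyplot", "cutoff", "uBound=0.85", "", "path"),
]


def write_default_tasks(path: str | Path) -> Path:
    """Write the default QA task roster as a task-definition CSV."""
    cols = ["qaID", "qaName", "description", "qaLevel", "pop", "formula",
            "plotType", "outlier_func", "params", "rFunc", "popMode"]
    df = pd.DataFrame(DEFAULT_TASKS, columns=cols)
    df.to_csv(path, index=False)
    return Path(path)
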