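"""End-to-end orchestration: configuration, stage running, manifests.

Stages: ``call`` (PSI + CE calling), ``nmd`` (rescue / dark / true-dark),
``dose`` (responsiveness staging), ``biomarker`` (marker stats + burden),
``seqfeat`` (motif and binding features).  ``biomarker`` and ``seqfeat``
depend on ``call``.  All thresholds default to the analysis's stated
values and travel in one :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    CohortDesign,
    read_annotation,
    read_design,
    read_intervals,
    read_junctions,
    write_table,
    SequenceStore,
)
from . import biomarker_burden as bb
from . import dose_response as dr
from . import nmd_localization as nmd
from . import sequence_features as sf
from . import splicing_core as sc

logger = logging.getLogger(__name__)

STAGES = ("call", "nmd", "dose", "biomarker", "seqfeat")
_STAGE_DEPS = {"biomarker": ("call",), "seqfeat": ("call",)}


@dataclass
class RunConfig:
    """Paths plus every tunable threshold of the analysis."""

    junctions: str | None = None
    junctions_dialect: str = "leafcutter_counts"
    annotation: str | None = None
    design: str | None = None
    fasta: str | None = None
    clip: str | None = None
    kd_junctions: str | None = None
    kd_nmdi_junctions: str | None = None
    out_dir: str = "crypticburden_out"
    seed: int = 0
    # thresholds (the analysis's identity)
    control_max: float = sc.DEFAULT_CONTROL_MAX
    min_dpsi: float = sc.DEFAULT_MIN_DPSI
    rescue_threshold: float = nmd.DEFAULT_RESCUE_THRESHOLD
    fpr_max: float = bb.DEFAULT_FPR_MAX
    tpr_min: float = bb.DEFAULT_TPR_MIN
    min_case_samples: int = bb.DEFAULT_MIN_CASE_SAMPLES
    min_reads: int = bb.DEFAULT_MIN_READS_PER_SAMPLE
    min_detect_samples: int = bb.DEFAULT_MIN_DETECT_SAMPLES
    window: int = sf.DEFAULT_PROFILE_WINDOW
    radius: int = sf.DEFAULT_BOUND_RADIUS
    logo_length: int = sf.DEFAULT_LOGO_LENGTH
    background_n: int = sf.DEFAULT_BACKGROUND_N
    min_cluster_reads: int = sc.DEFAULT_MIN_CLUSTER_READS
    min_fraction: float = sc.DEFAULT_MIN_FRACTION
    min_support: int = dr.DEFAULT_MIN_SUPPORT
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = {k: v for k, v in data.items() if k not in known}
        data = {k: v for k, v in data.items() if k in known}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.extra.update(extra)
        return cfg

    def validate(self) -> None:
        for name in ("control_max", "min_dpsi", "rescue_threshold",
                     "fpr_max", "tpr_min", "min_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_case_samples", "min_reads", "min_detect_samples",
                     "min_cluster_reads", "min_support", "window", "radius",
                     "logo_length", "background_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    if config.junctions is None or config.design is None:
        raise ValueError("pipeline needs --junctions and --design")
    table = read_junctions(config.junctions, config.junctions_dialect)
    table = sc.filter_cluster_junctions(table, config.min_fraction)
    design = read_design(config.design)
    design.validate_against(table)
    ann = read_annotation(config.annotation) if config.annotation else None
    return table, design, ann


def _categories(table, ann) -> pd.Series:
    if ann is not None:
        return sc.classify_junctions(table.junctions, ann)
    # without annotation nothing can be called annotated; the placeholder
    # keeps every junction eligible for CE calling
    return pd.Series("none", index=table.junction_ids, name="category")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ("call",)) -> Path:
    """Run the requested stages, writing one TSV per product plus a
    manifest with input checksums, the config, and per-stage wall time.

    Returns the output directory.
    """
    config.validate()
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in stages:
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "stages": {},
    }
    for key in ("junctions", "annotation", "design", "fasta", "clip",
                "kd_junctions", "kd_nmdi_junctions"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    table, design, ann = _load_inputs(config)
    categories = _categories(table, ann)
    psi = sc.compute_psi(table, config.min_cluster_reads)
    events = None

    for stage in stages:
        t0 = time.monotonic()
        if stage == "call":
            events = sc.call_cryptic_events(
                psi, design, categories,
                control_max=config.control_max, min_dpsi=config.min_dpsi,
                annotation=ann,
            )
            write_table(sc.events_to_frame(events), out / "events.tsv")
            logger.info("call: %d junction(s) in, %d event(s) out",
                        table.n_junctions, len(events))
        elif stage == "nmd":
            _run_nmd_stage(config, out)
        elif stage == "dose":
            series = dr.dose_series_from_psi(psi, design)
            rows = []
            for jid, s in series.items():
                kept = dr.filter_support(s, config.min_support)
                rows.append({
                    "junction_id": jid,
                    "response_class": dr.classify_responsiveness(kept)
                    if kept is not None else "excluded",
                })
            write_table(pd.DataFrame(rows), out / "response_classes.tsv")
        elif stage == "biomarker":
            z = bb.zscore_psi(psi)
            detection = bb.detection_flags(
                table, design, config.min_reads, config.min_detect_samples)
            markers = bb.evaluate_markers(
                z, design, detection, config.fpr_max, config.tpr_min,
                config.min_case_samples)
            if events is not None:
                event_ids = {e.id for e in events} | {
                    e.partner.id for e in events if e.partner}
                markers = markers.loc[markers.index.isin(event_ids)]
            predictive = bb.select_predictive(markers)
            write_table(markers.reset_index(names="junction_id"),
                        out / "markers.tsv")
            if predictive:
                burden = bb.compute_burden(z, predictive)
                burden_df = burden.reset_index()
                burden_df.columns = ["sample_id", "burden"]
                burden_df["class"] = design.classes(burden_df["sample_id"]).values
                write_table(burden_df, out / "burden.tsv")
            else:
                logger.warning("biomarker: no predictive junctions; "
                               "burden not computed")
        elif stage == "seqfeat":
            _run_seqfeat_stage(config, events or [], ann, out)
        manifest["stages"][stage] = {
            "wall_time_s": round(time.monotonic() - t0, 3)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _run_nmd_stage(config: RunConfig, out: Path) -> None:
    """Call CEs separately under KD and KD+NMDi, then classify rescue and
    darkness.  Requires kd/kd_nmdi junction tables sharing the control
    samples (design rows select conditions by nmd_condition)."""
    if not (config.kd_junctions and config.kd_nmdi_junctions and config.design):
        raise ValueError("nmd stage needs kd_junctions, kd_nmdi_junctions "
                         "and design")
    design = read_design(config.design)
    results = {}
    for key, path in (("kd", config.kd_junctions),
                      ("kd_nmdi", config.kd_nmdi_junctions)):
        table = read_junctions(path, config.junctions_dialect)
        table = sc.filter_cluster_junctions(table, config.min_fraction)
        ann = read_annotation(config.annotation) if config.annotation else None
        psi = sc.compute_psi(table, config.min_cluster_reads)
        cats = _categories(table, ann)
        sub = CohortDesign(design.table.loc[
            design.table["sample_id"].isin(table.sample_ids)].copy())
        events = sc.call_cryptic_events(
            psi, sub, cats, config.control_max, config.min_dpsi, annotation=ann)
        case_samples = [s for s in table.sample_ids if sub.is_case([s]).iloc[0]]
        results[key] = (events, psi.group_mean(case_samples))
    events_kd, mean_kd = results["kd"]
    events_nmdi, mean_nmdi = results["kd_nmdi"]
    ids = sorted({e.id for e in events_kd} | {e.id for e in events_nmdi})
    calls = nmd.classify_nmd(ids, mean_kd.to_dict(), mean_nmdi.to_dict(),
                             config.rescue_threshold)
    dark = nmd.detect_dark(events_kd, events_nmdi)
    dark_ids = {e.id for e in dark}
    rows = [
        {"event_id": c.event_id, "psi_kd": c.psi_kd, "psi_kd_nmdi": c.psi_kd_nmdi,
         "delta": c.delta, "nmd_class": c.nmd_class,
         "dark": c.event_id in dark_ids}
        for c in calls
    ]
    write_table(pd.DataFrame(rows), out / "nmd_calls.tsv")


def _run_seqfeat_stage(config: RunConfig, events, ann, out: Path) -> None:
    if not config.fasta:
        raise ValueError("seqfeat stage needs a fasta")
    genome = SequenceStore.from_fasta(config.fasta)
    junctions = [e.junction for e in events]
    ppm = sf.donor_downstream_ppm(junctions, genome, config.logo_length)
    write_table(ppm.reset_index(), out / "donor_ppm.tsv")
    if config.clip:
        peaks = sf.merge_intervals(read_intervals(config.clip))
        for anchor in ("acceptor", "donor"):
            profile = sf.binding_fraction_profile(
                junctions, peaks, anchor, config.window)
            write_table(profile.reset_index(), out / f"binding_{anchor}.tsv")
        bound = sf.fraction_bound_within(junctions, peaks, config.radius)
        write_table(pd.DataFrame([{"radius": config.radius,
                                   "fraction_bound": bound}]),
                    out / "fraction_bound.tsv")
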