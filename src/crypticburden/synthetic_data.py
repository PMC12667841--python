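"""Synthetic cohorts, knockdown series, NMD experiments, fractionation and
sequences with planted ground truth.

Every generator is deterministic under ``SimulationConfig.seed`` and draws
from a named substream, so adding a stage never perturbs earlier draws.
The statistical model:

* cluster sequencing depth per sample ~ NegativeBinomial(mean, dispersion);
* baseline (control) inclusion PSI ~ Beta(alpha, beta), AT the junction
  level, emulating the near-zero inclusion of repressed cryptic exons;
* planted cryptic events add ``effect_dpsi`` to the PSI of *penetrant*
  case samples (penetrance ~ Bernoulli per case sample);
* knockdown dose response follows a Hill curve
  psi(dose) = psi_max / (1 + (ec50 / dose)^hill) with psi(0) = 0;
* NMD degrades the cryptic *isoform* abundance by a factor (1 - d) before
  PSI is formed, so observed PSI under active NMD is
  psi (1-d) / (psi (1-d) + (1-psi)) — competition renormalisation, which
  reproduces the nonlinear masking of cryptic inclusion.

Truth labels are produced by applying the pipeline's own decision rules to
the NOISELESS latent values, so classifier-recovery tests are exact in the
zero-noise limit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CohortDesign, GenomicJunction, IntervalSet, JunctionTable, SequenceStore
from .splicing_core import DEFAULT_CONTROL_MAX, DEFAULT_MIN_DPSI


@dataclass
class SimulationConfig:
    """Knobs for every generator; defaults are the stated study designs.

    ``cluster_depth_dispersion`` is the negative-binomial shape k
    (variance = mu + mu^2 / k).  ``control_psi_alpha/beta`` give baseline
    inclusion Beta(1, 99), mean 1% — cryptic exons are repressed in
    controls.  ``nmd_degradation`` is the mean fraction of cryptic
    transcripts destroyed by NMD; ``nmd_concentration`` spreads per-event
    degradation as Beta(d*c, (1-d)*c) (None = identical d for all events).
    """

    seed: int = 0
    # cohort
    n_case: int = 40
    n_control: int = 40
    n_clusters: int = 200
    cluster_depth_mean: float = 100.0
    cluster_depth_dispersion: float = 10.0
    ce_fraction: float = 0.15
    effect_dpsi: float = 0.2
    penetrance: float = 0.5
    control_psi_alpha: float = 1.0
    control_psi_beta: float = 99.0
    # dose response (dose value at level i is simply i, i = 1..K)
    dose_levels: int = 5
    n_replicates: int = 3
    hill_coefficient: float = 6.0
    ec50_grid: tuple[float, ...] = (0.8, 2.5, 6.0)
    psi_max: float = 0.5
    # NMD
    nmd_degradation: float = 0.8
    nmd_concentration: float | None = None
    nmd_sensitive_fraction: float = 0.5
    # fractionation
    n_genes: int = 100
    log2_nc_sd: float = 1.0
    nc_depth: float = 10_000.0
    nuclear_retention_fraction: float = 0.0
    nuclear_retention_shift: float = 3.0
    fractionation_concentration: float = 2.0
    # sequences
    n_sequences_per_class: int = 30
    seq_length: int = 1200
    seq_flank: int = 100
    gc_content: float = 0.4
    ug_run_length: int = 20
    interruption_rate: float = 1 / 3
    clip_jitter: int = 10

    def __post_init__(self) -> None:
        for name in ("ce_fraction", "penetrance", "effect_dpsi",
                     "nmd_degradation", "nmd_sensitive_fraction",
                     "gc_content", "interruption_rate",
                     "nuclear_retention_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cluster_depth_mean <= 0 or self.cluster_depth_dispersion <= 0:
            raise ValueError("depth mean and dispersion must be positive")
        if any(e <= 0 for e in self.ec50_grid):
            raise ValueError("ec50 values must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, platform-stable substream keyed by stage name."""
        h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        return np.random.default_rng(np.random.SeedSequence([self.seed, h]))


@dataclass
class TruthTable:
    """Planted ground truth: one row per event (and per sequence)."""

    events: pd.DataFrame
    sequences: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def write(self, path) -> None:
        from .io_formats import write_table

        write_table(self.events, path)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float,
              size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _two_junction_cluster(i: int, chrom: str = "chr1") -> tuple[GenomicJunction, GenomicJunction, str]:
    """Inclusion + exclusion junctions sharing a donor, one region per cluster."""
    base = 10_000 * i + 1_000
    inclusion = GenomicJunction(chrom, base, base + 200, "+")
    exclusion = GenomicJunction(chrom, base, base + 1_200, "+")
    return inclusion, exclusion, f"clu_{i + 1}"


def _binomial_counts(rng, depth: np.ndarray, psi: np.ndarray) -> np.ndarray:
    return rng.binomial(depth, np.clip(psi, 0.0, 1.0))


def degraded_psi(psi: np.ndarray | float, d: np.ndarray | float):
    """Observed PSI after NMD destroys a fraction ``d`` of the inclusion isoform.

    psi' = psi (1-d) / (psi (1-d) + (1-psi)).
    """
    psi = np.asarray(psi, dtype=float)
    num = psi * (1.0 - np.asarray(d, dtype=float))
    den = num + (1.0 - psi)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[JunctionTable, CohortDesign, TruthTable]:
    """Case/control junction-count cohort with planted CEs.

    The first ``round(n_clusters * ce_fraction)`` clusters carry a CE:
    penetrant case samples (Bernoulli ``penetrance``) gain ``effect_dpsi``
    inclusion PSI over their Beta baseline, clipped to [0, 1].  Each
    cluster holds an inclusion and an exclusion junction sharing a donor.
    """
    rng = config.rng("cohort")
    n_case, n_ctrl = config.n_case, config.n_control
    n_samples = n_case + n_ctrl
    sample_ids = [f"case_{i + 1}" for i in range(n_case)] + [
        f"ctrl_{i + 1}" for i in range(n_ctrl)
    ]
    n_ce = int(round(config.n_clusters * config.ce_fraction))

    junctions: list[GenomicJunction] = []
    cluster_ids: list[str] = []
    counts_rows: list[np.ndarray] = []
    truth_rows = []
    penetrance_masks = {}
    for i in range(config.n_clusters):
        inc, exc, cid = _two_junction_cluster(i)
        is_ce = i < n_ce
        baseline = rng.beta(config.control_psi_alpha, config.control_psi_beta,
                            size=n_samples)
        psi = baseline.copy()
        penetrant = np.zeros(n_samples, dtype=bool)
        if is_ce and n_case:
            penetrant[:n_case] = rng.random(n_case) < config.penetrance
            psi[penetrant] = psi[penetrant] + config.effect_dpsi
        clipped = bool((psi > 1).any())
        psi = np.clip(psi, 0.0, 1.0)
        depth = _nb_depth(rng, config.cluster_depth_mean,
                          config.cluster_depth_dispersion, n_samples)
        inc_counts = _binomial_counts(rng, depth, psi)
        exc_counts = depth - inc_counts
        junctions.extend([inc, exc])
        cluster_ids.extend([cid, cid])
        counts_rows.extend([inc_counts, exc_counts])
        truth_rows.append(
            {
                "cluster": cid,
                "junction_id": inc.id,
                "is_ce": is_ce,
                "control_psi": config.control_psi_alpha
                / (config.control_psi_alpha + config.control_psi_beta),
                "effect_dpsi": config.effect_dpsi if is_ce else 0.0,
                "penetrance": config.penetrance if is_ce else 0.0,
                "n_penetrant": int(penetrant.sum()),
                "clipped": clipped,
                "predictive": bool(is_ce and n_case > 0),
            }
        )
        penetrance_masks[inc.id] = penetrant
    table = JunctionTable(junctions, cluster_ids,
                          np.array(counts_rows, dtype=np.int64), sample_ids)
    design = CohortDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "class": ["TDP-43 proteinopathy"] * n_case
                + ["non-TDP-43 proteinopathy"] * n_ctrl,
                "dataset": "synthetic_cohort",
            }
        )
    )
    truth = TruthTable(
        pd.DataFrame(truth_rows),
        extras={"penetrant": pd.DataFrame(penetrance_masks, index=sample_ids).T},
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------


def hill_psi(dose: float, ec50: float, hill: float, psi_max: float) -> float:
    if dose <= 0:
        return 0.0
    return psi_max / (1.0 + (ec50 / dose) ** hill)


def simulate_dose_response(
    config: SimulationConfig,
) -> tuple[JunctionTable, CohortDesign, TruthTable]:
    """Graded-knockdown series: one event per cluster on a Hill curve.

    Dose level i (1..K) corresponds to dose value i; level 0 is untreated.
    ec50 values cycle through ``ec50_grid``, so an equal number of events
    lands in each responsiveness class when the grid spans the dose range.
    Truth classes come from the pipeline's own staging rule applied to the
    noiseless latent curve; events whose latent PSI never clears the CE
    delta threshold are marked not-CE with class ``none``.
    """
    from .dose_response import classify_responsiveness_values

    if config.dose_levels < 3:
        raise ValueError("need >= 3 dose levels beyond untreated")
    rng = config.rng("dose")
    K, R = config.dose_levels, config.n_replicates
    sample_ids, levels = [], []
    for lev in range(K + 1):
        for r in range(R):
            sample_ids.append(f"dose{lev}_rep{r + 1}")
            levels.append(lev)
    levels_arr = np.array(levels)

    junctions, cluster_ids, counts_rows, truth_rows = [], [], [], []
    latent_curves = {}
    for i in range(config.n_clusters):
        inc, exc, cid = _two_junction_cluster(i)
        ec50 = config.ec50_grid[i % len(config.ec50_grid)]
        baseline = rng.beta(config.control_psi_alpha, config.control_psi_beta)
        latent = np.array(
            [
                min(1.0, baseline + hill_psi(lev, ec50, config.hill_coefficient,
                                             config.psi_max))
                for lev in range(K + 1)
            ]
        )
        is_ce = bool(
            baseline < DEFAULT_CONTROL_MAX
            and (latent[1:].max() - baseline) > DEFAULT_MIN_DPSI
        )
        true_class = (
            classify_responsiveness_values(latent[1:]) if is_ce else "none"
        )
        psi_per_sample = latent[levels_arr]
        depth = _nb_depth(rng, config.cluster_depth_mean,
                          config.cluster_depth_dispersion, len(sample_ids))
        inc_counts = _binomial_counts(rng, depth, psi_per_sample)
        junctions.extend([inc, exc])
        cluster_ids.extend([cid, cid])
        counts_rows.extend([inc_counts, depth - inc_counts])
        latent_curves[inc.id] = latent
        truth_rows.append(
            {
                "cluster": cid,
                "junction_id": inc.id,
                "ec50": ec50,
                "baseline_psi": baseline,
                "is_ce": is_ce,
                "response_class": true_class,
            }
        )
    table = JunctionTable(junctions, cluster_ids,
                          np.array(counts_rows, dtype=np.int64), sample_ids)
    design = CohortDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "class": ["control" if lev == 0 else "KD" for lev in levels],
                "dose_level": levels,
                "dataset": "synthetic_dose",
            }
        )
    )
    latent_df = pd.DataFrame(latent_curves,
                             index=[f"level_{k}" for k in range(K + 1)]).T
    truth = TruthTable(pd.DataFrame(truth_rows), extras={"latent_psi": latent_df})
    return table, design, truth


# ---------------------------------------------------------------------------
# NMD inhibition experiment
# ---------------------------------------------------------------------------


def _event_degradation(config: SimulationConfig, rng, n: int) -> np.ndarray:
    d, c = config.nmd_degradation, config.nmd_concentration
    if c is None or d in (0.0, 1.0):
        return np.full(n, d)
    return rng.beta(d * c, (1.0 - d) * c, size=n)


def simulate_nmd_experiment(
    config: SimulationConfig,
) -> tuple[JunctionTable, CohortDesign, TruthTable]:
    """Paired TDP-43 KD with and without NMD inhibition.

    Each event has a latent knockdown inclusion psi_true ~ U(0.15, 0.5);
    a Bernoulli ``nmd_sensitive_fraction`` of events is NMD-sensitive and
    degraded by d (competition renormalisation), the rest are untouched
    (frame-preserving / 3'UTR-type events).  KD+NMDi samples observe
    psi_true; KD samples observe the degraded PSI; controls stay at their
    Beta baseline.  Truth: rescued iff psi_true - degraded > 0.05; dark
    iff the event passes CE thresholds only under NMD inhibition
    (evaluated on the noiseless latents).
    """
    rng = config.rng("nmd")
    n_events = config.n_clusters
    n_rep = config.n_replicates
    sample_ids = (
        [f"ctrl_{i + 1}" for i in range(n_rep)]
        + [f"kd_{i + 1}" for i in range(n_rep)]
        + [f"kd_nmdi_{i + 1}" for i in range(n_rep)]
    )
    condition = ["control"] * n_rep + ["kd"] * n_rep + ["kd_nmdi"] * n_rep

    psi_true = rng.uniform(0.15, 0.5, size=n_events)
    sensitive = rng.random(n_events) < config.nmd_sensitive_fraction
    d = np.where(sensitive, _event_degradation(config, rng, n_events), 0.0)
    baseline = rng.beta(config.control_psi_alpha, config.control_psi_beta,
                        size=n_events)
    psi_kd = degraded_psi(psi_true, d)

    junctions, cluster_ids, counts_rows, truth_rows = [], [], [], []
    for i in range(n_events):
        inc, exc, cid = _two_junction_cluster(i)
        latent = np.where(
            np.array(condition) == "control", baseline[i],
            np.where(np.array(condition) == "kd", psi_kd[i], psi_true[i]),
        )
        depth = _nb_depth(rng, config.cluster_depth_mean,
                          config.cluster_depth_dispersion, len(sample_ids))
        inc_counts = _binomial_counts(rng, depth, latent)
        junctions.extend([inc, exc])
        cluster_ids.extend([cid, cid])
        counts_rows.extend([inc_counts, depth - inc_counts])
        delta = psi_true[i] - psi_kd[i]
        ce_kd = (
            baseline[i] < DEFAULT_CONTROL_MAX
            and psi_kd[i] - baseline[i] > DEFAULT_MIN_DPSI
        )
        ce_nmdi = (
            baseline[i] < DEFAULT_CONTROL_MAX
            and psi_true[i] - baseline[i] > DEFAULT_MIN_DPSI
        )
        truth_rows.append(
            {
                "cluster": cid,
                "junction_id": inc.id,
                "psi_true": psi_true[i],
                "psi_kd_latent": psi_kd[i],
                "baseline_psi": baseline[i],
                "degradation": d[i],
                "nmd_sensitive": bool(sensitive[i]),
                "delta": delta,
                "nmd_class": "rescued" if delta > 0.05 else "non_rescued",
                "ce_kd": bool(ce_kd),
                "ce_kd_nmdi": bool(ce_nmdi),
                "dark": bool(ce_nmdi and not ce_kd),
            }
        )
    table = JunctionTable(junctions, cluster_ids,
                          np.array(counts_rows, dtype=np.int64), sample_ids)
    design = CohortDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "class": ["control" if c == "control" else "KD" for c in condition],
                "nmd_condition": ["inhibited" if c == "kd_nmdi" else "none"
                                  for c in condition],
                "dataset": "synthetic_nmd",
            }
        )
    )
    return table, design, TruthTable(pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# nuclear / cytoplasmic fractionation
# ---------------------------------------------------------------------------


def simulate_fractionation(
    config: SimulationConfig,
) -> tuple[JunctionTable, JunctionTable, dict[str, pd.DataFrame], TruthTable]:
    """Fractionated counts for CE and annotated junctions, gene by gene.

    Each gene draws a log2 nuclear/cytoplasmic ratio ~ N(0, log2_nc_sd)
    shared by its annotated and CE isoforms.  When NMD is active the
    *cytoplasmic* CE abundance is multiplied by (1 - d_g), with d_g per
    gene ~ Beta(d*c, (1-d)*c) (c = ``fractionation_concentration``) —
    NMD efficacy varies between events, which is what decouples CE from
    annotated localisation under active NMD.  Planted nuclear-retention
    events add ``nuclear_retention_shift`` to the CE log-ratio in *every*
    condition.  Counts ~ Poisson around ``nc_depth``.

    Returns (nuclear table, cytoplasmic table, gene-level count tables
    keyed by fraction, truth).  Samples cover both NMD conditions.
    """
    rng = config.rng("fractionation")
    n_genes = config.n_genes
    n_rep = config.n_replicates
    log2_nc = rng.normal(0.0, config.log2_nc_sd, size=n_genes)
    retained = rng.random(n_genes) < config.nuclear_retention_fraction
    d_mean, c = config.nmd_degradation, config.fractionation_concentration
    if d_mean in (0.0, 1.0) or c is None:
        d_g = np.full(n_genes, d_mean)
    else:
        d_g = rng.beta(d_mean * c, (1.0 - d_mean) * c, size=n_genes)
    ce_share = 0.5  # CE isoform abundance relative to the annotated isoform

    sample_ids, nmd_cond = [], []
    for cond in ("none", "inhibited"):
        for r in range(n_rep):
            sample_ids.append(f"nmd_{cond}_rep{r + 1}")
            nmd_cond.append(cond)

    junctions, cluster_ids = [], []
    nuc_rows, cyt_rows = [], []
    gene_nuc = np.zeros((n_genes, len(sample_ids)))
    gene_cyt = np.zeros((n_genes, len(sample_ids)))
    truth_rows = []
    for g in range(n_genes):
        ann_j, ce_j, cid = _two_junction_cluster(g)
        ce_log2 = log2_nc[g] + (config.nuclear_retention_shift if retained[g] else 0.0)
        # expected cytoplasmic abundance nc_depth; nuclear = cyto * 2^log2ratio
        ann_cyt = config.nc_depth
        ann_nuc = config.nc_depth * 2.0 ** log2_nc[g]
        ce_cyt_base = config.nc_depth * ce_share
        ce_nuc = ce_cyt_base * 2.0 ** ce_log2
        ann_nuc_counts, ann_cyt_counts = [], []
        ce_nuc_counts, ce_cyt_counts = [], []
        for s, cond in enumerate(nmd_cond):
            surv = 1.0 - d_g[g] if cond == "none" else 1.0
            ann_nuc_counts.append(rng.poisson(ann_nuc))
            ann_cyt_counts.append(rng.poisson(ann_cyt))
            ce_nuc_counts.append(rng.poisson(ce_nuc))
            ce_cyt_counts.append(rng.poisson(ce_cyt_base * surv))
        junctions.extend([ann_j, ce_j])
        cluster_ids.extend([cid, cid])
        nuc_rows.extend([ann_nuc_counts, ce_nuc_counts])
        cyt_rows.extend([ann_cyt_counts, ce_cyt_counts])
        gene_nuc[g] = np.array(ann_nuc_counts) + np.array(ce_nuc_counts)
        gene_cyt[g] = np.array(ann_cyt_counts) + np.array(ce_cyt_counts)
        truth_rows.append(
            {
                "gene": f"gene_{g + 1}",
                "annotated_junction_id": ann_j.id,
                "ce_junction_id": ce_j.id,
                "log2_nc": log2_nc[g],
                "ce_log2_nc": ce_log2,
                "degradation": d_g[g],
                "nuclear_retained": bool(retained[g]),
            }
        )
    nuclear = JunctionTable(junctions, cluster_ids,
                            np.array(nuc_rows, dtype=np.int64), sample_ids)
    cytoplasmic = JunctionTable(junctions, cluster_ids,
                                np.array(cyt_rows, dtype=np.int64), sample_ids)
    gene_index = [f"gene_{g + 1}" for g in range(n_genes)]
    gene_tables = {
        "nuclear": pd.DataFrame(gene_nuc.astype(np.int64), index=gene_index,
                                columns=sample_ids),
        "cytoplasmic": pd.DataFrame(gene_cyt.astype(np.int64), index=gene_index,
                                    columns=sample_ids),
    }
    truth = TruthTable(pd.DataFrame(truth_rows),
                       extras={"nmd_condition": pd.Series(nmd_cond,
                                                          index=sample_ids)})
    return nuclear, cytoplasmic, gene_tables, truth


# ---------------------------------------------------------------------------
# sequences with planted UG runs and CLIP peaks
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def simulate_sequences(
    config: SimulationConfig,
) -> tuple[SequenceStore, IntervalSet, list[GenomicJunction], TruthTable]:
    """Intron-bearing contigs with planted UG runs and CLIP peaks.

    One contig per junction; the intron spans [flank, length - flank) on
    the plus strand, so the donor sits at ``flank``.  "early"-class
    junctions get an uninterrupted (TG)^n run starting 5 bp into the
    intron; "late"-class junctions get the same run with dinucleotides
    replaced by AA at ``interruption_rate``.  A CLIP peak covers each
    planted run, jittered by up to ``clip_jitter`` bp on each side.
    ``ug_run_length == 0`` plants nothing (pure background).
    """
    rng = config.rng("sequences")
    L, flank = config.seq_length, config.seq_flank
    n_run = config.ug_run_length
    run_offset = 5  # bp downstream of the donor
    if 2 * n_run + run_offset > L - 2 * flank:
        raise ValueError(
            f"(TG)^{n_run} run does not fit in the {L - 2 * flank} bp intron"
        )
    seqs: dict[str, str] = {}
    peaks = []
    junctions = []
    seq_rows = []
    for cls in ("early", "late"):
        for i in range(config.n_sequences_per_class):
            name = f"{cls}_{i + 1}"
            arr = _random_seq(rng, L, config.gc_content)
            run_start = run_end = -1
            n_interruptions = 0
            if n_run > 0:
                dints = []
                for _ in range(n_run):
                    if cls == "late" and rng.random() < config.interruption_rate:
                        dints.append("AA")
                        n_interruptions += 1
                    else:
                        dints.append("TG")
                run = "".join(dints)
                run_start = flank + run_offset
                run_end = run_start + len(run)
                arr[run_start:run_end] = list(run)
                jl = int(rng.integers(0, config.clip_jitter + 1))
                jr = int(rng.integers(0, config.clip_jitter + 1))
                peaks.append(
                    (name, max(0, run_start - jl), min(L, run_end + jr), "+",
                     f"clip_{name}")
                )
            seqs[name] = "".join(arr)
            junctions.append(GenomicJunction(name, flank, L - flank, "+"))
            seq_rows.append(
                {
                    "name": name,
                    "class": cls,
                    "run_start": run_start,
                    "run_end": run_end,
                    "n_interruptions": n_interruptions,
                }
            )
    truth = TruthTable(pd.DataFrame(), sequences=pd.DataFrame(seq_rows))
    return SequenceStore(seqs), IntervalSet(peaks), junctions, truth


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
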