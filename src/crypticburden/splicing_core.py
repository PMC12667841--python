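"""Cluster PSI computation, junction classification and cryptic-event calling.

PSI (percent spliced in) is the per-sample fraction of a cluster's reads
supporting one junction.  A cryptic splicing event (CE) is an unannotated
junction quiet in controls (mean PSI < 5%) that appears on TDP-43 loss
(delta PSI > 10%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationIndex,
    CohortDesign,
    GenomicJunction,
    JunctionTable,
)

logger = logging.getLogger(__name__)

#: Junction categories relative to annotation (DASPER-style vocabulary).
JUNCTION_CATEGORIES = (
    "annotated",
    "novel_acceptor",
    "novel_donor",
    "novel_exon_skip",
    "novel_combo",
    "ambig_gene",
    "none",
)

DEFAULT_CONTROL_MAX = 0.05
DEFAULT_MIN_DPSI = 0.10
DEFAULT_MIN_CLUSTER_READS = 15
DEFAULT_MIN_FRACTION = 1e-4
#: Putative cassette exon length bounds used when pairing junctions.
CASSETTE_EXON_BOUNDS = (1, 10_000)


class PsiMatrix:
    """Junctions x samples percent-spliced-in with explicit missingness.

    PSI is missing (NaN) exactly where the junction's cluster has fewer
    than ``min_cluster_reads`` reads in that sample.  Where defined, the
    PSI of a cluster's junctions sums to 1 per sample.
    """

    def __init__(
        self,
        psi: pd.DataFrame,
        cluster_totals: pd.DataFrame,
        junctions: Sequence[GenomicJunction],
        cluster_ids: Sequence[str],
        min_cluster_reads: int,
    ) -> None:
        self.psi = psi  # index: junction id, columns: sample ids
        self.cluster_totals = cluster_totals  # same shape: cluster depth per cell
        self.junctions = list(junctions)
        self.cluster_ids = list(cluster_ids)
        self.min_cluster_reads = min_cluster_reads

    @property
    def sample_ids(self) -> list[str]:
        return list(self.psi.columns)

    @property
    def junction_ids(self) -> list[str]:
        return list(self.psi.index)

    def group_mean(self, samples: Sequence[str]) -> pd.Series:
        """Per-junction mean PSI over the given samples, ignoring missing."""
        return self.psi[list(samples)].mean(axis=1, skipna=True)


def filter_cluster_junctions(
    table: JunctionTable, min_fraction: float = DEFAULT_MIN_FRACTION
) -> JunctionTable:
    """Drop junctions contributing < ``min_fraction`` of their cluster's reads.

    Fractions are computed on counts summed across samples (LeafCutter's
    relaxed-filtering rule); junctions exactly at the threshold are kept.
    Clusters emptied by the filter disappear.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    if min_fraction == 0 or table.n_junctions == 0:
        return table
    row_sums = table.counts.sum(axis=1)
    cluster_sums: dict[str, int] = {}
    for cid, s in zip(table.cluster_ids, row_sums):
        cluster_sums[cid] = cluster_sums.get(cid, 0) + int(s)
    keep = np.array(
        [
            cluster_sums[cid] > 0 and s / cluster_sums[cid] >= min_fraction
            for cid, s in zip(table.cluster_ids, row_sums)
        ]
    )
    return table.subset_junctions(keep)


def compute_psi(
    table: JunctionTable, min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS
) -> PsiMatrix:
    """Cluster-ratio PSI: count(j, s) / cluster_total(s), missing below depth."""
    if min_cluster_reads < 1:
        raise ValueError("min_cluster_reads must be >= 1")
    jids = table.junction_ids
    counts = pd.DataFrame(table.counts, index=jids, columns=table.sample_ids)
    clusters = pd.Series(table.cluster_ids, index=jids)
    totals = counts.groupby(clusters).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = counts / totals
    psi = psi.where(totals >= min_cluster_reads)
    return PsiMatrix(psi, totals, table.junctions, table.cluster_ids, min_cluster_reads)


# ---------------------------------------------------------------------------
# Junction classification
# ---------------------------------------------------------------------------


def classify_junction(j: GenomicJunction, ann: AnnotationIndex) -> str:
    """Assign one category from :data:`JUNCTION_CATEGORIES`.

    ``annotated``: coordinates match a derived annotated intron exactly.
    ``none``: no gene overlap.  ``ambig_gene``: the junction overlaps
    several genes and neither end resolves it to one, or its strand
    conflicts with every overlapping gene.  Within one gene the ends are
    compared against that gene's annotated donor/acceptor sites
    (strand-aware): one novel end gives ``novel_acceptor`` /
    ``novel_donor``; two annotated ends in an unannotated combination
    give ``novel_exon_skip`` when >=1 annotated exon lies strictly inside
    the junction, else ``novel_combo``; two novel ends give ``novel_combo``.
    """
    genes = ann.overlapping_genes(j.chrom, j.start, j.end)
    if j.strand in {"+", "-"}:
        genes = [g for g in genes if ann.gene_strand(g) == j.strand]
    if not genes:
        return "none"
    if len(genes) > 1:
        # try to resolve by splice-site match: a unique gene owning either end
        owners = [
            g
            for g in genes
            if j.start in ann.gene_donors[g]
            or j.start in ann.gene_acceptors[g]
            or j.end in ann.gene_donors[g]
            or j.end in ann.gene_acceptors[g]
        ]
        if len(owners) != 1:
            return "ambig_gene"
        genes = owners
    gene = genes[0]
    strand = ann.gene_strand(gene)
    if j.strand == "." and strand not in {"+", "-"}:
        return "ambig_gene"
    if (j.start, j.end) in ann.gene_introns[gene]:
        return "annotated"
    if strand == "-":
        donor_end, acceptor_end = j.end, j.start
    else:
        donor_end, acceptor_end = j.start, j.end
    donor_known = donor_end in ann.gene_donors[gene]
    acceptor_known = acceptor_end in ann.gene_acceptors[gene]
    if donor_known and not acceptor_known:
        return "novel_acceptor"
    if acceptor_known and not donor_known:
        return "novel_donor"
    if donor_known and acceptor_known:
        skipped = any(
            j.start < es and ee < j.end for es, ee in ann.gene_exons[gene]
        )
        return "novel_exon_skip" if skipped else "novel_combo"
    return "novel_combo"


def classify_junctions(
    junctions: Sequence[GenomicJunction], ann: AnnotationIndex
) -> pd.Series:
    """Vector form of :func:`classify_junction`, indexed by junction id."""
    return pd.Series(
        [classify_junction(j, ann) for j in junctions],
        index=[j.id for j in junctions],
        name="category",
    )


# ---------------------------------------------------------------------------
# Cryptic event calling
# ---------------------------------------------------------------------------


@dataclass
class CrypticEvent:
    """A called cryptic splicing event.

    Cassette events carry the acceptor- and donor-side junctions; events
    supported by one junction only carry it alone with
    ``single_junction`` set.
    """

    junction: GenomicJunction
    category: str
    control_psi: float
    condition_psi: float
    dpsi: float
    gene_id: str | None = None
    partner: GenomicJunction | None = None
    dataset: str | None = None
    single_junction: bool = True

    @property
    def id(self) -> str:
        return self.junction.id


def _resolve_strand(
    j: GenomicJunction, ann: AnnotationIndex | None
) -> str | None:
    if j.strand in {"+", "-"}:
        return j.strand
    if ann is None:
        return None
    genes = ann.overlapping_genes(j.chrom, j.start, j.end)
    strands = {ann.gene_strand(g) for g in genes} & {"+", "-"}
    return strands.pop() if len(strands) == 1 else None


def _assign_gene(j: GenomicJunction, ann: AnnotationIndex | None) -> str | None:
    if ann is None:
        return None
    genes = ann.overlapping_genes(j.chrom, j.start, j.end)
    return genes[0] if len(genes) == 1 else None


def call_cryptic_events(
    psi: PsiMatrix,
    design: CohortDesign,
    categories: pd.Series,
    control_max: float = DEFAULT_CONTROL_MAX,
    min_dpsi: float = DEFAULT_MIN_DPSI,
    annotation: AnnotationIndex | None = None,
    dataset: str | None = None,
    exon_bounds: tuple[int, int] = CASSETTE_EXON_BOUNDS,
) -> list[CrypticEvent]:
    """Call CEs: unannotated junctions with control mean PSI < ``control_max``
    and condition-minus-control mean PSI > ``min_dpsi`` (strict inequalities).

    Group means are unweighted over non-missing per-sample PSI.  Adjacent
    novel_acceptor + novel_donor junctions flanking a common unannotated
    exonic interval (length within ``exon_bounds``) are paired into one
    cassette event; unpaired events keep ``single_junction=True``.
    """
    samples = psi.sample_ids
    design.validate_against_samples(samples)
    is_case = design.is_case(samples)
    case_samples = [s for s, c in zip(samples, is_case) if c]
    control_samples = [s for s, c in zip(samples, is_case) if not c]
    if not case_samples or not control_samples:
        raise ValueError("design must provide >=1 case and >=1 control sample")

    control_mean = psi.group_mean(control_samples)
    case_mean = psi.group_mean(case_samples)
    n_skipped = 0
    events: list[CrypticEvent] = []
    for j in psi.junctions:
        jid = j.id
        cat = categories.get(jid, "none")
        if cat == "annotated":
            continue
        c, k = control_mean[jid], case_mean[jid]
        if np.isnan(c) or np.isnan(k):
            n_skipped += 1
            continue
        if c < control_max and (k - c) > min_dpsi:
            events.append(
                CrypticEvent(
                    junction=j,
                    category=cat,
                    control_psi=float(c),
                    condition_psi=float(k),
                    dpsi=float(k - c),
                    gene_id=_assign_gene(j, annotation),
                    dataset=dataset,
                )
            )
    if n_skipped:
        logger.info("call_cryptic_events: skipped %d junction(s) with no "
                    "covered samples in a group", n_skipped)
    return _pair_cassette_events(events, annotation, exon_bounds)


def _pair_cassette_events(
    events: list[CrypticEvent],
    ann: AnnotationIndex | None,
    exon_bounds: tuple[int, int],
) -> list[CrypticEvent]:
    """Pair acceptor/donor-side events flanking one putative cassette exon.

    Genomically, the left junction must end where the exon starts and the
    right junction start where it ends.  On the plus strand the left
    junction is the novel_acceptor and the right the novel_donor; on the
    minus strand the roles swap.  The exon interval must be unannotated.
    """
    lo, hi = exon_bounds
    paired: set[str] = set()
    out: list[CrypticEvent] = []
    acceptors = [e for e in events if e.category == "novel_acceptor"]
    donors = [e for e in events if e.category == "novel_donor"]
    for ea in acceptors:
        if ea.id in paired:
            continue
        ja = ea.junction
        strand = _resolve_strand(ja, ann)
        for ed in donors:
            if ed.id in paired or ed.junction.chrom != ja.chrom:
                continue
            jd = ed.junction
            ds = _resolve_strand(jd, ann)
            if strand is not None and ds is not None and strand != ds:
                continue
            s = strand or ds
            if s == "-":
                left, right = jd, ja  # novel_donor left of the exon on minus
            else:
                left, right = ja, jd
            exon_len = right.start - left.end
            if not (lo <= exon_len <= hi):
                continue
            if ann is not None:
                exon = (left.end, right.start)
                in_annotation = any(
                    exon in ann.gene_exons.get(g, set())
                    for g in ann.overlapping_genes(ja.chrom, left.end, right.start)
                )
                if in_annotation:
                    continue
            cassette = replace(
                ea,
                partner=jd,
                single_junction=False,
                condition_psi=float(np.mean([ea.condition_psi, ed.condition_psi])),
                control_psi=float(np.mean([ea.control_psi, ed.control_psi])),
                dpsi=float(np.mean([ea.dpsi, ed.dpsi])),
            )
            out.append(cassette)
            paired.update({ea.id, ed.id})
            break
    out.extend(e for e in events if e.id not in paired)
    out.sort(key=lambda e: (e.junction.chrom, e.junction.start, e.junction.end))
    return out


def events_to_frame(events: Sequence[CrypticEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "junction_id": e.id,
                "chrom": e.junction.chrom,
                "start": e.junction.start,
                "end": e.junction.end,
                "strand": e.junction.strand,
                "category": e.category,
                "gene_id": e.gene_id,
                "control_psi": e.control_psi,
                "condition_psi": e.condition_psi,
                "dpsi": e.dpsi,
                "partner_id": e.partner.id if e.partner else None,
                "single_junction": e.single_junction,
                "dataset": e.dataset,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "junction_id", "chrom", "start", "end", "strand", "category",
            "gene_id", "control_psi", "condition_psi", "dpsi", "partner_id",
            "single_junction", "dataset",
        ],
    )


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def normalize_median_of_ratios(
    counts: pd.DataFrame | np.ndarray,
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors (the DESeq2 scheme).

    For each gene with all-positive counts, compute counts / geometric
    mean across samples; the per-sample median of those ratios is the
    size factor.  Returns (size factors, counts / size factor).
    """
    df = pd.DataFrame(counts)
    if (df.values < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (df > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-of-ratios "
            "is undefined (a pseudo-reference fallback is not implemented)"
        )
    ref = df.loc[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geomean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    size_factors.name = "size_factor"
    return size_factors, df.div(size_factors, axis=1)
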