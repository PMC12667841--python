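"""Splice-site-proximal sequence and CLIP-binding features.

TDP-43 binds UG repeats; early-responsive cryptic exons sit in a dense,
uninterrupted UG context near their splice sites while late-responsive
ones show AA-interrupted repeats.  This module scores UG density
(TGTGTG windows allowing one mismatch, per base), hexamer-class
frequencies per kilobase, CLIP-peak binding profiles around splice
sites, and the donor-downstream nucleotide probability matrix.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationIndex, GenomicJunction, IntervalSet, SequenceStore

logger = logging.getLogger(__name__)

#: TDP-43 binding hexamer classes (condensation-dependent YG/YA vs
#: condensation-independent AA-interrupted motifs).
HEXAMER_CLASSES: dict[str, frozenset[str]] = {
    "YG": frozenset({"TGTGTG", "GTGTGT", "TGTGCG", "TGCGTG", "CGTGTG", "GTGTGC"}),
    "YA": frozenset({"ATGTGT", "GTATGT", "GTGTAT", "TGTGTA", "TGTATG", "TGCATG"}),
    "AA": frozenset({"GTGTGA", "AATGAA", "GAATGA", "TGAATG", "ATGAAT", "GTGAAT",
                     "GAATGT", "TTGAAT"}),
}

UG_MOTIF = "TGTGTG"
DEFAULT_PROFILE_WINDOW = 500
DEFAULT_BOUND_RADIUS = 250
DEFAULT_LOGO_LENGTH = 50
DEFAULT_BACKGROUND_N = 500


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------


def merge_intervals(peaks: IntervalSet) -> IntervalSet:
    """Collapse overlapping or touching intervals per chromosome (and
    strand, when stranded) into single binding regions.

    Half-open adjacency merges: [10,20) + [20,30) -> [10,30).  Idempotent
    and covered-base preserving.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, start, end, strand, _label in peaks:
        grouped.setdefault((chrom, strand), []).append((start, end))
    merged_rows = []
    for (chrom, strand), ivs in sorted(grouped.items()):
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                merged_rows.append((chrom, cur_s, cur_e, strand, None))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        merged_rows.append((chrom, cur_s, cur_e, strand, None))
    return IntervalSet(merged_rows)


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------


def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def ug_density(seq: str, max_mismatch: int = 1) -> float:
    """UG-repeat density: TGTGTG windows (all overlapping offsets) within
    ``max_mismatch`` substitutions, divided by sequence length.

    N never matches.  Sequences shorter than 6 bp score 0 with a warning.
    """
    count = count_motif_windows(seq, UG_MOTIF, max_mismatch)
    if len(seq) < len(UG_MOTIF):
        warnings.warn(f"sequence shorter than {len(UG_MOTIF)} bp: density 0")
        return 0.0
    return count / len(seq)


def count_motif_windows(seq: str, motif: str, max_mismatch: int = 0) -> int:
    """Overlapping windows of ``seq`` within Hamming distance
    ``max_mismatch`` of ``motif`` (vectorised sliding comparison)."""
    m = len(motif)
    if len(seq) < m:
        return 0
    codes = _seq_to_codes(seq.upper())
    motif_codes = _seq_to_codes(motif.upper())
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    mismatches = (windows != motif_codes).sum(axis=1)
    # N (and any non-ACGT) already differs from every motif base, so it
    # can never help a window match
    return int((mismatches <= max_mismatch).sum())


def hexamer_class_freq(
    seq: str, classes: Mapping[str, frozenset[str]] = HEXAMER_CLASSES
) -> dict[str, float]:
    """Occurrences per kilobase of each hexamer class (overlapping exact
    matches of any member, summed within class)."""
    out = {}
    length = len(seq)
    for name, members in classes.items():
        count = sum(count_motif_windows(seq, h, 0) for h in sorted(members))
        out[name] = count * 1000.0 / length if length >= 6 else 0.0
    return out


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------


def fisher_enrichment(
    present_a: int, absent_a: int, present_b: int, absent_b: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test on a motif present/absent 2x2 table.

    Returns (sample odds ratio (a d)/(b c) with inf/0 allowed, p).  A
    zero margin makes the table uninformative: p = 1, odds ratio NaN.
    """
    a, b, c, d = present_a, absent_a, present_b, absent_b
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def enrichment_table(
    group_a_seqs: Sequence[str],
    group_b_seqs: Sequence[str],
    classes: Mapping[str, frozenset[str]] = HEXAMER_CLASSES,
) -> pd.DataFrame:
    """Per-class enrichment of group A (e.g. late) vs group B (early).

    The 2x2 unit is the sequence (bound region): motif-class present vs
    absent.  Fold enrichment is the ratio of mean per-kb frequencies;
    BH correction spans the classes tested.
    """
    rows = []
    for name in classes:
        members = classes[name]
        pres_a = sum(
            any(count_motif_windows(s, h, 0) for h in members) for s in group_a_seqs
        )
        pres_b = sum(
            any(count_motif_windows(s, h, 0) for h in members) for s in group_b_seqs
        )
        freq_a = float(np.mean([hexamer_class_freq(s, {name: members})[name]
                                for s in group_a_seqs])) if group_a_seqs else 0.0
        freq_b = float(np.mean([hexamer_class_freq(s, {name: members})[name]
                                for s in group_b_seqs])) if group_b_seqs else 0.0
        odds, p = fisher_enrichment(
            pres_a, len(group_a_seqs) - pres_a, pres_b, len(group_b_seqs) - pres_b
        )
        log2_fold = (
            float(np.log2(freq_a / freq_b)) if freq_a > 0 and freq_b > 0
            else float("nan")
        )
        rows.append(
            {"class": name, "freq_per_kb_a": freq_a, "freq_per_kb_b": freq_b,
             "log2_fold": log2_fold, "odds_ratio": odds, "p": p}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].values)
    return table


# ---------------------------------------------------------------------------
# binding profiles
# ---------------------------------------------------------------------------


def _site_position(j: GenomicJunction, anchor: str) -> int:
    """Genomic position of offset 0 for a donor/acceptor anchor.

    Donor offset 0 = first intronic base; acceptor offset 0 = first
    exonic base downstream of the intron (transcript orientation).
    """
    if anchor == "donor":
        return j.start if j.strand != "-" else j.end - 1
    if anchor == "acceptor":
        return j.end if j.strand != "-" else j.start - 1
    raise ValueError(f"anchor must be donor or acceptor, got {anchor!r}")


def binding_fraction_profile(
    junctions: Sequence[GenomicJunction],
    peaks: IntervalSet,
    anchor: str,
    window: int = DEFAULT_PROFILE_WINDOW,
) -> pd.Series:
    """Fraction of junctions whose base at each offset in
    [-window, +window] around the anchor splice site lies in a CLIP peak.

    Offsets run in transcript orientation (sign flips on the minus
    strand): positive offsets go into the intron for donors and into the
    downstream exon for acceptors.  Junctions with unresolvable strand
    are excluded and counted.
    """
    offsets = np.arange(-window, window + 1)
    usable = [j for j in junctions if j.strand in {"+", "-"}]
    n_excluded = len(junctions) - len(usable)
    if n_excluded:
        logger.info("binding_fraction_profile: %d junction(s) with unknown "
                    "strand excluded", n_excluded)
    if not usable:
        return pd.Series(np.zeros(offsets.size), index=offsets, name="fraction_bound")
    covered = np.zeros(offsets.size)
    for j in usable:
        site = _site_position(j, anchor)
        sign = -1 if j.strand == "-" else 1
        positions = site + sign * offsets
        lo, hi = int(positions.min()), int(positions.max()) + 1
        mask = np.zeros(hi - lo, dtype=bool)
        for s, e in peaks.query(j.chrom, lo, hi):
            mask[max(s, lo) - lo : max(min(e, hi) - lo, 0)] = True
        covered += mask[positions - lo]
    profile = pd.Series(covered / len(usable), index=offsets, name="fraction_bound")
    profile.index.name = "offset"
    return profile


def fraction_bound_within(
    junctions: Sequence[GenomicJunction],
    peaks: IntervalSet,
    radius: int = DEFAULT_BOUND_RADIUS,
    anchor: str = "donor",
) -> float:
    """Fraction of junctions with >= 1 peak overlapping
    [site - radius, site + radius) around the anchor splice site."""
    junctions = list(junctions)
    if not junctions:
        return 0.0
    n_bound = 0
    for j in junctions:
        site = _site_position(j, anchor) if j.strand in {"+", "-"} else j.start
        if peaks.query(j.chrom, site - radius, site + radius):
            n_bound += 1
    return n_bound / len(junctions)


def donor_downstream_ppm(
    junctions: Sequence[GenomicJunction],
    genome: SequenceStore,
    length: int = DEFAULT_LOGO_LENGTH,
) -> pd.DataFrame:
    """Per-position nucleotide probabilities for the first ``length``
    intronic bases downstream of the donor (transcript orientation;
    reverse-complemented on the minus strand).

    Ns are excluded from the denominator position-wise; junctions whose
    flank is truncated by a contig end are skipped and logged.  Returns a
    (length x 4) frame with columns A, C, G, T summing to 1 wherever any
    non-N base was observed.
    """
    counts = np.zeros((length, 4))
    base_index = {b: i for i, b in enumerate("ACGT")}
    n_skipped = 0
    for j in junctions:
        if j.strand == "-":
            start, end = j.end - length, j.end
        else:
            start, end = j.start, j.start + length
        if j.chrom not in genome or start < 0 or end > genome.length(j.chrom):
            n_skipped += 1
            continue
        seq = genome.fetch(j.chrom, start, end, j.strand if j.strand == "-" else "+")
        for pos, base in enumerate(seq):
            if base in base_index:
                counts[pos, base_index[base]] += 1
    if n_skipped:
        logger.info("donor_downstream_ppm: %d junction(s) with truncated "
                    "flank skipped", n_skipped)
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        probs = np.divide(counts, denom, out=np.zeros_like(counts), where=denom > 0)
    out = pd.DataFrame(probs, columns=list("ACGT"))
    out.index.name = "position"
    return out


def sample_background_exons(
    ann: AnnotationIndex, n: int = DEFAULT_BACKGROUND_N, seed: int = 0
) -> list[tuple[str, int, int, str]]:
    """Uniform sample (without replacement) of internal exons as a
    background set; deterministic under ``seed``.  If fewer than ``n``
    internal exons exist, all are returned with a warning."""
    internal = ann.internal_exons()
    if len(internal) < n:
        warnings.warn(
            f"only {len(internal)} internal exon(s) available, sampling all"
        )
        return list(internal)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(internal), size=n, replace=False)
    return [internal[i] for i in sorted(idx)]


def ingest_splice_scores(
    scores: pd.DataFrame, junctions: Sequence[GenomicJunction]
) -> pd.DataFrame:
    """Join externally computed splice-site probabilities (e.g. a deep
    splice model's output) onto junctions by exact coordinates.

    ``scores`` needs columns chrom, start, end, score in [0, 1].  The
    result has one row per junction with NaN + ``missing`` flag where no
    score matched.
    """
    required = {"chrom", "start", "end", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    if ((scores["score"] < 0) | (scores["score"] > 1)).any():
        bad = scores.loc[(scores["score"] < 0) | (scores["score"] > 1), "score"]
        raise ValueError(f"scores outside [0, 1]: {bad.tolist()[:5]}")
    lookup = {
        (r.chrom, int(r.start), int(r.end)): float(r.score)
        for r in scores.itertuples()
    }
    rows = []
    for j in junctions:
        score = lookup.get(j.coords)
        rows.append(
            {"junction_id": j.id, "score": score if score is not None else np.nan,
             "missing": score is None}
        )
    return pd.DataFrame(rows).set_index("junction_id")
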