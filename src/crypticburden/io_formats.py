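"""Readers, writers and the internal data model.

All genomic intervals (introns, exons, peaks) use 0-based half-open
coordinates internally.  GTF input (1-based inclusive) is converted on
ingest; BED and the LeafCutter / regtools junction dialects are already
half-open and are preserved as-is.

A junction identifies the *intron*: ``start`` is the first intronic base,
``end`` is one past the last.  Strand "." is permitted on junctions;
strand-aware operations must then resolve strand from annotation or fail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum intron length accepted on ingest (bp).
MAX_INTRON_SIZE = 500_000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicJunction:
    """An intron-spanning splice junction in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("junction chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"junction start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"

    @property
    def coords(self) -> tuple[str, int, int]:
        """Strand-free coordinate key used for cross-dataset matching."""
        return (self.chrom, self.start, self.end)


class JunctionTable:
    """Per-sample junction read counts grouped into splice clusters.

    Parameters
    ----------
    junctions:
        Ordered junction records.
    cluster_ids:
        One opaque cluster label per junction.
    counts:
        Array of shape (n_junctions, n_samples), non-negative integers.
    sample_ids:
        Unique ordered sample names (count matrix columns).
    """

    def __init__(
        self,
        junctions: Sequence[GenomicJunction],
        cluster_ids: Sequence[str],
        counts: np.ndarray,
        sample_ids: Sequence[str],
    ) -> None:
        junctions = list(junctions)
        cluster_ids = [str(c) for c in cluster_ids]
        sample_ids = [str(s) for s in sample_ids]
        counts = np.asarray(counts)
        if counts.ndim == 1:
            counts = counts.reshape(-1, max(len(sample_ids), 1))
        if counts.shape != (len(junctions), len(sample_ids)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(junctions)} junctions x {len(sample_ids)} samples"
            )
        if len(cluster_ids) != len(junctions):
            raise ValueError("one cluster id required per junction")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.junctions = junctions
        self.cluster_ids = cluster_ids
        self.counts = counts.astype(np.int64)
        self.sample_ids = sample_ids

    # -- convenience ------------------------------------------------------

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def junction_ids(self) -> list[str]:
        return [j.id for j in self.junctions]

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by junction id, with a cluster column."""
        df = pd.DataFrame(
            self.counts, index=self.junction_ids, columns=self.sample_ids
        )
        df.insert(0, "cluster", self.cluster_ids)
        return df

    def subset_junctions(self, keep: np.ndarray) -> "JunctionTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return JunctionTable(
            [self.junctions[i] for i in keep],
            [self.cluster_ids[i] for i in keep],
            self.counts[keep],
            self.sample_ids,
        )

    def subset_samples(self, samples: Sequence[str]) -> "JunctionTable":
        idx = [self.sample_ids.index(s) for s in samples]
        return JunctionTable(
            self.junctions, self.cluster_ids, self.counts[:, idx], list(samples)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionTable):
            return NotImplemented
        return (
            self.junctions == other.junctions
            and self.cluster_ids == other.cluster_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


#: Allowed class labels, postmortem mode.
POSTMORTEM_CLASSES = frozenset({"TDP-43 proteinopathy", "non-TDP-43 proteinopathy"})
#: Allowed class labels, in vitro mode.
INVITRO_CLASSES = frozenset({"control", "KD"})
_VOCABULARIES = {
    "class": POSTMORTEM_CLASSES | INVITRO_CLASSES,
    "nmd_condition": frozenset({"none", "inhibited"}),
    "fraction": frozenset({"nuclear", "cytoplasmic", "whole"}),
    "pathology_type": frozenset({"A", "B", "C", "unknown"}),
}


class CohortDesign:
    """Sample sheet mapping sample ids to condition labels.

    The ``class`` column is the binary disease / perturbation label:
    ``TDP-43 proteinopathy`` vs ``non-TDP-43 proteinopathy`` for postmortem
    cohorts, ``KD`` vs ``control`` for in vitro knockdowns.  Optional
    columns: ``dataset``, ``dose_level`` (ordinal, 0 = untreated),
    ``nmd_condition``, ``fraction``, ``region``, ``genotype``,
    ``pathology_type``.  Unknown columns are carried through untouched.
    """

    CASE_LABELS = frozenset({"TDP-43 proteinopathy", "KD"})

    def __init__(self, table: pd.DataFrame) -> None:
        table = table.copy()
        if "sample_id" not in table.columns or "class" not in table.columns:
            raise ValueError("design requires 'sample_id' and 'class' columns")
        table["sample_id"] = table["sample_id"].astype(str)
        if table["sample_id"].duplicated().any():
            dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in design")
        if table["class"].isna().any():
            raise ValueError("every design row must carry a class label")
        for col, vocab in _VOCABULARIES.items():
            if col in table.columns:
                bad = set(table[col].dropna().astype(str)) - vocab
                if bad:
                    raise ValueError(
                        f"invalid {col} value(s) {sorted(bad)}; "
                        f"allowed: {sorted(vocab)}"
                    )
        if "dose_level" in table.columns:
            doses = table["dose_level"].dropna().astype(int)
            if len(doses):
                levels = sorted(set(doses))
                if levels != list(range(min(levels), max(levels) + 1)):
                    raise ValueError(
                        f"dose levels must form a contiguous ordinal range, got {levels}"
                    )
        self.table = table.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def classes(self, samples: Iterable[str] | None = None) -> pd.Series:
        t = self.table if samples is None else self.table.loc[list(samples)]
        return t["class"]

    def is_case(self, samples: Iterable[str] | None = None) -> pd.Series:
        """Boolean mask: proteinopathy / knockdown samples."""
        return self.classes(samples).isin(self.CASE_LABELS)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all column == value conditions."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            if col not in self.table.columns:
                raise KeyError(f"design has no column {col!r}")
            mask &= self.table[col] == val
        return list(self.table.index[mask])

    def validate_against(self, table: JunctionTable) -> None:
        self.validate_against_samples(table.sample_ids)

    def validate_against_samples(self, samples: Iterable[str]) -> None:
        missing = set(samples) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")


@dataclass
class _Transcript:
    gene_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # sorted half-open


class AnnotationIndex:
    """Gene models indexed for junction classification.

    Derived from a GTF: per-gene strand and span, exon intervals, and the
    set of annotated introns (consecutive exon gaps per transcript, in the
    same half-open frame as :class:`GenomicJunction`).
    """

    def __init__(
        self,
        genes: Mapping[str, tuple[str, str, int, int]],
        transcripts: Mapping[str, _Transcript],
    ) -> None:
        # genes: gene_id -> (chrom, strand, start, end)
        self.genes = dict(genes)
        self.transcripts = dict(transcripts)
        self.introns: set[tuple[str, int, int, str]] = set()
        # per gene: donor sites, acceptor sites (genomic coords of intron
        # boundaries, strand-resolved), exon intervals
        self.gene_donors: dict[str, set[int]] = {g: set() for g in self.genes}
        self.gene_acceptors: dict[str, set[int]] = {g: set() for g in self.genes}
        self.gene_exons: dict[str, set[tuple[int, int]]] = {g: set() for g in self.genes}
        self.gene_introns: dict[str, set[tuple[int, int]]] = {g: set() for g in self.genes}
        for tx in self.transcripts.values():
            gid = tx.gene_id
            chrom = self.genes[gid][0]
            exons = sorted(tx.exons)
            self.gene_exons[gid].update(exons)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if e1 >= s2:
                    continue  # overlapping/adjacent exons yield no intron
                self.introns.add((chrom, e1, s2, tx.strand))
                self.gene_introns[gid].add((e1, s2))
                if tx.strand == "-":
                    self.gene_donors[gid].add(s2)
                    self.gene_acceptors[gid].add(e1)
                else:
                    self.gene_donors[gid].add(e1)
                    self.gene_acceptors[gid].add(s2)
        # per-chrom gene interval index for overlap queries
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gid, (chrom, _strand, start, end) in self.genes.items():
            per_chrom.setdefault(chrom, []).append((start, end, gid))
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            ids = [r[2] for r in rows]
            self._by_chrom[chrom] = (starts, ends, ids)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene ids whose span overlaps [start, end)."""
        if chrom not in self._by_chrom:
            return []
        starts, ends, ids = self._by_chrom[chrom]
        cand = np.flatnonzero((starts < end) & (ends > start))
        return [ids[i] for i in cand]

    def gene_strand(self, gene_id: str) -> str:
        return self.genes[gene_id][1]

    def is_annotated_intron(self, j: GenomicJunction, strand: str | None = None) -> bool:
        s = strand if strand is not None else j.strand
        if s in {"+", "-"}:
            return (j.chrom, j.start, j.end, s) in self.introns
        return any((j.chrom, j.start, j.end, st) in self.introns for st in "+-")

    def internal_exons(self) -> list[tuple[str, int, int, str]]:
        """Unique non-first, non-last exons across transcripts (chrom, start, end, strand)."""
        out: set[tuple[str, int, int, str]] = set()
        for tx in self.transcripts.values():
            chrom = self.genes[tx.gene_id][0]
            exons = sorted(tx.exons)
            for s, e in exons[1:-1]:
                out.add((chrom, s, e, tx.strand))
        return sorted(out)


class IntervalSet:
    """Strand-aware half-open genomic intervals with fast overlap queries.

    Backed by per-chromosome sorted numpy arrays; ``query`` is
    O(log n + hits) once indexed.  Construction does not merge — merging
    is an explicit operation (:func:`crypticburden.sequence_features.merge_intervals`).
    """

    def __init__(
        self,
        intervals: Iterable[tuple],
    ) -> None:
        # rows: (chrom, start, end[, strand[, label]])
        rows = []
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            strand = iv[3] if len(iv) > 3 and iv[3] in {"+", "-"} else "."
            label = iv[4] if len(iv) > 4 else None
            if start >= end:
                raise ValueError(f"interval start >= end: {chrom}:{start}-{end}")
            rows.append((chrom, start, end, strand, label))
        self._rows = rows
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._rows, columns=["chrom", "start", "end", "strand", "label"]
        )

    def _build_index(self) -> None:
        idx: dict[str, list[tuple[int, int, int]]] = {}
        for i, (chrom, start, end, _strand, _label) in enumerate(self._rows):
            idx.setdefault(chrom, []).append((start, end, i))
        self._index = {}
        for chrom, rows in idx.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            # running max of ends enables early cut-off for nested intervals
            maxend = np.maximum.accumulate(ends)
            self._index[chrom] = (starts, ends, maxend)

    def query(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Intervals on ``chrom`` overlapping [start, end), as (start, end)."""
        if self._index is None:
            self._build_index()
        if chrom not in self._index:
            return []
        starts, ends, maxend = self._index[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        lo = int(np.searchsorted(maxend[:hi], start, side="right"))
        out = []
        for i in range(lo, hi):
            if ends[i] > start:
                out.append((int(starts[i]), int(ends[i])))
        return out

    def covers(self, chrom: str, pos: int) -> bool:
        return bool(self.query(chrom, pos, pos + 1))

    def covered_bases(self) -> int:
        """Total bases covered by >= 1 interval (union size), per chrom."""
        total = 0
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _s, _l in self._rows:
            per_chrom.setdefault(chrom, []).append((start, end))
        for ivs in per_chrom.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
        return total


class SequenceStore:
    """Uppercase nucleotide sequences addressable by name and interval.

    ``fetch`` on the minus strand returns the reverse complement, so the
    result always reads 5'->3' in transcript orientation.
    """

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self._seqs = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"sequence {name!r} has invalid characters {bad}")
            self._seqs[name] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceStore":
        from pyfaidx import Fasta

        fa = Fasta(str(path), sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def fetch(self, name: str, start: int, end: int, strand: str = "+") -> str:
        seq = self._seqs[name]
        if start < 0 or end > len(seq):
            raise IndexError(
                f"[{start}, {end}) outside {name!r} (length {len(seq)})"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _parse_leafcutter_counts(path: Path, max_intron_size: int):
    """LeafCutter ``_perind_numers``-style layout: row key chrom:start:end:cluster."""
    junctions, clusters, rows = [], [], []
    header: list[str] | None = None
    sample_ids: list[str] | None = None
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split()
            if not fields:
                continue
            if header is None:
                if ":" in fields[0]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header row with sample names"
                    )
                header = fields
                continue
            if sample_ids is None:
                # disambiguate on the first data row: the header either names
                # every column including the junction key, or samples only
                sample_ids = header[1:] if len(header) == len(fields) else header
            key = fields[0]
            parts = key.split(":")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: malformed junction key {key!r} "
                    "(expected chrom:start:end:cluster)"
                )
            chrom, start_s, end_s, cluster = parts
            try:
                start, end = int(start_s), int(end_s)
                counts = [int(x) for x in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if len(counts) != len(sample_ids):
                raise ValueError(
                    f"{path}:{lineno}: {len(counts)} counts for "
                    f"{len(sample_ids)} samples"
                )
            if end - start > max_intron_size:
                n_dropped += 1
                continue
            # LeafCutter clusters encode strand as a clu_N_? suffix when
            # stranded; extract it and normalise the label
            strand = "."
            if cluster.endswith(("_+", "_-")):
                strand = cluster[-1]
                cluster = cluster[:-2]
            junctions.append(GenomicJunction(chrom, start, end, strand))
            clusters.append(cluster)
            rows.append(counts)
    if sample_ids is None:
        sample_ids = header[1:] if header and header[0] == "junction" else (header or [])
    counts_arr = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=np.int64)
    )
    return junctions, clusters, counts_arr, sample_ids, n_dropped


def _parse_regtools_file(path: Path, max_intron_size: int):
    """One regtools ``junctions extract`` BED12-like file = one sample.

    The BED start/end include the anchors; the intron is recovered by
    stripping the two block sizes: intron = [start + block1, end - block2).
    """
    out: dict[GenomicJunction, int] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >=12 BED12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                score = int(fields[4])
                strand = fields[5] if fields[5] in {"+", "-"} else "."
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if len(block_sizes) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 anchor blocks, got {len(block_sizes)}"
                )
            intron_start = start + block_sizes[0]
            intron_end = end - block_sizes[1]
            if intron_start >= intron_end:
                raise ValueError(f"{path}:{lineno}: anchors swallow the intron")
            if intron_end - intron_start > max_intron_size:
                n_dropped += 1
                continue
            j = GenomicJunction(chrom, intron_start, intron_end, strand)
            if j in out:
                raise ValueError(
                    f"{path}:{lineno}: duplicate junction {j.id} within one sample"
                )
            out[j] = score
    return out, n_dropped


def read_junctions(
    path: str | Path | Sequence[str | Path],
    dialect: str,
    max_intron_size: int = MAX_INTRON_SIZE,
    cluster_unclustered: bool = True,
) -> JunctionTable:
    """Read a junction count table.

    Parameters
    ----------
    path:
        File path; for the ``regtools`` dialect a list of paths (one per
        sample) is accepted and merged on identical junctions.
    dialect:
        ``"leafcutter_counts"`` (clustered counts, row key
        ``chrom:start:end:cluster``, one column per sample) or
        ``"regtools"`` (BED12-like ``junctions extract`` output, one file
        per sample; anchor blocks are stripped to recover the intron).
    max_intron_size:
        Junctions with longer introns are dropped with a logged count.
    cluster_unclustered:
        For the regtools dialect (which carries no clusters), assign each
        group of junctions sharing either boundary to one connected-component
        cluster.
    """
    if dialect == "leafcutter_counts":
        if isinstance(path, (list, tuple)):
            raise ValueError("leafcutter_counts dialect takes a single file")
        junctions, clusters, counts, samples, n_dropped = _parse_leafcutter_counts(
            Path(path), max_intron_size
        )
        if n_dropped:
            logger.info("read_junctions: dropped %d junctions over %d bp",
                        n_dropped, max_intron_size)
        table = JunctionTable(junctions, clusters, counts, samples)
        table.n_dropped_long = n_dropped
        return table
    if dialect != "regtools":
        raise ValueError(f"unknown dialect {dialect!r}")

    paths = [Path(p) for p in (path if isinstance(path, (list, tuple)) else [path])]
    per_sample: list[dict[GenomicJunction, int]] = []
    n_dropped = 0
    for p in paths:
        counts, dropped = _parse_regtools_file(p, max_intron_size)
        per_sample.append(counts)
        n_dropped += dropped
    all_junctions = sorted({j for d in per_sample for j in d})
    counts_arr = np.zeros((len(all_junctions), len(paths)), dtype=np.int64)
    for s, d in enumerate(per_sample):
        for i, j in enumerate(all_junctions):
            counts_arr[i, s] = d.get(j, 0)
    sample_ids = [p.stem for p in paths]
    if cluster_unclustered and all_junctions:
        clusters = _connected_component_clusters(all_junctions)
    else:
        clusters = [f"clu_{i}" for i in range(len(all_junctions))]
    if n_dropped:
        logger.info("read_junctions: dropped %d junctions over %d bp",
                    n_dropped, max_intron_size)
    table = JunctionTable(all_junctions, clusters, counts_arr, sample_ids)
    table.n_dropped_long = n_dropped
    return table


def _connected_component_clusters(junctions: Sequence[GenomicJunction]) -> list[str]:
    """Group junctions sharing a splice site into clusters (union-find)."""
    parent = list(range(len(junctions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    site_owner: dict[tuple[str, int], int] = {}
    for i, j in enumerate(junctions):
        for site in ((j.chrom, j.start), (j.chrom, j.end)):
            if site in site_owner:
                ra, rb = find(i), find(site_owner[site])
                if ra != rb:
                    parent[ra] = rb
            else:
                site_owner[site] = i
    roots: dict[int, int] = {}
    labels = []
    for i in range(len(junctions)):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels.append(f"clu_{roots[r]}")
    return labels


def read_annotation(path: str | Path) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GTF file.

    Exon coordinates are converted from GTF 1-based inclusive to 0-based
    half-open; annotated introns are derived per transcript from
    consecutive exons sorted by position.  Gene spans are taken from gene
    features when present, else derived as the envelope of the gene's exons.
    Exons without a transcript_id are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, _Transcript] = {}
    gene_span: dict[str, list] = {}  # gene_id -> [chrom, strand, min, max]
    n_orphan = 0
    for ex in db.features_of_type("exon"):
        tx_ids = ex.attributes.get("transcript_id")
        gene_ids = ex.attributes.get("gene_id")
        if not tx_ids or not gene_ids:
            n_orphan += 1
            continue
        tx_id, gene_id = tx_ids[0], gene_ids[0]
        start, end = ex.start - 1, ex.end  # GTF -> half-open
        tx = transcripts.setdefault(tx_id, _Transcript(gene_id, ex.strand or "."))
        tx.exons.append((start, end))
        span = gene_span.setdefault(gene_id, [ex.seqid, ex.strand or ".", start, end])
        span[2] = min(span[2], start)
        span[3] = max(span[3], end)
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        gene_span[gid] = [g.seqid, g.strand or ".", g.start - 1, g.end]
    if n_orphan:
        warnings.warn(f"skipped {n_orphan} exon(s) without transcript/gene id")
    genes = {gid: tuple(span) for gid, span in gene_span.items()}
    for tx in transcripts.values():
        tx.exons.sort()
    return AnnotationIndex(genes, transcripts)


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Column 4 (name), if present, becomes the source label; column 6 the
    strand.  Overlapping intervals are preserved unmerged — the reader
    does not transform.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            rows.append((chrom, start, end, strand, label))
    return IntervalSet(rows)


def read_design(
    path: str | Path,
    class_mapping: Mapping[str, str] | None = None,
) -> CohortDesign:
    """Read a TSV sample sheet into a :class:`CohortDesign`.

    ``class_mapping`` optionally maps raw class values (e.g. ``case`` /
    ``control``) onto the controlled vocabulary before validation.
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if class_mapping and "class" in table.columns:
        table["class"] = table["class"].map(lambda v: class_mapping.get(v, v))
    return CohortDesign(table)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame, path: str | Path, sig_digits: int = 6) -> None:
    """Write a tabular result as TSV: UTF-8, header, NaN as ``NA``, floats
    at ``sig_digits`` significant digits, deterministic column order
    (as given)."""
    records.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep="NA",
        float_format=f"%.{sig_digits}g",
        encoding="utf-8",
    )


def write_junctions(table: JunctionTable, path: str | Path) -> None:
    """Serialize a JunctionTable in the leafcutter_counts dialect.

    Strand survives the round trip through the cluster-label suffix used
    by stranded LeafCutter runs (``<cluster>_<strand>``).
    """
    with open(path, "w") as fh:
        fh.write("junction\t" + "\t".join(table.sample_ids) + "\n" if table.sample_ids
                 else "junction\n")
        for j, cluster, row in zip(table.junctions, table.cluster_ids, table.counts):
            label = cluster
            if j.strand in {"+", "-"} and not cluster.endswith(("_+", "_-")):
                label = f"{cluster}_{j.strand}"
            key = f"{j.chrom}:{j.start}:{j.end}:{label}"
            fh.write(key + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def write_intervals(intervals: IntervalSet, path: str | Path) -> None:
    """Serialize an IntervalSet as BED6 (label in column 4, strand in 6)."""
    with open(path, "w") as fh:
        for chrom, start, end, strand, label in intervals:
            name = label if label is not None else "."
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
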