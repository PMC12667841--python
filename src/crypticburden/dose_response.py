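"""Staging of cryptic events by responsiveness to graded TDP-43 knockdown.

An event is *early* if its mean PSI reaches 20% at either of the two
lowest knockdown levels, *late* if it reaches 10% only at the strongest
level, and *intermediate* otherwise ("reached" is inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CohortDesign
from .splicing_core import PsiMatrix

logger = logging.getLogger(__name__)

RESPONSE_CLASSES = ("early", "intermediate", "late")
EARLY_PSI = 0.20
LATE_PSI = 0.10
DEFAULT_MIN_SUPPORT = 5


@dataclass
class DoseSeries:
    """Mean PSI of one event across ordered dose levels 0..K (0 = untreated).

    ``support`` holds the best per-level junction read count, one row per
    defining junction (cassette events have two rows).
    """

    event_id: str
    psi: np.ndarray  # length K+1, level 0 first; NaN = missing
    support: np.ndarray  # shape (n_junctions, K+1)

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.support = np.atleast_2d(np.asarray(self.support))
        if self.support.shape[1] != self.psi.shape[0]:
            raise ValueError("support and psi must cover the same levels")
        finite = self.psi[np.isfinite(self.psi)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("PSI must lie in [0, 1]")

    @property
    def n_levels(self) -> int:
        """Knockdown levels beyond the untreated control."""
        return self.psi.shape[0] - 1


def filter_support(
    series: DoseSeries, min_reads: int = DEFAULT_MIN_SUPPORT
) -> DoseSeries | None:
    """Keep the series only if every defining junction reaches
    ``min_reads`` junction-spanning reads at some level (both sides must
    pass for cassette events).  Returns None when excluded."""
    per_junction_max = series.support.max(axis=1)
    if (per_junction_max >= min_reads).all():
        return series
    return None


def classify_responsiveness_values(psi_kd: np.ndarray) -> str:
    """Stage a noise-free or mean PSI vector over knockdown levels 1..K.

    early: PSI >= 0.20 at level 1 or 2; late: PSI < 0.10 at every level
    except the strongest and >= 0.10 at the strongest; else intermediate.
    """
    psi_kd = np.asarray(psi_kd, dtype=float)
    if psi_kd.shape[0] < 3:
        raise ValueError("need >= 3 knockdown levels")
    if np.nanmax(psi_kd[:2]) >= EARLY_PSI:
        return "early"
    if (psi_kd[:-1] < LATE_PSI).all() and psi_kd[-1] >= LATE_PSI:
        return "late"
    return "intermediate"


def classify_responsiveness(series: DoseSeries) -> str:
    """Stage one event; missing PSI at a level is treated as 0 (logged)."""
    psi_kd = series.psi[1:].copy()
    n_missing = int(np.isnan(psi_kd).sum())
    if n_missing:
        logger.info("classify_responsiveness: %s has %d missing level(s), "
                    "treated as 0", series.event_id, n_missing)
        psi_kd = np.nan_to_num(psi_kd, nan=0.0)
    return classify_responsiveness_values(psi_kd)


def dose_series_from_psi(
    psi: PsiMatrix,
    design: CohortDesign,
    junction_ids: list[str] | None = None,
    partners: dict[str, str] | None = None,
) -> dict[str, DoseSeries]:
    """Build per-event dose series from a PSI matrix and a dosed design.

    ``partners`` optionally maps an event's junction id to its cassette
    partner so both sides contribute support.
    """
    if "dose_level" not in design.table.columns:
        raise ValueError("design lacks a dose_level column")
    doses = design.table.loc[psi.sample_ids, "dose_level"].astype(int)
    levels = sorted(doses.unique())
    jids = junction_ids if junction_ids is not None else psi.junction_ids
    partners = partners or {}
    counts = psi.psi * psi.cluster_totals  # reconstruct junction read counts
    out: dict[str, DoseSeries] = {}
    for jid in jids:
        mean_psi, sup_rows = [], []
        members = [jid] + ([partners[jid]] if jid in partners else [])
        for member in members:
            row = counts.loc[member]
            sup_rows.append(
                [
                    float(row[doses.index[doses == lev]].max(skipna=True))
                    if (doses == lev).any() else 0.0
                    for lev in levels
                ]
            )
        for lev in levels:
            sel = doses.index[doses == lev]
            mean_psi.append(float(psi.psi.loc[jid, sel].mean(skipna=True)))
        out[jid] = DoseSeries(jid, np.array(mean_psi),
                              np.nan_to_num(np.array(sup_rows)))
    return out


def category_concordance(
    class_a: pd.Series, class_b: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate responsiveness classes of events matched by junction
    coordinates across two datasets.

    Returns the 3x3 contingency with an ``unmatched`` margin on each axis,
    and the agreement fraction among matched events (NaN if none match).
    """
    cats = list(RESPONSE_CLASSES)
    idx = cats + ["unmatched"]
    table = pd.DataFrame(0, index=idx, columns=idx)
    shared = class_a.index.intersection(class_b.index)
    for ev in shared:
        table.loc[class_a[ev], class_b[ev]] += 1
    for ev in class_a.index.difference(class_b.index):
        table.loc[class_a[ev], "unmatched"] += 1
    for ev in class_b.index.difference(class_a.index):
        table.loc["unmatched", class_b[ev]] += 1
    n_matched = len(shared)
    agreement = (
        float(np.trace(table.loc[cats, cats].values)) / n_matched
        if n_matched else float("nan")
    )
    return table, agreement
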