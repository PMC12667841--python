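"""NMD-sensitivity classification, dark-cryptic detection and
nuclear/cytoplasmic localisation of cryptic events.

A CE is *NMD-rescued* when inhibiting NMD raises its mean PSI by more
than 5 PSI points (strict).  A *dark* cryptic passes CE thresholds only
under NMD inhibition; it is *true dark* if additionally absent from every
reference knockdown dataset lacking NMD inhibition.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortDesign
from .splicing_core import CrypticEvent, PsiMatrix, normalize_median_of_ratios

logger = logging.getLogger(__name__)

DEFAULT_RESCUE_THRESHOLD = 0.05
#: Extended poison-exon QC bin width (3.3 PSI points).
DEFAULT_POISON_BIN = 0.033
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class NmdCall:
    event_id: str
    psi_kd: float
    psi_kd_nmdi: float
    delta: float
    nmd_class: str | None  # "rescued" / "non_rescued" / None when unquantified
    dark: bool = False
    true_dark: bool = False


def classify_nmd(
    event_ids: Sequence[str],
    psi_kd: Mapping[str, float],
    psi_kd_nmdi: Mapping[str, float],
    rescue_threshold: float = DEFAULT_RESCUE_THRESHOLD,
) -> list[NmdCall]:
    """Classify events as rescued (delta > threshold, strict) or not.

    ``psi_kd`` / ``psi_kd_nmdi`` are group-mean PSI per event under
    knockdown alone and knockdown + NMD inhibition.  Events missing from
    either condition get ``nmd_class=None`` and are logged.
    """
    calls: list[NmdCall] = []
    n_unset = 0
    for ev in event_ids:
        a = psi_kd.get(ev, np.nan)
        b = psi_kd_nmdi.get(ev, np.nan)
        if np.isnan(a) or np.isnan(b):
            n_unset += 1
            calls.append(NmdCall(ev, float(a), float(b), np.nan, None))
            continue
        delta = b - a
        cls = "rescued" if delta > rescue_threshold else "non_rescued"
        calls.append(NmdCall(ev, float(a), float(b), float(delta), cls))
    if n_unset:
        logger.info("classify_nmd: %d event(s) missing in one condition "
                    "left unclassified", n_unset)
    return calls


def _coord_key(event: CrypticEvent | tuple) -> tuple:
    if isinstance(event, CrypticEvent):
        return event.junction.coords
    return tuple(event)


def detect_dark(
    events_kd: Iterable[CrypticEvent | tuple],
    events_kd_nmdi: Iterable[CrypticEvent | tuple],
) -> list:
    """Events meeting CE criteria under KD + NMD inhibition but not under
    KD alone (matched by junction coordinates)."""
    kd_keys = {_coord_key(e) for e in events_kd}
    return [e for e in events_kd_nmdi if _coord_key(e) not in kd_keys]


def flag_true_dark(
    dark_events: Iterable[CrypticEvent | tuple],
    reference_kd_datasets: Sequence[Iterable[CrypticEvent | tuple]],
) -> list:
    """Dark events whose coordinates match no CE in any reference
    knockdown-without-NMD-inhibition dataset (exact match)."""
    dark_events = list(dark_events)
    if not reference_kd_datasets:
        warnings.warn("no reference KD datasets: every dark event is "
                      "vacuously true-dark")
        return dark_events
    seen = {
        _coord_key(e)
        for ref in reference_kd_datasets
        for e in ref
    }
    return [e for e in dark_events if _coord_key(e) not in seen]


def poison_exon_qc(
    psi: PsiMatrix,
    poison_junctions: Sequence[str],
    design: CohortDesign,
    bin_width: float = DEFAULT_POISON_BIN,
) -> tuple[pd.Series, int]:
    """Confirm NMD inhibition via known poison-exon junctions.

    Returns per-junction delta PSI (inhibited minus control group mean)
    and the number of junctions whose |delta| exceeds one histogram bin.
    """
    if "nmd_condition" not in design.table.columns:
        raise ValueError("design lacks an nmd_condition column")
    cond = design.table.loc[psi.sample_ids, "nmd_condition"]
    inhibited = list(cond.index[cond == "inhibited"])
    control = list(cond.index[cond != "inhibited"])
    if not inhibited:
        raise ValueError("design has no NMD-inhibited samples")
    found = [j for j in poison_junctions if j in psi.psi.index]
    if not found:
        raise ValueError("none of the poison junctions occur in the PSI matrix")
    delta = (
        psi.psi.loc[found, inhibited].mean(axis=1, skipna=True)
        - psi.psi.loc[found, control].mean(axis=1, skipna=True)
    )
    delta.name = "delta_psi"
    n_changed = int((delta.abs() > bin_width).sum())
    return delta, n_changed


# ---------------------------------------------------------------------------
# localisation
# ---------------------------------------------------------------------------


def compute_nc_ratio(
    nuclear: pd.DataFrame | pd.Series,
    cytoplasmic: pd.DataFrame | pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2 nuclear-over-cytoplasmic ratio per feature.

    Each fraction is normalised independently by median-of-ratios (a
    single-column input is left as-is, since size factors need >= 2
    columns to mean anything), averaged across its samples, and combined
    as log2((nuc + pc) / (cyt + pc)).  Features absent from either
    fraction are skipped with a log message.
    """
    def _collapse(frame) -> pd.Series:
        if isinstance(frame, pd.Series):
            return frame.astype(float)
        if frame.shape[1] == 1:
            return frame.iloc[:, 0].astype(float)
        _, norm = normalize_median_of_ratios(frame)
        return norm.mean(axis=1)

    nuc = _collapse(nuclear)
    cyt = _collapse(cytoplasmic)
    shared = nuc.index.intersection(cyt.index)
    n_skipped = len(nuc.index.union(cyt.index)) - len(shared)
    if n_skipped:
        logger.info("compute_nc_ratio: %d feature(s) absent in one fraction "
                    "skipped", n_skipped)
    ratio = np.log2((nuc[shared] + pseudocount) / (cyt[shared] + pseudocount))
    ratio.name = "log2_nc_ratio"
    return ratio


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for the Spearman statistic (n <= 10)."""
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    target = abs(rho_obs) - 1e-12
    n_extreme = 0
    n_total = 0
    for perm in itertools.permutations(range(n)):
        rho = float(np.dot(rx, ry[list(perm)])) / n
        n_extreme += abs(rho) >= target
        n_total += 1
    return n_extreme / n_total


def correlate_localization(
    x: Sequence[float] | pd.Series,
    y: Sequence[float] | pd.Series,
    method: str = "spearman",
) -> tuple[float, float]:
    """Spearman rank correlation between paired localisation ratios.

    Average ranks break ties.  Two-sided p: exhaustive permutation for
    n <= 10, t-approximation otherwise.  Constant input is an error
    (rho undefined).
    """
    if method != "spearman":
        raise ValueError("only the spearman method is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        # t approximation on n - 2 degrees of freedom
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)
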