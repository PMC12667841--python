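"""Biomarker evaluation and the composite cryptic-burden score.

Per dataset: PSI is z-scored per junction across all samples (missing
PSI — an uncovered cluster — counts as 0 inclusion first); each junction
is then a one-dimensional classifier at threshold zero, i.e. at the
cohort mean.  *Predictive* junctions (FPR <= 10%, TPR >= 10%, detected
in >= 5 distinct proteinopathy samples) are summed into a per-sample
cryptic burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortDesign, JunctionTable
from .splicing_core import PsiMatrix

DEFAULT_FPR_MAX = 0.10
DEFAULT_TPR_MIN = 0.10
DEFAULT_MIN_CASE_SAMPLES = 5
DEFAULT_MIN_READS_PER_SAMPLE = 2
DEFAULT_MIN_DETECT_SAMPLES = 2


class ZMatrix:
    """Junctions x samples z-scored PSI with the moments used.

    Degenerate junctions (zero standard deviation) have all-zero rows and
    are flagged.
    """

    def __init__(self, z: pd.DataFrame, mean: pd.Series, sd: pd.Series,
                 degenerate: pd.Series) -> None:
        self.z = z
        self.mean = mean
        self.sd = sd
        self.degenerate = degenerate

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)

    @property
    def junction_ids(self) -> list[str]:
        return list(self.z.index)


def zscore_psi(psi: PsiMatrix | pd.DataFrame, impute_missing: float | None = 0.0) -> ZMatrix:
    """z-score PSI per junction across samples (sample sd, n-1 denominator).

    ``impute_missing`` replaces missing PSI before scoring; the default 0
    reflects that a junction absent from a sample's clusters carries no
    supporting reads.  Pass None to propagate NaN instead.
    """
    values = psi.psi if isinstance(psi, PsiMatrix) else psi
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    values = values.astype(float)
    if impute_missing is not None:
        values = values.fillna(impute_missing)
    mean = values.mean(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=1, skipna=True)
    # PSI lives on [0, 1]; anything this small is a constant row up to
    # floating-point noise
    degenerate = (sd <= 1e-12) | sd.isna()
    safe_sd = sd.where(~degenerate, 1.0)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = 0.0
    mean.name, sd.name, degenerate.name = "mean", "sd", "degenerate"
    return ZMatrix(z, mean, sd, degenerate)


def classify_at_zero(z: ZMatrix, design: CohortDesign) -> pd.DataFrame:
    """Per-junction TPR / FPR at decision threshold zero (the cohort mean).

    A sample is called positive iff its z-scored PSI is strictly above 0;
    z == 0 counts negative.
    """
    samples = z.sample_ids
    design.validate_against_samples(samples)
    is_case = design.is_case(samples).values
    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present")
    positive = z.z.values > 0
    tpr = positive[:, is_case].sum(axis=1) / n_case
    fpr = positive[:, ~is_case].sum(axis=1) / n_ctrl
    return pd.DataFrame({"tpr": tpr, "fpr": fpr}, index=z.junction_ids)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals P(score_case > score_control) + 0.5 P(equal), and hence the
    trapezoidal ROC area; ties receive average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def detection_flags(
    table: JunctionTable,
    design: CohortDesign,
    min_reads_per_sample: int = DEFAULT_MIN_READS_PER_SAMPLE,
    min_samples: int = DEFAULT_MIN_DETECT_SAMPLES,
) -> pd.DataFrame:
    """Per-junction detection: a sample detects a junction at
    >= ``min_reads_per_sample`` reads; the junction is detected overall
    at >= ``min_samples`` detecting samples.  Case counts use the
    proteinopathy / KD side of the design."""
    design.validate_against(table)
    detected = table.counts >= min_reads_per_sample
    is_case = design.is_case(table.sample_ids).values
    n_detected = detected.sum(axis=1)
    n_detected_case = detected[:, is_case].sum(axis=1)
    return pd.DataFrame(
        {
            "n_detected": n_detected,
            "n_detected_case": n_detected_case,
            "detected": n_detected >= min_samples,
        },
        index=table.junction_ids,
    )


@dataclass
class MarkerStats:
    junction_id: str
    tpr: float
    fpr: float
    auc: float
    n_detected_case: int
    predictive: bool


def evaluate_markers(
    z: ZMatrix,
    design: CohortDesign,
    detection: pd.DataFrame,
    fpr_max: float = DEFAULT_FPR_MAX,
    tpr_min: float = DEFAULT_TPR_MIN,
    min_case_samples: int = DEFAULT_MIN_CASE_SAMPLES,
) -> pd.DataFrame:
    """TPR/FPR at zero, AUC and the predictive flag for every junction."""
    rates = classify_at_zero(z, design)
    labels = design.is_case(z.sample_ids).values
    auc = pd.Series(
        [roc_auc(z.z.loc[j].values, labels) for j in z.junction_ids],
        index=z.junction_ids, name="auc",
    )
    stats_df = rates.join(auc)
    stats_df["n_detected_case"] = detection["n_detected_case"].reindex(
        stats_df.index).fillna(0).astype(int)
    stats_df["predictive"] = (
        (stats_df["fpr"] <= fpr_max)
        & (stats_df["tpr"] >= tpr_min)
        & (stats_df["n_detected_case"] >= min_case_samples)
    )
    return stats_df


def select_predictive(stats_df: pd.DataFrame) -> list[str]:
    """Junction ids passing the predictive cutoffs (inclusive
    inequalities, per the MarkerStats invariant)."""
    return list(stats_df.index[stats_df["predictive"]])


def compute_burden(z: ZMatrix, predictive: list[str]) -> pd.Series:
    """Per-sample cryptic burden: summed z-scored PSI over the dataset's
    predictive junctions.  Every sample is scored, cases and controls
    alike."""
    if not predictive:
        raise ValueError("predictive set is empty; burden undefined")
    burden = z.z.loc[list(predictive)].sum(axis=0)
    burden.name = "burden"
    return burden


def compare_groups(values, grouping) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison of a per-sample score
    between two groups (exact p for min(n) <= 8 without ties, normal
    approximation with tie correction otherwise)."""
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    groups = pd.unique(grouping)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    a = values[grouping == groups[0]]
    b = values[grouping == groups[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(values)) < values.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
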