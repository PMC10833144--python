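"""Three-stage differential-abundance biomarker discovery.

Stage 1 screens every peptide case-vs-normal-control with a two-sided
Wilcoxon rank-sum test and false-discovery-rate adjustment; candidates
(adjusted p < alpha) are then required to show an unadjusted p < alpha AND
the same direction of change in both additional comparisons (cases vs
disease-control group, cases vs other-CKD group) to be retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, IntensityDataset

STATUS_CANDIDATE = "candidate_step1"
STATUS_RETAINED = "retained_final"
STATUS_EXCLUDED = "excluded"


@dataclass
class DiscoveryResult:
    """Per-peptide statistics and retention status for the three-stage filter.

    ``table`` has one row per peptide with the raw/adjusted stage-1 p-value,
    stage-2/3 unadjusted p-values, per-stage directions ('up'/'down' in cases
    relative to the comparator), group means and a status/reason pair.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def candidates(self) -> list[str]:
        mask = self.table["status"].isin([STATUS_CANDIDATE, STATUS_RETAINED])
        return self.table.loc[mask, "peptide_id"].tolist()

    @property
    def retained(self) -> list[str]:
        mask = self.table["status"] == STATUS_RETAINED
        return self.table.loc[mask, "peptide_id"].tolist()


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration when both samples have at most 10 observations
    and no ties are present, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size <= 10 and y.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def bh_adjust(p: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (or Bonferroni).

    Order-preserving; every adjusted value is >= its raw value and <= 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "fdr_bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards (step-up)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _columnwise_rank_test(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized tie-corrected two-sided rank-test p-values per column.

    Columns that are constant across both groups get p = 1.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=0,
        )
        p = np.asarray(res.pvalue, dtype=float)
    pooled = np.vstack([a, b])
    constant = (pooled == pooled[0]).all(axis=0)
    p[constant] = 1.0
    return np.minimum(np.nan_to_num(p, nan=1.0), 1.0)


def _direction(case_means: np.ndarray, comp_means: np.ndarray) -> np.ndarray:
    diff = case_means - comp_means
    return np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))


def step1_screen(
    data: IntensityDataset,
    alpha: float = 0.05,
    method: str = "fdr_bh",
    min_detection_frequency: float = 0.0,
) -> DiscoveryResult:
    """Stage-1 screen: rank test cases vs NC per peptide, FDR adjustment.

    ``min_detection_frequency`` optionally drops peptides detected (nonzero)
    in less than that fraction of all samples before testing; it is off by
    default.
    """
    cases = data.group_matrix("pFSGS")
    controls = data.group_matrix("NC")
    if cases.shape[0] == 0 or controls.shape[0] == 0:
        raise DataError("step 1 requires both pFSGS and NC samples")

    tested = np.ones(data.n_peptides, dtype=bool)
    if min_detection_frequency > 0:
        freq = (data.intensities > 0).mean(axis=0)
        tested = freq >= min_detection_frequency

    p_raw = np.full(data.n_peptides, np.nan)
    p_adj = np.full(data.n_peptides, np.nan)
    p_raw[tested] = _columnwise_rank_test(cases[:, tested], controls[:, tested])
    p_adj[tested] = bh_adjust(p_raw[tested], method=method)

    mean_case = cases.mean(axis=0)
    mean_nc = controls.mean(axis=0)
    direction1 = _direction(mean_case, mean_nc)

    candidate = tested & (p_adj < alpha) & (direction1 != "none")
    status = np.where(candidate, STATUS_CANDIDATE, STATUS_EXCLUDED)
    reason = np.where(
        candidate, "", np.where(tested, "step1_not_significant", "low_detection")
    )

    table = pd.DataFrame(
        {
            "peptide_id": data.peptide_ids,
            "p_step1_raw": p_raw,
            "p_step1_adj": p_adj,
            "direction_step1": direction1,
            "p_step2": np.nan,
            "direction_step2": "",
            "p_step3": np.nan,
            "direction_step3": "",
            "mean_pfsgs": mean_case,
            "mean_nc": mean_nc,
            "mean_sfsgs": np.nan,
            "mean_ckd": np.nan,
            "status": status,
            "reason": reason,
        }
    )
    return DiscoveryResult(table=table, alpha=alpha)


def directional_filter(
    result: DiscoveryResult,
    data: IntensityDataset,
    alpha: float = 0.05,
) -> DiscoveryResult:
    """Stages 2-3: keep candidates significant with consistent direction in
    cases-vs-sFSGS and cases-vs-other-CKD; everything else is excluded with
    an explicit reason."""
    cases = data.group_matrix("pFSGS")
    sfsgs = data.group_matrix("sFSGS")
    ckd = data.group_matrix("CKD_other")
    if sfsgs.shape[0] == 0 or ckd.shape[0] == 0:
        raise DataError("directional filter requires sFSGS and CKD_other samples")

    table = result.table.copy()
    idx = {p: i for i, p in enumerate(data.peptide_ids)}
    cand_rows = table.index[table["status"] == STATUS_CANDIDATE]
    cols = np.array([idx[table.at[r, "peptide_id"]] for r in cand_rows], dtype=int)
    if cols.size == 0:
        return DiscoveryResult(table=table, alpha=result.alpha)

    p2 = _columnwise_rank_test(cases[:, cols], sfsgs[:, cols])
    p3 = _columnwise_rank_test(cases[:, cols], ckd[:, cols])
    mean_case = cases[:, cols].mean(axis=0)
    mean_s = sfsgs[:, cols].mean(axis=0)
    mean_c = ckd[:, cols].mean(axis=0)
    dir2 = _direction(mean_case, mean_s)
    dir3 = _direction(mean_case, mean_c)

    table.loc[cand_rows, "p_step2"] = p2
    table.loc[cand_rows, "p_step3"] = p3
    table.loc[cand_rows, "direction_step2"] = dir2
    table.loc[cand_rows, "direction_step3"] = dir3
    table.loc[cand_rows, "mean_sfsgs"] = mean_s
    table.loc[cand_rows, "mean_ckd"] = mean_c

    dir1 = table.loc[cand_rows, "direction_step1"].to_numpy()
    sig2 = p2 < alpha
    sig3 = p3 < alpha
    same2 = dir2 == dir1
    same3 = dir3 == dir1
    keep = sig2 & sig3 & same2 & same3

    reasons = np.select(
        [~sig2, ~sig3, ~(same2 & same3)],
        ["step2_not_significant", "step3_not_significant", "direction_mismatch"],
        default="",
    )
    table.loc[cand_rows, "status"] = np.where(keep, STATUS_RETAINED, STATUS_EXCLUDED)
    table.loc[cand_rows, "reason"] = reasons
    return DiscoveryResult(table=table, alpha=result.alpha)


def discover(
    data: IntensityDataset, alpha: float = 0.05, method: str = "fdr_bh"
) -> DiscoveryResult:
    """Run the full three-stage filter on one dataset."""
    return directional_filter(step1_screen(data, alpha=alpha, method=method),
                              data, alpha=alpha)
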