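"""ROC/AUC machinery, DeLong confidence intervals and paired tests,
independent specificity evaluation, covariable logistic regression and the
two-term nomogram combination, plus cohort-table hypothesis tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .data import DataError, IntensityDataset
from .svmpanel import TrainedPanel, score_samples


# ---------------------------------------------------------------------------
# AUC and DeLong
# ---------------------------------------------------------------------------

def auc(cases, controls) -> float:
    """Tie-corrected probability that a random case outscores a random
    control (ties count 1/2); equals the trapezoidal area under the
    empirical ROC curve."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise DataError("both classes required for AUC")
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)
    r_cases = ranks[: cases.size].sum()
    u = r_cases - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))


def roc_points(cases, controls) -> pd.DataFrame:
    """Empirical ROC points (FPR, TPR, threshold), monotone non-decreasing."""
    from sklearn.metrics import roc_curve

    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    s = np.concatenate([cases, controls])
    fpr, tpr, thr = roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _delong_placements(cases: np.ndarray, controls: np.ndarray):
    """Mid-rank placement values V10 (per case) and V01 (per control)."""
    m, n = cases.size, controls.size
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)
    r_cases, r_controls = ranks[:m], ranks[m:]
    rank_within_cases = stats.rankdata(cases)
    rank_within_controls = stats.rankdata(controls)
    v10 = (r_cases - rank_within_cases) / n
    v01 = 1.0 - (r_controls - rank_within_controls) / m
    a = v10.mean()
    return a, v10, v01


def delong_variance(cases, controls) -> tuple[float, float]:
    """DeLong AUC estimate and its variance."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    a, v10, v01 = _delong_placements(cases, controls)
    m, n = cases.size, controls.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(a), float(s10 / m + s01 / n)


def delong_ci(cases, controls, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong normal-approximation CI truncated to [0, 1]."""
    a, var = delong_variance(cases, controls)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return a, (max(0.0, a - half), min(1.0, a + half))


@dataclass
class DelongComparison:
    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    delta: float
    p_difference: float


def delong_ci_and_test(scores_a, scores_b, labels) -> DelongComparison:
    """Paired DeLong comparison of two scores on the same samples.

    ``labels`` is boolean (True = case). Returns both AUCs with 95% CIs and
    the two-sided p-value for their difference.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise DataError("paired comparison requires equally shaped inputs")
    ca, na = scores_a[labels], scores_a[~labels]
    cb, nb = scores_b[labels], scores_b[~labels]
    a_a, v10_a, v01_a = _delong_placements(ca, na)
    a_b, v10_b, v01_b = _delong_placements(cb, nb)
    m, n = ca.size, na.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = a_a - a_b
    if var_delta <= 1e-16:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2.0 * stats.norm.sf(abs(z)))
    zq = stats.norm.ppf(0.975)
    ci_a = (max(0.0, a_a - zq * np.sqrt(max(cov[0, 0], 0))),
            min(1.0, a_a + zq * np.sqrt(max(cov[0, 0], 0))))
    ci_b = (max(0.0, a_b - zq * np.sqrt(max(cov[1, 1], 0))),
            min(1.0, a_b + zq * np.sqrt(max(cov[1, 1], 0))))
    return DelongComparison(float(a_a), float(a_b), ci_a, ci_b, float(delta), p)


# ---------------------------------------------------------------------------
# Operating points and independent specificity
# ---------------------------------------------------------------------------

def sensitivity_percent(n_detected: int, n_cases: int) -> float:
    """Sensitivity as a percentage to one decimal."""
    if n_cases <= 0:
        raise DataError("no cases")
    return round(100.0 * n_detected / n_cases, 1)


def specificity_percent(n_correct: int, n_total: int) -> float:
    """Specificity as a percentage to one decimal."""
    if n_total <= 0:
        raise DataError("no controls")
    return round(100.0 * n_correct / n_total, 1)


def operating_point(cases, controls, cutoff: float) -> tuple[float, float]:
    """(sensitivity %, specificity %) at a fixed cutoff (case if score >= cutoff)."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    sens = sensitivity_percent(int((cases >= cutoff).sum()), cases.size)
    spec = specificity_percent(int((controls < cutoff).sum()), controls.size)
    return sens, spec


def independent_specificity(
    panel: TrainedPanel, data: IntensityDataset
) -> tuple[int, int, float]:
    """Fraction of non-case samples scoring below the stored cutoff.

    ``data`` must contain no case-group (pFSGS) samples; returns
    ``(n_correct, n_total, specificity_percent)``.
    """
    if any(g == "pFSGS" for g in data.group):
        raise DataError("specificity evaluation dataset must not contain pFSGS samples")
    if panel.cutoff is None:
        raise DataError("panel has no cutoff")
    scores, _, _ = score_samples(panel, data)
    n_total = scores.size
    n_correct = int((scores < panel.cutoff).sum())
    return n_correct, n_total, specificity_percent(n_correct, n_total)


# ---------------------------------------------------------------------------
# Covariable regression and nomogram
# ---------------------------------------------------------------------------

@dataclass
class CovariableModel:
    terms: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float] | None
    p_values: dict[str, float] | None
    n_samples: int
    penalized: bool = False


def covariable_screen(
    frame: pd.DataFrame,
    outcome: str = "outcome",
    terms: tuple[str, ...] = ("score", "sex", "age", "proteinuria", "egfr", "ifta"),
) -> CovariableModel:
    """Multivariable logistic regression of a binary outcome on the given
    terms (complete cases only), with Wald p-values.

    If the likelihood does not converge (separation), an L2-penalized fit is
    used instead and the result is flagged ``penalized=True`` (no p-values).
    """
    cols = [outcome, *terms]
    df = frame[cols].copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "M").astype(float)
    df = df.dropna()
    y = df[outcome].astype(float).to_numpy()
    if y.sum() < 10:
        raise DataError("need >= 10 events for the covariable screen")
    X = sm.add_constant(df[list(terms)].astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        # NaN standard errors from collinear columns are tolerated (their
        # Wald p is undefined); exploding coefficients signal separation
        if not converged or (np.abs(fit.params) > 1e3).any():
            raise np.linalg.LinAlgError("separation suspected")
        coefs = dict(zip(X.columns, fit.params))
        ses = dict(zip(X.columns, fit.bse))
        ps = dict(zip(X.columns, fit.pvalues))
        return CovariableModel(list(terms), coefs, ses, ps, len(df), penalized=False)
    except Exception:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit_regularized(
                method="l1", alpha=1.0, disp=0, maxiter=500
            )
        coefs = dict(zip(X.columns, np.asarray(fit.params)))
        return CovariableModel(list(terms), coefs, None, None, len(df), penalized=True)


@dataclass
class Nomogram:
    """Two-term logistic combination of the panel score and proteinuria."""

    coefficients: dict[str, float]
    intercept: float
    points_scale: dict[str, float]
    combined_scores: np.ndarray
    auc_combined: float
    auc_score_alone: float
    auc_proteinuria_alone: float
    vs_score: DelongComparison = field(repr=False, default=None)
    vs_proteinuria: DelongComparison = field(repr=False, default=None)

    def predict(self, score: np.ndarray, proteinuria: np.ndarray) -> np.ndarray:
        return (
            self.intercept
            + self.coefficients["score"] * np.asarray(score, dtype=float)
            + self.coefficients["proteinuria"] * np.asarray(proteinuria, dtype=float)
        )


def build_nomogram(scores, proteinuria, labels) -> Nomogram:
    """Fit the two-term logistic model and compare the combined predictor
    against each single term with paired DeLong tests."""
    scores = np.asarray(scores, dtype=float)
    proteinuria = np.asarray(proteinuria, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = np.isfinite(scores) & np.isfinite(proteinuria)
    scores, proteinuria, labels = scores[keep], proteinuria[keep], labels[keep]
    if np.ptp(scores) == 0 or np.ptp(proteinuria) == 0:
        raise DataError("constant predictor")
    X = sm.add_constant(
        pd.DataFrame({"score": scores, "proteinuria": proteinuria}),
        has_constant="add",
    )
    with np.errstate(all="ignore"):
        try:
            fit = sm.Logit(labels.astype(float), X).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)
            if not np.isfinite(params).all() or (np.abs(params) > 1e3).any():
                raise np.linalg.LinAlgError
        except Exception:
            fit = sm.Logit(labels.astype(float), X).fit_regularized(
                method="l1", alpha=0.1, disp=0, maxiter=500
            )
            params = np.asarray(fit.params)
    intercept, b_score, b_prot = params
    combined = intercept + b_score * scores + b_prot * proteinuria
    # nomogram points: each term's maximal linear-predictor span mapped so the
    # widest term is worth 100 points
    spans = {
        "score": abs(b_score) * np.ptp(scores),
        "proteinuria": abs(b_prot) * np.ptp(proteinuria),
    }
    widest = max(spans.values()) or 1.0
    points = {k: 100.0 * v / widest for k, v in spans.items()}
    a_comb = auc(combined[labels], combined[~labels])
    a_score = auc(scores[labels], scores[~labels])
    a_prot = auc(proteinuria[labels], proteinuria[~labels])
    return Nomogram(
        coefficients={"score": float(b_score), "proteinuria": float(b_prot)},
        intercept=float(intercept),
        points_scale=points,
        combined_scores=combined,
        auc_combined=a_comb,
        auc_score_alone=a_score,
        auc_proteinuria_alone=a_prot,
        vs_score=delong_ci_and_test(combined, scores, labels),
        vs_proteinuria=delong_ci_and_test(combined, proteinuria, labels),
    )


# ---------------------------------------------------------------------------
# Cohort-table statistics
# ---------------------------------------------------------------------------

def cohort_table_stats(kind: str, a, b=None) -> float:
    """Two-sided p-value for one cohort-table comparison.

    ``kind``:
      - ``"continuous"``: Student's t test on two raw vectors.
      - ``"nonnormal"``: Mann-Whitney U test on two raw vectors.
      - ``"categorical"``: chi-square with Yates continuity correction on a
        2x2 count table passed as ``a`` (``b`` must be None).
    """
    if kind == "categorical":
        if b is not None:
            raise DataError("categorical test takes a single 2x2 table")
        table = np.asarray(a, dtype=float)
        if table.shape != (2, 2):
            raise DataError("categorical test requires a 2x2 table")
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (
            table.sum(axis=1) == 0
        ).any():
            return 1.0
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
        return float(p)
    if b is None:
        raise DataError(f"{kind} test requires two raw vectors")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "continuous":
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if kind == "nonnormal":
        if np.all(np.concatenate([a, b]) == a[0]):
            return 1.0
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    raise DataError(f"unknown variable kind {kind!r}")
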