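"""Assessment procedures for target-prediction scores.

ROC/AUC with a paired significance test for AUC differences (DeLong or
bootstrap), precision-recall curves, a positives-only sensitivity-vs-threshold
curve for datasets without a defensible negative set, hypergeometric
enrichment of predicted targets in a test set, decile-wise ECDF comparison of
per-gene response measures against a reference gene set (two-sample KS and
rank-sum tests), and the additivity regression of co-transfection fold
changes with backward elimination of insignificant terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn import metrics as skm

__all__ = [
    "RocResult", "roc_auc", "AucComparison", "compare_auc",
    "PrecisionRecallResult", "precision_recall", "SensitivityCurve",
    "sensitivity_vs_threshold", "enrichment_pvalue",
    "decile_ecdf_analysis", "AdditivityFit", "additivity_regression",
]


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    return y


def roc_auc(scores, labels) -> RocResult:
    """ROC curve (every distinct score as a threshold) and trapezoidal AUC.

    The AUC equals the rank statistic P(score_pos > score_neg) + 0.5 P(tie).
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr, tpr, thr, auc, int(y.sum()), int((1 - y).sum()))


# --------------------------------------------------------------------------
# Paired AUC comparison (DeLong / bootstrap)
# --------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks as used by DeLong's structural components (1-based)."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """AUCs and the DeLong covariance matrix for paired score vectors.

    ``scores`` has shape (k, n).  Uses the midrank formulation: for each
    classifier the structural components are V10 (per positive) and V01
    (per negative); the AUC covariance is S10/m + S01/n.
    """
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for i in range(k):
        all_r = _midrank(np.concatenate([pos[i], neg[i]]))
        pos_r = _midrank(pos[i])
        neg_r = _midrank(neg[i])
        aucs[i] = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[i] = (all_r[:m] - pos_r) / n
        v01[i] = 1.0 - (all_r[m:] - neg_r) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    cov = s10 / m + s01 / n
    return aucs, np.atleast_2d(cov)


@dataclass
class AucComparison:
    auc_a: float
    auc_b: float
    diff: float
    p_value: float
    method: str
    note: str = ""


def compare_auc(
    scores_a,
    scores_b,
    labels,
    method: str = "delong",
    seed: int = 0,
    n_boot: int = 2000,
) -> AucComparison:
    """Two-sided test of the paired AUC difference of two score vectors.

    DeLong's asymptotic test by default; a paired stratified bootstrap
    (>= 2000 resamples) as an alternative.  A degenerate (zero-variance)
    difference is reported as such, with p = 1 for a zero difference and
    p = 0 otherwise, never as NaN.
    """
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("score vectors and labels must have equal length")

    if method == "delong":
        aucs, cov = _delong_components(np.vstack([a, b]), y)
        diff = float(aucs[0] - aucs[1])
        var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        if var <= np.finfo(float).tiny:
            p = 1.0 if abs(diff) < 1e-12 else 0.0
            return AucComparison(float(aucs[0]), float(aucs[1]), diff, p,
                                 "delong", note="degenerate variance")
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
        return AucComparison(float(aucs[0]), float(aucs[1]), diff, p, "delong")

    if method == "bootstrap":
        n_boot = max(int(n_boot), 2000)
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        auc_a = roc_auc(a, y).auc
        auc_b = roc_auc(b, y).auc
        diffs = np.empty(n_boot)
        for i in range(n_boot):
            idx = np.concatenate([
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ])
            yi = y[idx]
            diffs[i] = roc_auc(a[idx], yi).auc - roc_auc(b[idx], yi).auc
        p = float(min(1.0, 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())))
        return AucComparison(auc_a, auc_b, float(auc_a - auc_b), p, "bootstrap")

    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# Precision-recall
# --------------------------------------------------------------------------

@dataclass
class PrecisionRecallResult:
    precision: np.ndarray  # achieved points only, ordered by increasing recall
    recall: np.ndarray
    thresholds: np.ndarray
    area: float


def precision_recall(scores, labels) -> PrecisionRecallResult:
    """Precision-recall curve over achieved thresholds (tied scores grouped).

    The area is the trapezoid over the achieved points (the artificial
    recall-0/precision-1 anchor is excluded), matching how PR areas are
    usually reported for score rankings.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    prec, rec, thr = skm.precision_recall_curve(y, s)
    # sklearn appends a final (recall 0, precision 1) anchor with no threshold
    prec, rec = prec[:-1], rec[:-1]
    # one point per achieved recall: the best precision (highest threshold)
    keep = {}
    for p, r, t in zip(prec, rec, thr):
        if r not in keep or p > keep[r][0]:
            keep[r] = (p, t)
    rec = np.array(sorted(keep))
    prec = np.array([keep[r][0] for r in rec])
    thr = np.array([keep[r][1] for r in rec])
    area = float(np.trapezoid(prec, rec)) if rec.size > 1 else 0.0
    return PrecisionRecallResult(prec, rec, thr, area)


# --------------------------------------------------------------------------
# Positives-only sensitivity curve
# --------------------------------------------------------------------------

@dataclass
class SensitivityCurve:
    thresholds: np.ndarray
    frac_pos: np.ndarray   # fraction of positive-set genes called targets
    frac_all: np.ndarray   # fraction of all genes called targets
    area: float            # trapezoid of frac_pos over the normalized threshold axis
    not_standard_roc: bool = True


def sensitivity_vs_threshold(scores_all, scores_pos, grid=None) -> SensitivityCurve:
    """Fraction of positive-set genes called targets at each score threshold.

    For datasets with positives but no defensible negative set: a gene is
    "called" when its score >= threshold.  The reported area (over the
    min-max-normalized threshold axis) is flagged as not a standard ROC AUC.
    """
    s_all = np.asarray(scores_all, dtype=float)
    s_pos = np.asarray(scores_pos, dtype=float)
    if s_pos.size == 0:
        raise ValueError("positive score set is empty")
    if s_all.size == 0:
        raise ValueError("whole-set scores are empty")
    if grid is None:
        grid = np.linspace(s_all.min(), s_all.max(), 101)
    grid = np.asarray(grid, dtype=float)
    frac_pos = np.array([(s_pos >= t).mean() for t in grid])
    frac_all = np.array([(s_all >= t).mean() for t in grid])
    span = grid.max() - grid.min()
    x = (grid - grid.min()) / span if span > 0 else np.zeros_like(grid)
    area = float(np.trapezoid(frac_pos[np.argsort(x)], np.sort(x)))
    return SensitivityCurve(grid, frac_pos, frac_all, area)


# --------------------------------------------------------------------------
# Hypergeometric enrichment
# --------------------------------------------------------------------------

def enrichment_pvalue(n_universe: int, n_set: int, n_predicted: int, n_overlap: int) -> float:
    """Upper-tail hypergeometric P(X >= n_overlap) for a gene-set overlap.

    ``n_set`` genes of interest within a universe of ``n_universe``;
    ``n_predicted`` genes called targets; ``n_overlap`` in the intersection.
    """
    counts = dict(n_universe=n_universe, n_set=n_set,
                  n_predicted=n_predicted, n_overlap=n_overlap)
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"negative count in {counts}")
    if n_set > n_universe or n_predicted > n_universe:
        raise ValueError(f"set larger than universe in {counts}")
    if n_overlap > min(n_set, n_predicted):
        raise ValueError(f"overlap exceeds smaller set in {counts}")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set, n_predicted))


# --------------------------------------------------------------------------
# Decile ECDF analysis
# --------------------------------------------------------------------------

def decile_ecdf_analysis(
    scores,
    measure,
    reference_measure,
    *,
    n_bins: int = 10,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Compare per-decile response distributions with a reference gene set.

    Scored genes are split into ``n_bins`` score deciles (decile 1 = highest
    scores; ties broken by stable sort order) and each decile's per-gene
    ``measure`` (e.g. log fold change) is compared with the measure of
    ``reference_measure`` genes using the two-sample Kolmogorov-Smirnov
    distance and the two-sided rank-sum test.  Deciles with fewer than
    ``min_genes`` genes are flagged and their tests skipped.
    """
    s = np.asarray(scores, dtype=float)
    m = np.asarray(measure, dtype=float)
    ref = np.asarray(reference_measure, dtype=float)
    if s.shape != m.shape:
        raise ValueError("scores and measure must be aligned")
    if ref.size == 0:
        raise ValueError("reference measure is empty")
    order = np.argsort(-s, kind="stable")
    chunks = np.array_split(m[order], n_bins)
    rows = []
    for d, vals in enumerate(chunks, start=1):
        row = {
            "decile": d,
            "n": int(vals.size),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sdm": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
        }
        if vals.size < min_genes:
            row.update(ks_d=np.nan, ks_p=np.nan, wilcoxon_p=np.nan, flagged=True)
        else:
            ks = stats.ks_2samp(vals, ref)
            mw = stats.mannwhitneyu(vals, ref, alternative="two-sided")
            row.update(ks_d=float(ks.statistic), ks_p=float(ks.pvalue),
                       wilcoxon_p=float(mw.pvalue), flagged=False)
        rows.append(row)
    return pd.DataFrame(rows).set_index("decile")


# --------------------------------------------------------------------------
# Additivity regression with backward elimination
# --------------------------------------------------------------------------

@dataclass
class AdditivityFit:
    """Result of the co-transfection additivity regression.

    The full model regresses the co-transfection fold change on the two
    single-transfection fold changes, their product, and an intercept;
    backward elimination then drops the least significant slope while its
    p-value exceeds ``alpha`` (the intercept is always retained).
    """

    coef_full: dict
    coef_reduced: dict
    r2_full: float
    r2_reduced: float
    retained: list
    trace: list = field(default_factory=list)  # (term, p_at_removal, r2_after)
    alpha: float = 0.05


def additivity_regression(fc_l, fc_m, fc_lm, alpha: float = 0.05) -> AdditivityFit:
    """Fit FC_lm ~ intercept + a*FC_l + b*FC_m + c*FC_l*FC_m, then prune."""
    fl = np.asarray(fc_l, dtype=float)
    fm = np.asarray(fc_m, dtype=float)
    y = np.asarray(fc_lm, dtype=float)
    if not (fl.shape == fm.shape == y.shape):
        raise ValueError("fold-change vectors must be aligned")
    if y.size < 10:
        raise ValueError(f"need at least 10 genes, got {y.size}")
    X = pd.DataFrame({"fc_l": fl, "fc_m": fm, "fc_l:fc_m": fl * fm})
    design = sm.add_constant(X)
    if np.linalg.cond(design.to_numpy()) > 1e10:
        warnings.warn("additivity regression design is near-collinear",
                      stacklevel=2)

    fit = sm.OLS(y, design).fit()
    r2_full = float(fit.rsquared)
    coef_full = dict(fit.params)

    terms = list(X.columns)
    trace = []
    current = fit
    while terms:
        pvals = current.pvalues.drop("const").fillna(1.0)
        # perfect fits leave machine-noise coefficients whose t-tests are
        # meaningless; a numerically zero slope is never significant
        coefs = current.params.drop("const")
        scale = max(float(coefs.abs().max()), 1.0)
        pvals[coefs.abs() <= 1e-10 * scale] = 1.0
        worst = str(pvals.idxmax())
        if float(pvals[worst]) <= alpha:
            break
        terms.remove(worst)
        design_r = sm.add_constant(X[terms]) if terms else pd.DataFrame(
            {"const": np.ones(y.size)})
        current = sm.OLS(y, design_r).fit()
        trace.append((worst, float(pvals[worst]), float(current.rsquared)))
    return AdditivityFit(
        coef_full=coef_full,
        coef_reduced=dict(current.params),
        r2_full=r2_full,
        r2_reduced=float(current.rsquared),
        retained=terms,
        trace=trace,
        alpha=alpha,
    )
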