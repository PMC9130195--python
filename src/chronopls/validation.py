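"""Model validation: LOO cross-validation, permutation tests, ROC/AUC.

Cross-validation is strictly leave-one-out: for every sample the model
(including column centring and optional scaling) is re-estimated on the
remaining n-1 rows and the held-out row predicted, so no information leaks
from the fold into the fit. RMSECV is aggregated over folds per component
count and the working component count is the smallest one whose RMSECV is
within a parsimony tolerance of the minimum.

The permutation test refits the model after shuffling the response rows.
Model significance is summarized three ways, mirroring chemometric
practice:

* an empirical p for Q^2: ``(1 + #{Q2_perm >= Q2_true}) / (1 + n_perm)``;
* paired tests (Wilcoxon signed-rank, sign test, paired t) comparing the
  true model's per-sample absolute residuals against each permuted model's,
  one-sided (true smaller), aggregated across permutations by the median
  p-value; computed for both self-prediction (SP, training residuals) and
  cross-validation (CV) residuals, reporting per test the larger of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pls import PLSModel, nipals_fit, predict


@dataclass
class CVResult:
    rmsec: np.ndarray          # per component count 1..A_max
    rmsecv: np.ndarray
    chosen_a: int
    cv_residuals: np.ndarray   # per-sample held-out residuals at chosen_a
    r2: float
    q2: float


@dataclass
class PermutationResult:
    n_permutations: int
    seed: int
    q2_true: float
    q2_permuted: np.ndarray
    empirical_p: float
    p_wilcoxon: float
    p_sign: float
    p_ttest: float
    detail: dict = field(default_factory=dict)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    youden_threshold: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]] at the Youden threshold


def r2_q2(
    y: np.ndarray, fitted: np.ndarray, cv_pred: np.ndarray
) -> tuple[float, float]:
    """R^2 (training) and Q^2 (cross-validated R^2, may be negative)."""
    y = np.asarray(y, dtype=float)
    sstot = float(((y - y.mean(axis=0)) ** 2).sum())
    if sstot == 0:
        raise ValueError("zero total sum of squares in response")
    ssres = float(((y - fitted) ** 2).sum())
    press = float(((y - cv_pred) ** 2).sum())
    return 1.0 - ssres / sstot, 1.0 - press / sstot


def loo_cv(
    X: np.ndarray,
    Y: np.ndarray,
    a_max: int,
    center: bool = True,
    scale: bool = True,
    parsimony_tol: float = 0.01,
) -> CVResult:
    """Leave-one-out CV over component counts 1..a_max.

    Centring/scaling is re-estimated inside every fold. Deterministic.
    """
    X = np.asarray(X, dtype=float)
    Y1 = np.asarray(Y, dtype=float)
    Y2 = Y1[:, None] if Y1.ndim == 1 else Y1
    n, p = X.shape
    if n < 3:
        raise ValueError("LOO-CV needs at least 3 samples")
    if not (1 <= a_max <= min(n - 2, p)):
        raise ValueError(f"a_max={a_max} infeasible for n={n}, p={p}")

    cv_pred = np.zeros((a_max, *Y2.shape))
    for i in range(n):
        keep = np.arange(n) != i
        for a in range(1, a_max + 1):
            m = nipals_fit(X[keep], Y2[keep], a, center=center, scale=scale)
            cv_pred[a - 1, i] = predict(m, X[i])

    rmsec = np.zeros(a_max)
    fitted_full = {}
    for a in range(1, a_max + 1):
        m = nipals_fit(X, Y2, a, center=center, scale=scale)
        fit = predict(m, X)
        fitted_full[a] = fit
        rmsec[a - 1] = float(np.sqrt(((Y2 - fit) ** 2).mean()))
    rmsecv = np.sqrt(((Y2[None] - cv_pred) ** 2).mean(axis=(1, 2)))

    chosen = select_components(rmsecv, parsimony_tol)
    r2, q2 = r2_q2(Y2, fitted_full[chosen], cv_pred[chosen - 1])
    residuals = np.linalg.norm(Y2 - cv_pred[chosen - 1], axis=1)
    return CVResult(rmsec=rmsec, rmsecv=rmsecv, chosen_a=chosen,
                    cv_residuals=residuals, r2=r2, q2=q2)


def select_components(rmsecv: np.ndarray, parsimony_tol: float = 0.01) -> int:
    """Smallest component count within (1+tol) of the RMSECV minimum."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    bound = (1.0 + parsimony_tol) * rmsecv.min()
    return int(np.argmax(rmsecv <= bound)) + 1


def _q2_and_residuals(
    X: np.ndarray, Y: np.ndarray, a: int, center: bool, scale: bool
) -> tuple[float, np.ndarray, np.ndarray]:
    """Q2 plus per-sample absolute SP and CV residuals at fixed A."""
    n = X.shape[0]
    Y2 = Y[:, None] if Y.ndim == 1 else Y
    cv_pred = np.zeros_like(Y2)
    for i in range(n):
        keep = np.arange(n) != i
        m = nipals_fit(X[keep], Y2[keep], a, center=center, scale=scale)
        cv_pred[i] = predict(m, X[i])
    m_full = nipals_fit(X, Y2, a, center=center, scale=scale)
    fitted = predict(m_full, X)
    _, q2 = r2_q2(Y2, fitted, cv_pred)
    sp_res = np.linalg.norm(Y2 - fitted, axis=1)
    cv_res = np.linalg.norm(Y2 - cv_pred, axis=1)
    return q2, sp_res, cv_res


def _paired_p(true_res: np.ndarray, perm_res: np.ndarray) -> tuple[float, float, float]:
    """One-sided paired tests that the true residuals are smaller."""
    d = true_res - perm_res
    if np.allclose(d, 0):
        return 1.0, 1.0, 1.0
    try:
        p_w = float(stats.wilcoxon(d, alternative="less", method="approx").pvalue)
    except ValueError:
        p_w = 1.0
    neg = int((d < 0).sum())
    nz = int((d != 0).sum())
    p_s = float(stats.binomtest(neg, nz, alternative="greater").pvalue) if nz else 1.0
    p_t = float(stats.ttest_rel(true_res, perm_res, alternative="less").pvalue)
    return p_w, p_s, p_t


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    a: int,
    n_perm: int = 1000,
    seed: int = 0,
    center: bool = True,
    scale: bool = True,
    paired_tests: bool = True,
) -> PermutationResult:
    """Response-permutation test of model significance at fixed A."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)

    q2_true, sp_true, cv_true = _q2_and_residuals(X, Y, a, center, scale)
    q2s = np.zeros(n_perm)
    sp_ps, cv_ps = [], []
    n = X.shape[0]
    for k in range(n_perm):
        perm = rng.permutation(n)
        q2s[k], sp_res, cv_res = _q2_and_residuals(X, Y[perm], a, center, scale)
        if paired_tests:
            sp_ps.append(_paired_p(sp_true, sp_res))
            cv_ps.append(_paired_p(cv_true, cv_res))

    empirical_p = (1 + int((q2s >= q2_true).sum())) / (1 + n_perm)
    if paired_tests:
        sp_med = np.median(np.array(sp_ps), axis=0)
        cv_med = np.median(np.array(cv_ps), axis=0)
        p_w, p_s, p_t = np.maximum(sp_med, cv_med)
    else:
        p_w = p_s = p_t = float("nan")
    return PermutationResult(
        n_permutations=n_perm, seed=seed, q2_true=q2_true, q2_permuted=q2s,
        empirical_p=float(empirical_p), p_wilcoxon=float(p_w),
        p_sign=float(p_s), p_ttest=float(p_t),
        detail={"sp_vs_cv": "per-test p is max(SP, CV) of median permutation p"},
    )


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> ROCResult:
    """ROC curve, trapezoidal AUC and Youden-optimal threshold.

    ``truth`` holds binary labels (1 = positive class); ``scores`` are the
    predicted class scores. The confusion matrix is evaluated at the
    Youden threshold (score >= threshold predicts positive).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented")

    thr = np.unique(scores)[::-1]
    thresholds = np.concatenate(([np.inf], thr))
    tpr = np.array([(scores[pos] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[~pos] >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = int(np.argmax(j))
    youden = float(thresholds[best]) if np.isfinite(thresholds[best]) else float(thr[0])
    pred = scores >= youden
    confusion = np.array(
        [
            [int((~pred & ~pos).sum()), int((pred & ~pos).sum())],
            [int((~pred & pos).sum()), int((pred & pos).sum())],
        ]
    )
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     youden_threshold=youden, confusion=confusion)
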