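"""NIPALS partial least squares, VIP scoring, and exploratory PCA/HCA.

The engine is written from scratch around the classical NIPALS recursion:
for each latent component, alternate weight/score updates between the X and
Y blocks until the weight vector stabilizes, then deflate X (and Y for
multi-response models) by the rank-one score/loading product. Regression
coefficients come from ``B = W (P'W)^{-1} Q'`` on the centred/scaled
blocks. A fixed sign convention (the largest-magnitude element of each
weight vector is positive) makes outputs reproducible across platforms.

Single-response fits take the fast path: the weight vector ``X'y / |X'y|``
is already the NIPALS fixed point, so no inner iteration is needed.

Variable importance in projection (VIP) for variable j over A components is

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / |w_a|)^2 / sum_a SSY_a )

where SSY_a is the Y sum of squares captured by component a; the scores
always satisfy ``sum_j VIP_j^2 = p``. For discriminant models a per-class
variant restricts SSY_a to one response column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core import SampleMeta


@dataclass
class PLSModel:
    """Fitted latent-variable model (all blocks on the centred/scaled scale)."""

    n_components: int
    W: np.ndarray          # X-weights, p x A
    P: np.ndarray          # X-loadings, p x A
    T: np.ndarray          # X-scores, n x A
    Q: np.ndarray          # Y-loadings, m x A
    B: np.ndarray          # regression coefficients, p x m
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    ssx: np.ndarray        # explained X sum of squares per component
    ssy: np.ndarray        # explained Y sum of squares per component (total)
    ssy_per_column: np.ndarray  # A x m
    ssx_total: float
    ssy_total: float

    @property
    def explained_x_variance(self) -> np.ndarray:
        """Fraction of (centred/scaled) X variance captured per component."""
        return self.ssx / self.ssx_total

    @property
    def explained_y_variance(self) -> np.ndarray:
        return self.ssy / self.ssy_total


def _as_2d(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y[:, None] if y.ndim == 1 else y


def _fix_sign(w: np.ndarray) -> float:
    return -1.0 if w[np.argmax(np.abs(w))] < 0 else 1.0


def nipals_fit(
    X: np.ndarray,
    Y: np.ndarray,
    A: int,
    center: bool = True,
    scale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a PLS model with ``A`` latent components by NIPALS.

    ``X`` is expected column-scaled upstream (autoscaling); set
    ``scale=True`` to (re)scale inside the fit, e.g. within CV folds.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if not (1 <= A <= min(n - 1, p)):
        raise ValueError(f"A={A} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0) if center else np.zeros(p)
    y_mean = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    Xc = (X - x_mean) / x_scale
    Yc = Y - y_mean
    if not np.any(Yc):
        raise ValueError("zero-variance response")

    ssx_total = float((Xc * Xc).sum())
    ssy_total = float((Yc * Yc).sum())
    m = Yc.shape[1]
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    Q = np.zeros((m, A))
    ssx = np.zeros(A)
    ssy = np.zeros(A)
    ssy_col = np.zeros((A, m))

    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(A):
        u = Yd[:, int(np.argmax((Yd * Yd).sum(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xd.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                raise ValueError(f"degenerate component {a + 1}: zero weight vector")
            w_new /= nrm
            t = Xd @ w_new
            tt = float(t @ t)
            q = Yd.T @ t / tt
            if m == 1:
                w = w_new
                break
            u_new = Yd @ q / float(q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                u = u_new
                break
            w, u = w_new, u_new
        t = Xd @ w
        tt = float(t @ t)
        pv = Xd.T @ t / tt
        q = Yd.T @ t / tt
        sgn = _fix_sign(w)
        w, t, pv, q = sgn * w, sgn * t, sgn * pv, sgn * q

        Xd = Xd - np.outer(t, pv)
        Yd = Yd - np.outer(t, q)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, pv, t, q
        ssx[a] = tt * float(pv @ pv)
        ssy_col[a] = tt * q * q
        ssy[a] = ssy_col[a].sum()

    # coefficients on the centred/scaled block
    R = W @ np.linalg.solve(P.T @ W, np.eye(A))
    B = R @ Q.T
    return PLSModel(
        n_components=A, W=W, P=P, T=T, Q=Q, B=B,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        ssx=ssx, ssy=ssy, ssy_per_column=ssy_col,
        ssx_total=ssx_total, ssy_total=ssy_total,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for new rows (same centring/scaling applied)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.W.shape[0]}"
        )
    return ((X_new - model.x_mean) / model.x_scale) @ model.B + model.y_mean


def vip_scores(model: PLSModel, response_column: int | None = None) -> np.ndarray:
    """VIP per variable; restrict to one response column for per-class VIP."""
    ssy = model.ssy if response_column is None else model.ssy_per_column[:, response_column]
    total = ssy.sum()
    if total == 0:
        raise ValueError("explained Y sum of squares is zero")
    p = model.W.shape[0]
    wnorm2 = (model.W ** 2) / (model.W ** 2).sum(axis=0)
    return np.sqrt(p * (wnorm2 @ ssy) / total)


# ---------------------------------------------------------------------------
# discriminant-analysis encoding
# ---------------------------------------------------------------------------

@dataclass
class ClassEncoding:
    """One-hot response for PLS-DA with optional merged day-classes."""

    classes: list[str]
    day_to_class: dict[int, str]
    Y: np.ndarray  # n x m one-hot
    labels: list[str]  # per-sample class label

    @classmethod
    def from_days(
        cls, days: Sequence[int], merges: Sequence[Sequence[int]] = ()
    ) -> "ClassEncoding":
        day_to_class: dict[int, str] = {}
        for grouped in merges:
            name = "/".join(str(d) for d in sorted(grouped))
            for d in grouped:
                day_to_class[int(d)] = name
        classes: list[str] = []
        for d in days:
            name = day_to_class.get(int(d), str(int(d)))
            day_to_class.setdefault(int(d), name)
            if name not in classes:
                classes.append(name)
        labels = [day_to_class[int(d)] for d in days]
        Y = np.zeros((len(days), len(classes)))
        for i, lab in enumerate(labels):
            Y[i, classes.index(lab)] = 1.0
        return cls(classes=classes, day_to_class=day_to_class, Y=Y, labels=labels)


def plsda_encode(
    samples: Sequence[SampleMeta],
    merges: Sequence[Sequence[int]] = (),
    allowed_days: Sequence[int] | None = None,
) -> ClassEncoding:
    """Encode sample incubation days as a one-hot class matrix.

    When ``allowed_days`` is given, a sample whose day is outside the
    design raises instead of silently creating a new class.
    """
    days = []
    for s in samples:
        if s.day is None:
            raise ValueError(f"sample {s.sample_id!r} has no day; cannot classify")
        if allowed_days is not None and s.day not in allowed_days:
            raise ValueError(
                f"sample {s.sample_id!r} day {s.day} outside design days {sorted(allowed_days)}"
            )
        days.append(s.day)
    return ClassEncoding.from_days(days, merges)


def plsda_assign(
    model: PLSModel, X_new: np.ndarray, encoding: ClassEncoding
) -> tuple[list[str], list[int]]:
    """Assign each row to the class with maximum predicted response.

    Ties break toward the first class in encoding order; tied row indices
    are returned so callers can log them.
    """
    scores = predict(model, X_new)
    idx = np.argmax(scores, axis=1)
    ties = [
        i for i in range(scores.shape[0])
        if np.sum(scores[i] == scores[i, idx[i]]) > 1
    ]
    return [encoding.classes[k] for k in idx], ties


# ---------------------------------------------------------------------------
# exploratory methods
# ---------------------------------------------------------------------------

def pca_svd(X: np.ndarray, center: bool = True):
    """PCA via singular value decomposition.

    Returns (scores, loadings, explained_variance) where explained
    variances are ``s^2 / (n - 1)`` and sum to the total variance of the
    centred data. Loadings follow the same sign convention as the PLS
    weights.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0) if center else X.copy()
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(vt.shape[0]):
        if _fix_sign(vt[k]) < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    return scores, vt.T, s ** 2 / max(X.shape[0] - 1, 1)


def hca_ward(X: np.ndarray) -> np.ndarray:
    """Agglomerative clustering, Ward linkage on Euclidean distances.

    Returns the scipy linkage matrix (merge list with non-decreasing
    heights); deterministic given input order.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return linkage(X, method="ward", metric="euclidean")
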