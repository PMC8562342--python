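"""Multivariate stage: PCA, SIMPLS partial least squares, Venetian-blinds
cross-validation, reverse interval-PLS variable selection, and ANOVA/Tukey.

The regression problem is: predict a response block Y (biomass or volatile
concentrations) from the nitrogen-utilization block X (18 variables:
ammonia + amino acids, Arg/Gln merged).  PLS factors are extracted with the
SIMPLS algorithm of de Jong (1993): latent variables maximize covariance
with Y under orthogonality of the score vectors, with deflation applied to
the cross-product matrix S = X'Y rather than to X itself.

Model selection uses Venetian-blinds cross-validation (every k-th row into
the same fold, so interleaved strain x time rows are spread over folds) and
reverse-mode interval PLS: greedy backward elimination of single-variable
intervals for as long as the cross-validated error improves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLSModel",
    "SignSummary",
    "autoscale",
    "pca",
    "simpls_fit",
    "venetian_blinds_split",
    "cross_validate",
    "ipls_reverse",
    "regression_summary",
    "anova_tukey",
]


# -- preprocessing ---------------------------------------------------------

def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centering and scaling to unit sample standard deviation.

    Returns (Xs, centers, scales).  Zero-variance columns cannot be scaled:
    they are centered, given scale 1, and reported with a warning — the
    caller's variable mask should exclude them.
    """
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    dead = scales == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance column(s) left unscaled",
            stacklevel=2,
        )
        scales = np.where(dead, 1.0, scales)
    return (X - centers) / scales, centers, scales


def pca(
    X: np.ndarray, n_comp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of a preprocessed matrix via SVD.

    Returns (scores, loadings, pct_variance); loadings are orthonormal
    columns, scores = X @ loadings, and pct_variance sums to 100 over the
    full rank.
    """
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if n_comp > rank:
        warnings.warn(f"n_comp={n_comp} exceeds rank {rank}; truncating",
                      stacklevel=2)
        n_comp = rank
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    pct = 100.0 * s[:n_comp] ** 2 / total
    loadings = vt[:n_comp].T
    return X @ loadings, loadings, pct


# -- SIMPLS ----------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted SIMPLS regression model.

    ``regression_vector`` holds the coefficients in preprocessed
    (autoscaled) space; ``regression_vector_raw`` and ``intercept_raw`` give
    the back-transformed original-unit coefficients so that
    ``Y ≈ X @ B_raw + intercept``.  ``selected_mask`` marks, over the
    *original* predictor list, the variables the model was fitted on.
    """

    n_lv: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    regression_vector: np.ndarray
    regression_vector_raw: np.ndarray
    intercept_raw: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)
    variance_captured: tuple[float, float] = (0.0, 0.0)
    variance_per_lv: tuple[np.ndarray, np.ndarray] | None = None
    selected_mask: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.selected_mask is not None and X.shape[1] == self.selected_mask.size:
            X = X[:, self.selected_mask]
        Xs = (X - self.x_center) / self.x_scale
        return Xs @ self.regression_vector * self.y_scale + self.y_center

    def outlier_leverage(self, X: np.ndarray, conf: float = 0.95) -> np.ndarray:
        """Flag high-leverage rows in score space at the given confidence
        limit (Hotelling T² against an F distribution).  Reported only;
        never auto-removed."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.selected_mask is not None and X.shape[1] == self.selected_mask.size:
            X = X[:, self.selected_mask]
        T = (X - self.x_center) / self.x_scale @ self.x_weights
        n = T.shape[0]
        cov = np.cov(T, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        t2 = np.einsum("ij,jk,ik->i", T, np.linalg.pinv(cov), T)
        a = self.n_lv
        crit = a * (n - 1) / max(n - a, 1) * stats.f.ppf(conf, a, max(n - a, 1))
        return t2 > crit


def _simpls_core(
    Xs: np.ndarray, Ys: np.ndarray, n_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """SIMPLS factor extraction on preprocessed blocks.

    Returns (R, P, Q, T): X-weights (Xs @ R = T), X-loadings, Y-loadings,
    and orthonormal scores.  Deflation acts on the covariance matrix
    S = Xs'Ys through an orthonormal basis of the X-loadings.
    """
    n, p = Xs.shape
    m = Ys.shape[1]
    R = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    T = np.zeros((n, n_lv))
    V = np.zeros((p, n_lv))
    S = Xs.T @ Ys
    for a in range(n_lv):
        u, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] < 1e-14:
            raise np.linalg.LinAlgError(
                f"X is rank-deficient beyond {a} latent variables; "
                f"refit with n_lv <= {a}"
            )
        r = u[:, 0]
        t = Xs @ r
        normt = np.linalg.norm(t)
        t /= normt
        r /= normt
        p_a = Xs.T @ t
        q_a = Ys.T @ t
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], P[:, a], Q[:, a], T[:, a], V[:, a] = r, p_a, q_a, t, v
    return R, P, Q, T


def simpls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    scale: bool = True,
    selected_mask: np.ndarray | None = None,
) -> PLSModel:
    """Fit a SIMPLS model with internal autoscaling of both blocks.

    ``selected_mask`` records, over the caller's full predictor list, which
    columns the supplied X corresponds to (used after iPLS selection).
    Training metrics (R², RMSEC, % variance captured) are computed on the
    original-unit responses.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    max_allowed = min(np.linalg.matrix_rank(X - X.mean(0)), 18)
    if not 1 <= n_lv <= max_allowed:
        raise ValueError(f"n_lv must be in [1, {max_allowed}]")

    if scale:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xs, xc, xs = autoscale(X)
            Ys, yc, ys = autoscale(Y)
    else:
        xc, xs = np.zeros(X.shape[1]), np.ones(X.shape[1])
        yc, ys = np.zeros(Y.shape[1]), np.ones(Y.shape[1])
        Xs, Ys = X, Y

    R, P, Q, T = _simpls_core(Xs, Ys, n_lv)
    B = R @ Q.T
    B_raw = (B / xs[:, None]) * ys[None, :]
    intercept = yc - xc @ B_raw

    Yhat = Xs @ B * ys + yc
    Yorig = Ys * ys + yc
    ss_res = float(np.sum((Yorig - Yhat) ** 2))
    ss_tot = float(np.sum((Yorig - yc) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmsec = float(np.sqrt(np.mean((Yorig - Yhat) ** 2)))
    # per-LV captured variance; scores are orthonormal so the contribution
    # of LV a to the X block is ||p_a||^2
    vx = 100.0 * np.sum(P**2, axis=0) / np.sum(Xs**2)
    vy = 100.0 * np.sum(Q**2, axis=0) / np.sum(Ys**2)
    return PLSModel(
        n_lv=n_lv,
        x_weights=R,
        x_loadings=P,
        y_loadings=Q,
        regression_vector=B,
        regression_vector_raw=B_raw,
        intercept_raw=intercept,
        x_center=xc,
        x_scale=xs,
        y_center=yc,
        y_scale=ys,
        metrics={"R2": r2, "RMSEC": rmsec},
        variance_captured=(float(vx.sum()), float(vy.sum())),
        variance_per_lv=(vx, vy),
        selected_mask=selected_mask,
    )


# -- cross-validation ------------------------------------------------------

def venetian_blinds_split(n_rows: int, n_splits: int = 24) -> list[np.ndarray]:
    """Interleaved CV folds: fold j holds rows {j, j+k, j+2k, ...}.

    If there are fewer rows than requested splits, falls back to
    leave-one-out with a warning.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows to cross-validate")
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if n_rows < n_splits:
        warnings.warn(
            f"{n_rows} rows < {n_splits} splits; using leave-one-out",
            stacklevel=2,
        )
        n_splits = n_rows
    return [np.arange(j, n_rows, n_splits) for j in range(n_splits)]


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    max_lv: int = 18,
    n_splits: int = 24,
    splits: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Venetian-blinds CV of SIMPLS over 1..max_lv latent variables.

    Preprocessing (autoscaling) is re-estimated inside every training fold;
    held-out predictions accumulate PRESS per LV count.  Returns
    (rmsecv_per_lv, q2_per_lv, chosen_n_lv) with the LV count chosen as the
    argmin of RMSECV, ties resolved toward fewer LVs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if splits is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            splits = venetian_blinds_split(n, n_splits)
    for s in splits:
        if n - len(s) < 2:
            raise ValueError("a training fold has fewer than 2 rows")
    lv_cap = max_lv
    for s in splits:
        tr = n - len(s)
        Xtr = np.delete(X, s, axis=0)
        lv_cap = min(lv_cap, np.linalg.matrix_rank(Xtr - Xtr.mean(0)), tr - 1)
    if lv_cap < 1:
        raise ValueError("cannot fit even one latent variable in every fold")

    press = np.zeros(lv_cap)
    for s in splits:
        Xtr, Ytr = np.delete(X, s, axis=0), np.delete(Y, s, axis=0)
        Xte, Yte = X[s], Y[s]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xs, xc, xsc = autoscale(Xtr)
            Ys, yc, ysc = autoscale(Ytr)
        R, _, Q, _ = _simpls_core(Xs, Ys, lv_cap)
        Xtes = (Xte - xc) / xsc
        for a in range(1, lv_cap + 1):
            B = R[:, :a] @ Q[:, :a].T
            Yhat = Xtes @ B * ysc + yc
            press[a - 1] += float(np.sum((Yte - Yhat) ** 2))

    tss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    rmsecv = np.sqrt(press / Y.size)
    q2 = 1.0 - press / tss
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest) tie
    return rmsecv, q2, chosen


# -- interval PLS (reverse mode) ------------------------------------------

def ipls_reverse(
    X: np.ndarray,
    Y: np.ndarray,
    interval_size: int = 1,
    max_lv: int = 18,
    n_splits: int = 24,
) -> np.ndarray:
    """Reverse-mode interval-PLS variable selection.

    Greedy backward elimination over intervals of ``interval_size``
    consecutive predictors: at each pass, drop the interval whose removal
    most lowers RMSECV (at the per-candidate best LV count); stop when no
    removal improves it.  Guarantees a non-empty mask and
    RMSECV(selected) <= RMSECV(full).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if p == 1:  # nothing to eliminate
        return np.ones(1, dtype=bool)
    intervals = [
        np.arange(start, min(start + interval_size, p))
        for start in range(0, p, interval_size)
    ]

    def score(mask: np.ndarray) -> float:
        rmsecv, _, chosen = cross_validate(
            X[:, mask], Y, max_lv=max_lv, n_splits=n_splits
        )
        return float(rmsecv[chosen - 1])

    mask = np.ones(p, dtype=bool)
    active = list(range(len(intervals)))
    best = score(mask)
    while len(active) > 1:
        trial_scores = []
        for idx in active:
            m = mask.copy()
            m[intervals[idx]] = False
            if not m.any():
                trial_scores.append(np.inf)
                continue
            trial_scores.append(score(m))
        j = int(np.argmin(trial_scores))
        if trial_scores[j] < best:
            best = trial_scores[j]
            mask[intervals[active[j]]] = False
            active.pop(j)
        else:
            break
    return mask


# -- reporting -------------------------------------------------------------

@dataclass
class SignSummary:
    """Qualitative regression-vector summary: one row per response, one
    column per nitrogen variable, entries in {+, -, 0}; 0 means the
    variable was not selected for that model."""

    rows: list[str]
    columns: list[str]
    entries: np.ndarray  # dtype '<U1'

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, index=self.rows, columns=self.columns)


def regression_summary(
    models: list[PLSModel], responses: list[str], columns: list[str]
) -> SignSummary:
    """Collapse fitted models into a sign table.

    Signs are taken from the preprocessed-space regression vector (scale-
    free); unselected variables get "0".  An exactly zero coefficient on a
    selected variable also reports "0", with a warning, since "0" denotes
    non-use.
    """
    entries = np.full((len(models), len(columns)), "0", dtype="<U1")
    for i, model in enumerate(models):
        mask = model.selected_mask
        if mask is None:
            mask = np.ones(len(columns), dtype=bool)
        coef = np.zeros(len(columns))
        coef[mask] = model.regression_vector[:, 0]
        for j in range(len(columns)):
            if not mask[j]:
                continue
            if coef[j] > 0:
                entries[i, j] = "+"
            elif coef[j] < 0:
                entries[i, j] = "-"
            else:
                warnings.warn(
                    f"selected variable {columns[j]!r} has exactly zero "
                    f"coefficient for {responses[i]!r}; reporting 0",
                    stacklevel=2,
                )
    return SignSummary(rows=list(responses), columns=list(columns), entries=entries)


def anova_tukey(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[float, float, dict[tuple[str, str], float]]:
    """One-way ANOVA with post-hoc Tukey HSD pairwise comparisons.

    Returns (F, p, pairwise p-values keyed by group-name pair).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("all within-group variances are zero")
    f, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    pairwise = {
        (names[i], names[j]): float(res.pvalue[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return float(f), float(p), pairwise
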