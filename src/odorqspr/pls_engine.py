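"""NIPALS partial least squares with diagnostics.

Single-response PLS fitted by NIPALS on autoscaled descriptors and a
standardized response.  Latent-variable count is chosen by honest
leave-one-out cross-validation (scaling refitted in every fold).  The
engine also provides VIP scores, Hotelling T2 and DModX applicability
domain diagnostics, response-permutation (Y-randomization) testing, and
PCA factor scores with varimax rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PLSModel",
    "ADReport",
    "RandomizationReport",
    "fit_pls",
    "fit_nipals",
    "loo_q2",
    "select_lv",
    "vip",
    "dmodx",
    "hotelling_t2",
    "y_randomization",
    "pca_factor_scores",
]


class PLSError(ValueError):
    pass


@dataclass
class PLSModel:
    """A fitted PLS model with scaling parameters.

    Weights W, loadings P, scores T and y-loadings q live on the
    autoscaled X / standardized y scale; ``coef_`` and ``intercept_``
    are back-transformed to original descriptor and response units so
    that predict(X) = intercept_ + X @ coef_.
    """

    A: int
    columns: list[str]
    W: np.ndarray  # p x A
    P: np.ndarray  # p x A
    T: np.ndarray  # n x A (training scores)
    q: np.ndarray  # A
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    coef_: np.ndarray
    intercept_: float
    b_scaled: np.ndarray  # coefficients on the scaled space
    residuals: np.ndarray  # n x p scaled X-residuals after A components
    s0: float  # pooled residual SD
    train_index: list = field(default_factory=list)

    @property
    def n_train(self) -> int:
        return self.T.shape[0]

    @property
    def n_vars(self) -> int:
        return len(self.columns)

    def scale_x(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = X[self.columns].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return (Xv - self.x_mean) / self.x_sd

    def scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project rows onto the latent space: T = Xs W(P'W)^-1."""
        Xs = self.scale_x(X)
        Wstar = self.W @ np.linalg.inv(self.P.T @ self.W)
        return Xs @ Wstar

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = X[self.columns].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.intercept_ + Xv @ self.coef_

    def predict_latent(self, X) -> np.ndarray:
        """Prediction via the (W, P, q) route; equals :meth:`predict`."""
        t = self.scores(X)
        return (t @ self.q) * self.y_sd + self.y_mean


def fit_nipals(Xs: np.ndarray, ys: np.ndarray, A: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core single-y NIPALS on pre-scaled data; returns (W, P, T, q).

    Per component: w = X'y normalized, t = Xw, p = X't/(t't),
    q = y't/(t't), then X and y are deflated.  For a single response
    each component is closed-form, so the only failure mode is
    degenerate input (A above the rank of X).
    """
    X = np.array(Xs, dtype=float)
    y = np.array(ys, dtype=float)
    n, p = X.shape
    if A < 1:
        raise PLSError("A must be >= 1")
    if A > min(n - 1, p) or A > np.linalg.matrix_rank(X):
        raise PLSError(f"A={A} exceeds the rank of X")
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    for a in range(A):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise PLSError(f"degenerate component {a + 1}: X'y vanished")
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            raise PLSError(f"degenerate component {a + 1}: zero score variance")
        pl = X.T @ t / tt
        qa = float(y @ t) / tt
        X = X - np.outer(t, pl)
        y = y - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, qa
    return W, P, T, q


def fit_pls(X: pd.DataFrame, y, A: int) -> PLSModel:
    """Autoscale X, standardize y, run NIPALS, and back-transform.

    The returned model predicts on original units through either the
    latent (W, P, q) route or the collapsed coefficient vector; the two
    agree to machine precision.
    """
    yv = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(yv) != n:
        raise PLSError("X and y disagree on sample count")
    x_mean = X.mean(axis=0).to_numpy()
    x_sd = X.std(axis=0, ddof=1).to_numpy()
    if np.any(x_sd == 0):
        bad = [c for c, s in zip(X.columns, x_sd) if s == 0]
        raise PLSError(f"zero-variance descriptor columns: {bad}")
    y_mean = float(yv.mean())
    y_sd = float(yv.std(ddof=1))
    if y_sd == 0:
        raise PLSError("zero-variance response")
    Xs = (X.to_numpy(dtype=float) - x_mean) / x_sd
    ys = (yv - y_mean) / y_sd
    W, P, T, q = fit_nipals(Xs, ys, A)
    Wstar = W @ np.linalg.inv(P.T @ W)
    b_scaled = Wstar @ q
    coef = b_scaled * y_sd / x_sd
    intercept = y_mean - float(x_mean @ coef)
    E = Xs - T @ P.T
    dof = (n - A - 1) * (p - A)
    # with A = p there is no residual X-space; DModX is then undefined
    s0 = float(np.sqrt(np.sum(E * E) / dof)) if dof > 0 else float("nan")
    return PLSModel(
        A=A, columns=list(X.columns), W=W, P=P, T=T, q=q,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        coef_=coef, intercept_=intercept, b_scaled=b_scaled,
        residuals=E, s0=s0, train_index=list(X.index),
    )


def loo_predictions(X: pd.DataFrame, y, A: int) -> np.ndarray:
    """Leave-one-out predictions with full honest refits.

    Every fold refits the model from scratch on the n-1 remaining rows,
    including recomputation of all scaling parameters, then predicts the
    held-out compound.  No shortcut is taken.
    """
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if n < 3:
        raise PLSError("need at least 3 samples for LOO")
    if yv.std() == 0:
        raise PLSError("zero-variance response")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls(X.iloc[mask], yv[mask], A)
        preds[i] = model.predict(X.iloc[[i]])[0]
    return preds


def loo_q2(X: pd.DataFrame, y, A: int) -> float:
    """Leave-one-out cross-validated Q2 (see :func:`loo_predictions`)."""
    yv = np.asarray(y, dtype=float).ravel()
    press = float(np.sum((yv - loo_predictions(X, yv, A)) ** 2))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    return 1.0 - press / sst


def select_lv(X: pd.DataFrame, y, A_max: int) -> tuple[int, list[float]]:
    """Latent-variable count maximizing LOO Q2 (ties favor fewer LVs)."""
    q2s = [loo_q2(X, y, A) for A in range(1, A_max + 1)]
    best = int(np.argmax(q2s)) + 1  # argmax returns first maximum
    return best, q2s


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( J * sum_f SSY_f (w_jf/||w_f||)^2 / SSY_total ) where
    SSY_f = q_f^2 t_f't_f is the y-variance explained by component f.
    The mean of VIP^2 over descriptors is 1 by construction.
    """
    ssy = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)
    total = float(ssy.sum())
    if total == 0:
        raise PLSError("model explains no y-variance")
    wnorm = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    J = model.n_vars
    return np.sqrt(J * (wnorm**2 @ ssy) / total)


@dataclass
class ADReport:
    """DModX applicability-domain report for a set of compounds."""

    ids: list
    dmodx: np.ndarray
    d_crit: float
    in_domain: np.ndarray
    t2: np.ndarray
    t2_limit: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "dmodx": self.dmodx,
                "in_domain": self.in_domain,
                "t2": self.t2,
            }
        )


def dmodx_values(model: PLSModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Normalized distance to the X-model for each row of X."""
    K, A = model.n_vars, model.A
    if K == A or not np.isfinite(model.s0):
        raise PLSError("no residual X-space: K equals A")
    Xs = model.scale_x(X)
    Wstar = model.W @ np.linalg.inv(model.P.T @ model.W)
    E = Xs - (Xs @ Wstar) @ model.P.T
    s_i = np.sqrt(np.sum(E * E, axis=1) / (K - A))
    return s_i / model.s0


def dmodx_crit(model: PLSModel, alpha: float = 0.01) -> float:
    """Critical DModX from the F distribution.

    Uses (K - A) observation degrees of freedom against the pooled
    model degrees of freedom (N - A - 1)(K - A), with the finite-sample
    correction factor sqrt(N/(N - A - 1)) that compensates s0 being
    estimated from the same training residuals.
    """
    N, K, A = model.n_train, model.n_vars, model.A
    f = sps.f.ppf(1.0 - alpha, K - A, (N - A - 1) * (K - A))
    return float(np.sqrt(f * N / (N - A - 1)))


def dmodx(model: PLSModel, X: pd.DataFrame, alpha: float = 0.01) -> ADReport:
    """Applicability-domain report: DModX vs the critical limit, plus T2."""
    d = dmodx_values(model, X)
    crit = dmodx_crit(model, alpha)
    t2, t2_lim = hotelling_t2(model, X)
    ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(d)))
    return ADReport(
        ids=ids, dmodx=d, d_crit=crit, in_domain=d <= crit, t2=t2, t2_limit=t2_lim
    )


def hotelling_t2(model: PLSModel, X: pd.DataFrame | np.ndarray | None = None,
                 alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Hotelling T2 in score space with its F-based limit.

    T2_i = sum_a t_ia^2 / var(t_a) with variances from the training
    scores; the limit is A(N^2-1)/(N(N-A)) * F_crit(alpha; A, N-A).
    """
    T = model.T if X is None else model.scores(X)
    var = model.T.var(axis=0, ddof=1)
    if np.any(var == 0):
        raise PLSError("zero-variance score column")
    t2 = np.sum(T**2 / var, axis=1)
    N, A = model.n_train, model.A
    limit = A * (N**2 - 1) / (N * (N - A)) * sps.f.ppf(1 - alpha, A, N - A)
    return t2, float(limit)


@dataclass
class RandomizationReport:
    """Y-randomization summary: per-permutation stats and intercepts."""

    correlations: np.ndarray
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    r2_unpermuted: float
    q2_unpermuted: float
    r2_intercept: float
    q2_intercept: float
    n_permutations: int

    @property
    def passed(self) -> bool:
        return self.r2_intercept < 0.4 and self.q2_intercept < 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "abs_corr": self.correlations,
                "r2": self.r2_perm,
                "q2": self.q2_perm,
            }
        )


def _train_r2(model: PLSModel, X: pd.DataFrame, y: np.ndarray) -> float:
    fitted = model.predict(X)
    return 1.0 - float(np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2))


def y_randomization(X: pd.DataFrame, y, A: int, n_perm: int = 100,
                    seed: int = 0) -> RandomizationReport:
    """Response-permutation test of chance correlation.

    The response is shuffled ``n_perm`` times; each shuffle refits the
    PLS model at A components and records |corr(y, y_perm)|, R2 and LOO
    Q2.  Straight lines of R2 and Q2 against |corr| — including the
    unpermuted model at corr = 1 — give the intercepts R2int and Q2int;
    the model passes when R2int < 0.4 and Q2int < 0.05.
    """
    yv = np.asarray(y, dtype=float).ravel()
    if n_perm < 2:
        raise PLSError("need at least 2 permutations")
    if len(yv) < 5:
        raise PLSError("too few samples for meaningful permutation")
    rng = np.random.default_rng(seed)
    corrs, r2s, q2s = [], [], []
    for _ in range(n_perm):
        yp = rng.permutation(yv)
        corrs.append(abs(float(np.corrcoef(yv, yp)[0, 1])))
        model = fit_pls(X, yp, A)
        r2s.append(_train_r2(model, X, yp))
        q2s.append(loo_q2(X, yp, A))
    model0 = fit_pls(X, yv, A)
    r2_0 = _train_r2(model0, X, yv)
    q2_0 = loo_q2(X, yv, A)
    xs = np.array(corrs + [1.0])
    r2_line = np.polyfit(xs, np.array(r2s + [r2_0]), 1)
    q2_line = np.polyfit(xs, np.array(q2s + [q2_0]), 1)
    return RandomizationReport(
        correlations=np.array(corrs),
        r2_perm=np.array(r2s),
        q2_perm=np.array(q2s),
        r2_unpermuted=r2_0,
        q2_unpermuted=q2_0,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
        n_permutations=n_perm,
    )


def pca_factor_scores(X: pd.DataFrame, n_factors: int = 2, rotate: bool = True
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factor scores from a correlation-matrix PCA, optionally varimax-rotated.

    Rows are standardized, the correlation matrix eigendecomposed, and
    the retained loadings (eigenvectors scaled by sqrt(eigenvalue))
    optionally rotated by varimax.  Returns (scores, loadings,
    explained_variance) where explained variance is per retained factor
    in correlation units (summing over all p factors would give p).
    """
    if X.shape[0] < 3:
        raise PLSError("need at least 3 rows for factor analysis")
    p = X.shape[1]
    if n_factors > p:
        raise PLSError(f"cannot extract {n_factors} factors from {p} variables")
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise PLSError("zero-variance column in factor analysis input")
    Z = (Xv - Xv.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    R = np.atleast_2d(R)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    L = evecs[:, :n_factors] * np.sqrt(evals[:n_factors])
    # standardized principal-component scores
    F = Z @ evecs[:, :n_factors] / np.sqrt(np.where(evals[:n_factors] > 0, evals[:n_factors], 1.0))
    if rotate and n_factors > 1:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        L_rot, Tm = rotate_factors(L, "varimax")
        F = F @ Tm
        L = L_rot
    explained = np.sum(L**2, axis=0)
    return F, L, explained
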