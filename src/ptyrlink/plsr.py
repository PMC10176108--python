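"""Single-response partial least squares regression with LOOCV and VIP.

The model projects the (centered, optionally autoscaled) feature matrix X
onto a small number of latent components chosen to maximize covariance with
the response y, via the classical NIPALS algorithm with X-deflation:

    w_a = X_a' y / ||X_a' y||        (weights)
    t_a = X_a w_a                    (scores; mutually orthogonal)
    p_a = X_a' t_a / (t_a' t_a)      (X loadings)
    q_a = y' t_a / (t_a' t_a)        (y loading)
    X_{a+1} = X_a - t_a p_a'

Regression coefficients on the processed scale are
b = W (P'W)^{-1} q, so that yhat = y_mean + X_proc b.  Goodness of fit is
R^2 = 1 - RSS/TSS; predictive power is assessed by leave-one-out
cross-validation, Q^2(A) = 1 - PRESS(A)/TSS, with centering/scaling redone
inside every fold and TSS taken about the full-data mean.

Variable importance in projection (VIP) scores summarize each feature's
contribution across components,

    VIP_j = sqrt( p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a ),
    SS_a = q_a^2 t_a't_a,

with the algebraic identity mean(VIP^2) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import PtyrlinkError


def _as_xy(X, y) -> tuple[pd.DataFrame, pd.Series]:
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if X.isna().any().any() or y.isna().any():
        raise PtyrlinkError("PLSR input contains missing cells")
    return X, y


@dataclass
class PlsrModel:
    n_components: int
    x_weights: np.ndarray  # p x A (unit-norm columns)
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray  # n x A
    coef: np.ndarray  # p (processed scale)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2: float
    feature_names: list[str]
    fitted: np.ndarray = field(repr=False, default=None)

    def coef_for(self, a: int) -> np.ndarray:
        """Coefficients of the nested a-component submodel."""
        if a == 0:
            return np.zeros(len(self.feature_names))
        W = self.x_weights[:, :a]
        P = self.x_loadings[:, :a]
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        Xp = (np.asarray(pd.DataFrame(X), dtype=float) - self.x_mean) / self.x_scale
        return self.y_mean + Xp @ self.coef_for(a)


def fit_plsr(
    X, y, n_components: int = 3, scale: bool = True
) -> PlsrModel:
    """NIPALS single-response PLSR on mean-centered (optionally
    unit-variance-scaled) X and centered y.

    A constant response is a documented degenerate case: zero components are
    extracted, coefficients are zero and R^2 is 0 by convention.  Extraction
    also stops early if a deflated X carries no covariance with y left.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise PtyrlinkError(
            f"n_components={n_components} exceeds min(n_obs - 1, n_features)"
            f" = {min(n - 1, p)}"
        )
    Xv = X.to_numpy(dtype=float)
    x_mean = Xv.mean(axis=0)
    if scale:
        sd = Xv.std(axis=0, ddof=1)
        if not (sd > 0).all():
            bad = X.columns[~(sd > 0)][0]
            raise PtyrlinkError(
                f"feature {bad!r} has zero variance; cannot autoscale"
            )
        x_scale = sd
    else:
        x_scale = np.ones(p)
    Xp = (Xv - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y.to_numpy(dtype=float) - y_mean

    Xa = Xp.copy()
    ya = yc.copy()
    Ws, Ps, qs, Ts = [], [], [], []
    # Covariance below this fraction of the initial scale is numerically zero.
    tol = 1e-12 * max(1.0, float(np.abs(Xp.T @ yc).max()))
    for _ in range(n_components):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= tol:
            break
        w = w / nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            break
        pa = Xa.T @ t / tt
        qa = float(ya @ t / tt)
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        Ws.append(w)
        Ps.append(pa)
        qs.append(qa)
        Ts.append(t)

    A = len(Ws)
    W = np.column_stack(Ws) if A else np.zeros((p, 0))
    P = np.column_stack(Ps) if A else np.zeros((p, 0))
    q = np.asarray(qs)
    T = np.column_stack(Ts) if A else np.zeros((n, 0))
    model = PlsrModel(
        n_components=A,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=np.zeros(p),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        r2=0.0,
        feature_names=[str(c) for c in X.columns],
    )
    model.coef = model.coef_for(A)
    fitted = y_mean + Xp @ model.coef
    tss = float(yc @ yc)
    rss = float(((y.to_numpy() - fitted) ** 2).sum())
    model.r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    model.fitted = fitted
    return model


@dataclass
class LoocvResult:
    q2_by_components: pd.Series  # Q^2 for A = 1..max
    selected_n_components: int
    q2: float  # Q^2 at the selected component count
    predictions: pd.DataFrame  # observation x component count
    tss: float


def loocv(
    X, y, max_components: int = 3, scale: bool = True
) -> LoocvResult:
    """Leave-one-out cross-validation over nested component counts.

    Selection rule: the smallest component count maximizing Q^2 (ties within
    1e-12 resolve to fewer components).  ``max_components`` is capped (with a
    warning) to what the training folds can support.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n < 3:
        raise PtyrlinkError("LOOCV requires at least 3 observations")
    cap = min(n - 2, p)
    if max_components > cap:
        warnings.warn(
            f"max_components={max_components} capped to {cap} for "
            f"{n}-observation LOOCV",
            stacklevel=2,
        )
        max_components = cap
    yv = y.to_numpy(dtype=float)
    preds = np.full((n, max_components), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_plsr(
            X.iloc[mask], y.iloc[mask], n_components=max_components, scale=scale
        )
        for a in range(1, max_components + 1):
            preds[i, a - 1] = model.predict(
                X.iloc[[i]], n_components=min(a, model.n_components)
            )[0]
    tss = float(((yv - yv.mean()) ** 2).sum())
    press = ((yv[:, None] - preds) ** 2).sum(axis=0)
    q2 = 1.0 - press / tss if tss > 0 else np.zeros(max_components)
    q2_s = pd.Series(q2, index=range(1, max_components + 1), name="q2")
    best = float(np.max(q2))
    selected = int(np.nonzero(q2 >= best - 1e-12)[0][0]) + 1
    return LoocvResult(
        q2_by_components=q2_s,
        selected_n_components=selected,
        q2=float(q2_s.loc[selected]),
        predictions=pd.DataFrame(
            preds, index=X.index, columns=range(1, max_components + 1)
        ),
        tss=tss,
    )


def vip(model: PlsrModel, threshold: float = 1.5) -> pd.DataFrame:
    """Per-feature VIP scores with the selection flag at ``threshold``."""
    if model.n_components < 1:
        raise PtyrlinkError("VIP requires a model with at least one component")
    W = model.x_weights
    T = model.scores
    q = model.y_loadings
    ss = q**2 * (T * T).sum(axis=0)  # per-component explained y-SS
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    p = W.shape[0]
    v = np.sqrt(p * (wn2 * ss).sum(axis=1) / ss.sum())
    out = pd.DataFrame({"vip": v}, index=pd.Index(model.feature_names,
                                                  name="feature"))
    out["selected"] = out["vip"] > threshold
    out["rank"] = (
        out["vip"].rank(ascending=False, method="first").astype(int)
    )
    return out


def cumulative_vip(
    models: Mapping[str, PlsrModel], threshold: float = 1.5
) -> pd.DataFrame:
    """Sum VIP across phenotype models sharing one feature space.

    Rank ties are broken lexicographically by feature id.
    """
    names = None
    per_model = {}
    for phen, model in models.items():
        if names is None:
            names = model.feature_names
        elif model.feature_names != names:
            raise PtyrlinkError(
                f"model {phen!r} does not share the common feature space"
            )
        per_model[phen] = vip(model, threshold=threshold)["vip"]
    table = pd.DataFrame(per_model)
    table["cumulative_vip"] = table.sum(axis=1)
    order = table.sort_values(
        ["cumulative_vip", "feature"],
        ascending=[False, True],
        key=lambda s: s if s.name == "cumulative_vip" else s.astype(str),
    ).index
    table["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order
    )
    return table.sort_values("rank")


@dataclass
class RobustnessResult:
    full: dict
    reduced: dict
    dropped: list[str]
    vip_spearman: float


def robustness_refit(
    X,
    y,
    drop_lines: Sequence[str],
    n_components: int = 3,
    scale: bool = True,
) -> RobustnessResult:
    """Refit after removing observations and compare fit, prediction and
    VIP ranking with the full model."""
    X, y = _as_xy(X, y)
    drop = [d for d in drop_lines if d in X.index]
    keep = [i for i in X.index if i not in set(drop)]
    if len(keep) < 3:
        raise PtyrlinkError("robustness_refit needs at least 3 remaining lines")

    def _summary(Xs, ys):
        a = min(n_components, len(Xs) - 2, Xs.shape[1])
        model = fit_plsr(Xs, ys, n_components=a, scale=scale)
        cv = loocv(Xs, ys, max_components=a, scale=scale)
        return model, {"r2": model.r2, "q2": cv.q2,
                       "n_components": model.n_components}

    full_model, full_stats = _summary(X, y)
    red_model, red_stats = _summary(X.loc[keep], y.loc[keep])
    if full_model.n_components >= 1 and red_model.n_components >= 1:
        rho = stats.spearmanr(
            vip(full_model)["vip"], vip(red_model)["vip"]
        ).statistic
    else:
        rho = float("nan")
    return RobustnessResult(
        full=full_stats,
        reduced=red_stats,
        dropped=drop,
        vip_spearman=float(rho),
    )
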