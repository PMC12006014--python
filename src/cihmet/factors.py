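"""Multi-view latent factor integration tolerant of missing views.

A Gaussian group factor analysis in the MOFA family: per-view matrices
``X_v`` (samples x features, centered and unit-scaled per feature) are
decomposed as ``X_v ~ Z @ W_v.T`` with shared factor scores Z, per-view
loadings W_v, per-view noise precision tau_v, and automatic-relevance
(ARD) precisions alpha_{v,k} that shrink factors a view does not need.
Patients missing a view simply contribute nothing to that view's terms,
so factor scores are informed only by the views a patient actually has.

Fitting minimizes the MAP objective

    J = sum_v [ tau_v/2 ||X_v - Z_v W_v^T||^2 - (N_v p_v/2) log tau_v + b_t tau_v ]
      + 1/2 ||Z||^2
      + sum_{v,k} [ alpha_vk/2 ||w_vk||^2 - (p_v/2) log alpha_vk + b_a alpha_vk ]

by exact block coordinate descent (Z rows, each W_v, each tau_v, each
alpha_vk in turn).  Every block update is the closed-form minimizer given
the others, so J is provably non-increasing; the tiny Gamma-prior terms
(b_a, b_t) keep the precision updates bounded without breaking exactness.
After convergence factors are re-ordered by total variance explained, so
"LF1" is always the most explanatory factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorModel",
    "FactorDiscrimination",
    "fit_factor_model",
    "variance_explained",
    "discriminative_factor",
    "top_weights",
]

_B_ALPHA = 1e-6  # Gamma rate on ARD precisions: bounds alpha at p/(2e-6)
_B_TAU = 1e-9  # Gamma rate on noise precisions


@dataclass
class FactorModel:
    """Fitted multi-view factor model."""

    Z: pd.DataFrame  # samples x K factor scores (patients with >=1 view)
    W: dict[str, pd.DataFrame]  # per view: features x K loadings
    tau: dict[str, float]  # per-view noise precision
    alpha: dict[str, np.ndarray]  # per-view ARD precisions, length K
    R2: pd.DataFrame  # factors x views variance-explained fractions
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    # scaled data retained for variance decomposition
    X_scaled: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def factors(self) -> list[str]:
        return list(self.Z.columns)


@dataclass
class FactorDiscrimination:
    """Which factor separates the groups best, and how well."""

    factor: str
    t_stat: float
    p_value: float
    auc: float


def _scale_view(df: pd.DataFrame) -> pd.DataFrame:
    x = df.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=df.index, columns=df.columns)


def _objective(X, Zfull, row_of, W, tau, alpha, b_a=_B_ALPHA, b_t=_B_TAU) -> float:
    J = 0.5 * float((Zfull**2).sum())
    for v, Xv in X.items():
        Zv = Zfull[row_of[v]]
        R = Xv - Zv @ W[v].T
        npv = Xv.size
        J += 0.5 * tau[v] * float((R**2).sum()) - 0.5 * npv * np.log(tau[v]) + b_t * tau[v]
        ss_w = (W[v] ** 2).sum(axis=0)
        p_v = W[v].shape[0]
        J += float(np.sum(0.5 * alpha[v] * ss_w - 0.5 * p_v * np.log(alpha[v]) + b_a * alpha[v]))
    return J


def _mp_noise_floor(n: int, p: int) -> float:
    """Largest variance fraction a single factor can carve out of pure noise.

    The Marchenko-Pastur edge: top singular value of an n x p Gaussian
    matrix is ~ (sqrt(n-1) + sqrt(p))^2, as a fraction of total variance.
    Factors below this floor in every view are indistinguishable from noise.
    """
    return (np.sqrt(max(n - 1, 1)) + np.sqrt(p)) ** 2 / (max(n - 1, 1) * p)


def fit_factor_model(
    views: dict[str, pd.DataFrame],
    k: int = 10,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int = 0,
    scale: bool = True,
    min_factors: int = 0,
) -> FactorModel:
    """Fit the group factor model to per-view (samples x features) matrices.

    Views need not cover the same patients; each view's frame should contain
    only its measured samples (no missing entries).  Initialization is an SVD
    warm start on the zero-filled concatenation plus seeded jitter, so a
    fixed seed reproduces the fit exactly.  Raises if the objective ever
    increases by more than 1e-6 (it cannot, barring a numerical defect).

    After fitting, factors are re-ordered by total variance explained and
    factors whose variance share sits below the noise floor in every view
    are pruned (at least ``min_factors`` survive).
    """
    if not views:
        raise ValueError("no views supplied")
    p_min = min(df.shape[1] for df in views.values())
    if k > p_min:
        raise ValueError(f"k={k} exceeds smallest view feature count {p_min}")
    names = list(views)
    if len(names) > 1:
        counts = pd.concat([pd.Series(1, index=df.index) for df in views.values()], axis=1).notna().sum(axis=1)
        if (counts >= 2).sum() == 0:
            raise ValueError("views have non-overlapping sample sets; nothing links them")

    # patient universe in order of first appearance across views
    seen: dict = {}
    for df in views.values():
        for s in df.index:
            seen.setdefault(s, None)
    samples = pd.Index(list(seen))
    X = {v: (_scale_view(df) if scale else df.astype(float)) for v, df in views.items()}
    for v, df in X.items():
        if df.isna().any().any():
            raise ValueError(f"view {v!r} contains missing entries; preprocess first")
    row_of = {v: samples.get_indexer(df.index) for v, df in X.items()}
    Xa = {v: df.to_numpy() for v, df in X.items()}

    n = len(samples)
    rng = np.random.default_rng(seed)
    concat = np.zeros((n, sum(df.shape[1] for df in X.values())))
    off = 0
    for v in names:
        concat[row_of[v], off : off + Xa[v].shape[1]] = Xa[v]
        off += Xa[v].shape[1]
    U, S, _ = np.linalg.svd(concat, full_matrices=False)
    Zfull = U[:, :k] * S[:k] / np.sqrt(max(n - 1, 1))
    if Zfull.shape[1] < k:
        Zfull = np.pad(Zfull, ((0, 0), (0, k - Zfull.shape[1])))
    Zfull = Zfull + 0.01 * rng.normal(size=(n, k))

    W = {v: np.zeros((Xa[v].shape[1], k)) for v in names}
    tau = {v: 1.0 for v in names}
    alpha = {v: np.ones(k) for v in names}

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # W_v update: rows share the Gram matrix of the view's observed scores
        for v in names:
            Zv = Zfull[row_of[v]]
            G = tau[v] * (Zv.T @ Zv) + np.diag(alpha[v])
            W[v] = np.linalg.solve(G, tau[v] * (Zv.T @ Xa[v])).T
        # alpha update (exact, bounded by the Gamma rate)
        for v in names:
            p_v = W[v].shape[0]
            alpha[v] = p_v / ((W[v] ** 2).sum(axis=0) + 2.0 * _B_ALPHA)
        # tau update
        for v in names:
            R = Xa[v] - Zfull[row_of[v]] @ W[v].T
            tau[v] = Xa[v].size / (float((R**2).sum()) + 2.0 * _B_TAU)
        # Z update, batched by view-presence pattern
        present = np.zeros((n, len(names)), dtype=bool)
        for j, v in enumerate(names):
            present[row_of[v], j] = True
        rhs = np.zeros((n, k))
        for j, v in enumerate(names):
            rhs[row_of[v]] += tau[v] * (Xa[v] @ W[v])
        patterns = {}
        for i in range(n):
            patterns.setdefault(tuple(present[i]), []).append(i)
        for pat, idx in patterns.items():
            M = np.eye(k)
            for j, v in enumerate(names):
                if pat[j]:
                    M = M + tau[v] * (W[v].T @ W[v])
            Zfull[idx] = np.linalg.solve(M, rhs[idx].T).T
        J = _objective(Xa, Zfull, row_of, W, tau, alpha)
        if trace and J > trace[-1] + 1e-6:
            raise RuntimeError(f"objective increased at sweep {it}: {trace[-1]:.6g} -> {J:.6g}")
        if trace and abs(trace[-1] - J) <= tol * max(1.0, abs(trace[-1])):
            trace.append(J)
            converged = True
            break
        trace.append(J)

    model = FactorModel(
        Z=pd.DataFrame(Zfull, index=samples, columns=[f"LF{i+1}" for i in range(k)]),
        W={v: pd.DataFrame(W[v], index=X[v].columns, columns=[f"LF{i+1}" for i in range(k)]) for v in names},
        tau=dict(tau),
        alpha={v: alpha[v].copy() for v in names},
        R2=pd.DataFrame(),
        objective_trace=[-j for j in trace],  # reported as non-decreasing fit score
        n_iter=it,
        converged=converged,
        X_scaled=X,
    )
    model.R2 = variance_explained(model)
    order = list(model.R2.sum(axis=1).sort_values(ascending=False).index)
    # prune factors below the noise floor in every view
    floors = {v: _mp_noise_floor(X[v].shape[0], X[v].shape[1]) for v in names}
    kept = [f for f in order if any(model.R2.loc[f, v] >= floors[v] for v in names)]
    if len(kept) < min_factors:
        kept = order[: min_factors]
    perm = [model.Z.columns.get_loc(o) for o in kept]
    new_names = [f"LF{i+1}" for i in range(len(kept))]
    model.Z = model.Z.iloc[:, perm].set_axis(new_names, axis=1)
    model.W = {v: df.iloc[:, perm].set_axis(new_names, axis=1) for v, df in model.W.items()}
    model.alpha = {v: a[perm] for v, a in model.alpha.items()}
    model.R2 = model.R2.loc[kept].set_axis(new_names, axis=0)
    return model


def variance_explained(model: FactorModel, views: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Per-factor, per-view variance explained: R2(k,v) = 1 - SS(X_v - z_k w_vk^T)/SS(X_v).

    Computed over the view's observed samples on the scaled data.  Small
    negative values (a factor that slightly hurts a view) are clipped at
    -0.05 for reporting.
    """
    X = model.X_scaled if views is None else {v: _scale_view(df) for v, df in views.items()}
    out = {}
    for v, Xv in X.items():
        x = Xv.to_numpy()
        ss = float((x**2).sum())
        z = model.Z.loc[Xv.index].to_numpy()
        w = model.W[v].to_numpy()
        r2 = []
        for j in range(z.shape[1]):
            resid = x - np.outer(z[:, j], w[:, j])
            r2.append(1.0 - float((resid**2).sum()) / ss if ss > 0 else 0.0)
        out[v] = r2
    return pd.DataFrame(out, index=list(model.Z.columns)).clip(lower=-0.05)


def discriminative_factor(model: FactorModel, labels: pd.Series) -> FactorDiscrimination:
    """Pick the factor whose scores best separate the two groups (max |t|)."""
    labels = labels.reindex(model.Z.index).dropna()
    z = model.Z.loc[labels.index]
    y = labels.to_numpy().astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two groups")
    best = None
    for col in z.columns:
        a, b = z.loc[y == 1, col], z.loc[y == 0, col]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if best is None or abs(t) > abs(best[1]):
            best = (col, float(t), float(p))
    col, t, p = best
    # AUC of scores vs. group via the rank (Mann-Whitney) formula
    scores = z[col].to_numpy()
    ranks = stats.rankdata(scores)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    auc = max(auc, 1.0 - auc)  # orientation-free separability
    return FactorDiscrimination(factor=col, t_stat=t, p_value=p, auc=float(auc))


def top_weights(model: FactorModel, factor: str, view: str | None = None) -> pd.DataFrame:
    """Rank features by absolute loading on ``factor`` (descending).

    Ties in |weight| break lexicographically by feature ID.  ``view``
    restricts to one view; otherwise all views are pooled with a ``view``
    column.
    """
    frames = []
    for v, Wv in model.W.items():
        if view is not None and v != view:
            continue
        frames.append(
            pd.DataFrame(
                {"view": v, "weight": Wv[factor], "abs_weight": Wv[factor].abs()},
                index=Wv.index,
            )
        )
    if not frames:
        raise ValueError(f"unknown view {view!r}")
    out = pd.concat(frames).sort_index(kind="mergesort")  # tie-break: feature ID
    return out.sort_values("abs_weight", ascending=False, kind="mergesort")
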