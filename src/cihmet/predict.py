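"""Biomarker panel construction: random-forest stability selection and a
logistic model evaluated by ROC/AUC on train / test / whole / external sets.

Stability selection fits a random forest on a bootstrap resample of the
samples in each of ``n_runs`` runs; a feature "appears" in a run when its
impurity importance ranks in that run's top ``top_k``.  Features appearing
in at least ``freq_threshold`` runs (convention: 500 of 1000) form the final
panel.  The panel feeds a multivariate logistic regression whose per-feature
odds ratios carry Wald 95% confidence intervals; quasi-separation — common
with small cohorts and strong markers, and the reason such intervals can be
spectacularly wide — is detected and answered with a ridge-penalized
refit, flagged on the model.

AUC is computed by trapezoidal integration of the empirical ROC curve, which
equals the normalized Mann-Whitney U statistic exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "StabilityResult",
    "LogisticPanelModel",
    "stability_select",
    "split_train_test",
    "fit_panel",
    "roc_auc",
    "roc_points",
    "external_validate",
]


@dataclass
class StabilityResult:
    freq: pd.Series  # per-feature appearance count over n_runs
    panel: list[str]  # features with freq >= threshold
    n_runs: int
    top_k: int
    freq_threshold: int
    seed: int


@dataclass
class LogisticPanelModel:
    features: list[str]
    coef: pd.Series
    intercept: float
    or_ci: pd.DataFrame  # columns: OR, ci_low, ci_high, p
    separation_flag: bool = False
    auc: dict[str, float] = field(default_factory=dict)
    train_index: list[str] = field(default_factory=list)
    test_index: list[str] = field(default_factory=list)

    def decision(self, X: pd.DataFrame) -> pd.Series:
        z = X[self.features].to_numpy(dtype=float) @ self.coef.to_numpy() + self.intercept
        return pd.Series(z, index=X.index, name="score")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": self.features,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "separation_flag": self.separation_flag,
            "auc": self.auc,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticPanelModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"],
            coef=pd.Series(d["coef"], index=d["features"]),
            intercept=d["intercept"],
            or_ci=pd.DataFrame(),
            separation_flag=d.get("separation_flag", False),
            auc=d.get("auc", {}),
        )


def stability_select(
    X: pd.DataFrame,
    y: pd.Series,
    n_runs: int = 1000,
    top_k: int = 10,
    freq_threshold: int = 500,
    seed: int = 0,
    n_trees: int = 500,
) -> StabilityResult:
    """Repeated bootstrap random forests; panel = features in the top_k >= threshold times.

    Ties at the top_k boundary break by column order (logged in the rank
    convention: ``argsort`` on negated importances is stable).  Fully
    reproducible: run ``i`` uses forest seed ``seed + i`` and an independent
    bootstrap stream.
    """
    y = y.reindex(X.index)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("stability selection needs both classes present")
    p = X.shape[1]
    if top_k >= p:
        raise ValueError(f"top_k={top_k} must be smaller than the candidate count {p}")
    original_order = list(X.columns)
    X = X[sorted(original_order)]  # canonical order: frequencies are column-order invariant
    Xa, ya = X.to_numpy(dtype=float), y.to_numpy()
    n = len(ya)
    counts = np.zeros(p, dtype=int)
    boot_rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xB007]))
    for run in range(n_runs):
        while True:  # bootstrap must contain both classes
            idx = boot_rng.integers(0, n, size=n)
            if len(np.unique(ya[idx])) == 2:
                break
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=(seed + run) % (2**32)
        ).fit(Xa[idx], ya[idx])
        top = np.argsort(-rf.feature_importances_, kind="stable")[:top_k]
        counts[top] += 1
    freq = pd.Series(counts, index=X.columns, name="freq").reindex(original_order)
    panel = list(freq.index[freq >= freq_threshold])
    return StabilityResult(freq=freq, panel=panel, n_runs=n_runs, top_k=top_k, freq_threshold=freq_threshold, seed=seed)


def split_train_test(
    samples: pd.Index | list[str],
    y: pd.Series,
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified 7:3 split: |train| = round(ratio*n), class shares preserved (+/-1).

    Per-class training counts are the largest-remainder apportionment of the
    total training size, so the minority class is never squeezed out.
    """
    samples = pd.Index(samples)
    y = y.reindex(samples)
    n = len(samples)
    n_train = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    quotas = {}
    by_class = {c: samples[y == c] for c in np.unique(y)}
    raw = {c: n_train * len(idx) / n for c, idx in by_class.items()}
    base = {c: int(np.floor(q)) for c, q in raw.items()}
    short = n_train - sum(base.values())
    for c in sorted(raw, key=lambda c: raw[c] - base[c], reverse=True)[:short]:
        base[c] += 1
    train: list[str] = []
    for c, idx in by_class.items():
        perm = rng.permutation(len(idx))
        quotas[c] = base[c]
        train += list(idx[perm[: base[c]]])
    train_set = set(train)
    test = [s for s in samples if s not in train_set]
    return sorted(train), sorted(test)


def fit_panel(
    X: pd.DataFrame,
    y: pd.Series,
    features: list[str],
    ridge_alpha: float = 1.0,
) -> LogisticPanelModel:
    """Maximum-likelihood logistic fit of the panel; Wald CIs on the OR scale.

    Separation (non-convergent or exploding MLE) is flagged and answered with
    an L2-penalized refit; the flag travels with the model so downstream
    reporting can note the unstable intervals.
    """
    import statsmodels.api as sm

    Xp = X[features].astype(float)
    exog = sm.add_constant(Xp, has_constant="add")
    separation = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.reindex(X.index).astype(float), exog).fit(disp=0, maxiter=200)
        params, bse, pvals = res.params, res.bse, res.pvalues
        if not res.mle_retvals.get("converged", True) or np.abs(params.iloc[1:]).max() > 50 or bse.isna().any():
            separation = True
    except Exception:
        separation = True
    if separation:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0 / ridge_alpha, solver="lbfgs", max_iter=1000)
        lr.fit(Xp.to_numpy(), y.reindex(X.index).to_numpy().astype(int))
        params = pd.Series([lr.intercept_[0], *lr.coef_[0]], index=["const", *features])
        bse = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)
    coef = params.drop("const")
    se = bse.drop("const")
    or_ci = pd.DataFrame(
        {
            "OR": np.exp(coef),
            "ci_low": np.exp(coef - 1.96 * se),
            "ci_high": np.exp(coef + 1.96 * se),
            "p": pvals.drop("const"),
        }
    )
    return LogisticPanelModel(
        features=list(features),
        coef=coef,
        intercept=float(params["const"]),
        or_ci=or_ci,
        separation_flag=separation,
    )


def roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve: (FPR, TPR) at every distinct score threshold."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y)[order]
    scores = np.asarray(scores)[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep only the last point of each tied-score block
    distinct = np.r_[scores[1:] != scores[:-1], True]
    tps, fps = tps[distinct], fps[distinct]
    P, N = tps[-1], fps[-1]
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes")
    return np.r_[0.0, fps / N], np.r_[0.0, tps / P]


def roc_auc(scores, y) -> float:
    """Trapezoidal area under the ROC curve (== normalized Mann-Whitney U)."""
    fpr, tpr = roc_points(np.asarray(scores, dtype=float), np.asarray(y))
    return float(np.trapezoid(tpr, fpr))


def external_validate(model: LogisticPanelModel, X: pd.DataFrame, y: pd.Series) -> float:
    """Apply a frozen panel model to an external cohort, aligned by feature ID."""
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise ValueError(f"external set lacks panel feature(s): {missing}")
    scores = model.decision(X)
    return roc_auc(scores.to_numpy(), y.reindex(X.index).to_numpy().astype(int))
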