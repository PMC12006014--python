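"""Covariate-adjusted differential expression with empirical-Bayes moderation.

Per-feature ordinary least squares on log2 abundances against a shared design
(intercept, group, clinical covariates), followed by the classic
moderated-t construction: per-feature residual variances s_g^2 with d_g
degrees of freedom are shrunk toward a prior s_0^2 estimated, together with
its prior degrees of freedom d_0, by matching the moments of log s_g^2
(digamma/trigamma inversion).  The moderated statistic

    t_g = beta_g / sqrt(s2_post_g * v_g),   s2_post = (d0*s0^2 + d_g*s_g^2)/(d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom.  p-values
are two-sided; Benjamini-Hochberg adjustment is applied within tissue.

Also provides HMDB-class tallies of the selected metabolites and PCA scores
on the differential features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_design",
    "fit_group_model",
    "ModerationState",
    "moderate",
    "test_features",
    "run_dem",
    "classify_dems",
    "pca_scores",
]

DEFAULT_COVARIATES = ("age", "gender", "bmi")


def build_design(
    metadata: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    bmi_cut: float | None = 24.0,
) -> pd.DataFrame:
    """Design matrix: intercept, group indicator, then covariate columns.

    ``gender`` becomes a male indicator; ``bmi`` is dichotomized at
    ``bmi_cut`` (kg/m^2) unless ``bmi_cut`` is None, in which case it enters
    continuously.  Age enters continuously.
    """
    cols = {"intercept": np.ones(len(metadata)), "group": metadata["group"].astype(float).to_numpy()}
    for cov in covariates:
        if cov == "gender":
            cols["gender_male"] = (metadata["gender"].astype(str).str.lower() == "male").astype(float).to_numpy()
        elif cov == "bmi" and bmi_cut is not None:
            cols["bmi_ge_cut"] = (metadata["bmi"].astype(float) >= bmi_cut).astype(float).to_numpy()
        else:
            cols[cov] = metadata[cov].astype(float).to_numpy()
    return pd.DataFrame(cols, index=metadata.index)


def fit_group_model(
    m: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    bmi_cut: float | None = 24.0,
) -> tuple[pd.DataFrame, float]:
    """Per-feature OLS of log2 abundance on the group design.

    Returns a per-feature frame (``coef`` = adjusted log2 fold-change,
    ``s2`` = residual variance, ``df`` = residual degrees of freedom) and the
    unscaled variance ``v_g`` of the group coefficient (shared across
    features since the design is shared).
    """
    metadata = metadata.loc[m.index]
    D = build_design(metadata, covariates, bmi_cut)
    X = D.to_numpy()
    n, q = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = [D.columns[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    if n <= q:
        raise ValueError(f"no residual degrees of freedom: n={n}, design columns={q}")
    Y = m.to_numpy(dtype=float)
    B, rss, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    df = n - q
    s2 = rss / df
    v_g = float(np.linalg.inv(X.T @ X)[1, 1])
    out = pd.DataFrame({"coef": B[1], "s2": s2, "df": float(df)}, index=m.columns)
    return out, v_g


@dataclass
class ModerationState:
    """Empirical-Bayes variance moderation parameters and posteriors."""

    d0: float  # prior degrees of freedom (may be inf)
    s0_2: float  # prior variance
    s2_post: pd.Series  # posterior (shrunk) variances per feature
    df_total: pd.Series  # d0 + d_g per feature (capped for inf)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate(fit: pd.DataFrame) -> ModerationState:
    """Estimate (d0, s0^2) from the spread of log residual variances and shrink.

    With all residual variances (near) equal the between-feature spread of
    log s_g^2 is fully explained by chi-square sampling noise, d0 is
    estimated as infinite and no feature-specific information survives
    (s2_post = s0^2... = s_g^2 in the exactly-equal case).  Fewer than two
    features: moderation is skipped (d0 = 0, ordinary t).
    """
    s2 = fit["s2"].to_numpy(dtype=float)
    df = fit["df"].to_numpy(dtype=float)
    if len(s2) < 2:
        import warnings

        warnings.warn("fewer than 2 features: variance moderation skipped (d0=0)")
        return ModerationState(0.0, float(np.nan), fit["s2"].copy(), fit["df"].copy())
    # moment matching on e_g = log s_g^2 corrected for the chi-square bias
    ok = s2 > 0
    e = np.log(np.where(ok, s2, np.nan))
    e = e - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = np.nanmean(e)
    e_var = np.nanvar(e, ddof=1) - np.nanmean(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))) if np.isfinite(d0) else float(
            np.exp(e_mean)
        )
    else:
        # no evidence of between-feature spread beyond sampling noise: infinite
        # prior df; the prior variance is the geometric mean of the observed
        # variances (so exactly-equal variances are returned unchanged)
        d0, s0_2 = np.inf, float(np.exp(np.nanmean(np.log(np.where(ok, s2, np.nan)))))
    if np.isfinite(d0):
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    else:
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(df, np.inf)
    return ModerationState(
        float(d0),
        s0_2,
        pd.Series(s2_post, index=fit.index),
        pd.Series(df_total, index=fit.index),
    )


def test_features(
    fit: pd.DataFrame,
    state: ModerationState,
    v_g: float,
    tissue: str = "",
    alpha: float = 0.05,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Moderated t-tests and BH adjustment; flags DEMs at raw p < ``alpha``.

    ``annotations`` may carry hmdb_id / kegg_id / hmdb_class columns indexed
    by feature.  The adjusted p-value is reported alongside; the selection
    gate uses the raw p by default (configurable upstream).
    """
    coef = fit["coef"].to_numpy(dtype=float)
    se = np.sqrt(state.s2_post.to_numpy() * v_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    dft = state.df_total.to_numpy(dtype=float)
    p = np.where(np.isfinite(dft), 2.0 * stats.t.sf(np.abs(t), np.maximum(dft, 1e-9)), 2.0 * stats.norm.sf(np.abs(t)))
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "feature_id": fit.index,
            "log2FC": coef,
            "t_moderated": t,
            "p_raw": p,
            "p_adjusted": p_adj,
            "dem": p < alpha,
            "tissue": tissue,
        }
    ).set_index("feature_id")
    if annotations is not None:
        for col in ("hmdb_id", "kegg_id", "hmdb_class"):
            if col in annotations.columns:
                out[col] = annotations[col].reindex(out.index)
    return out


def run_dem(
    m: pd.DataFrame,
    metadata: pd.DataFrame,
    tissue: str = "",
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    bmi_cut: float | None = 24.0,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit, moderate and test one tissue's log2 matrix in a single call."""
    fit, v_g = fit_group_model(m, metadata, covariates, bmi_cut)
    state = moderate(fit)
    return test_features(fit, state, v_g, tissue=tissue, alpha=alpha, annotations=annotations)


def classify_dems(dems: pd.DataFrame, taxonomy: pd.Series) -> pd.Series:
    """Count selected metabolites per HMDB chemical class, sorted descending."""
    flagged = dems.index[dems["dem"]] if "dem" in dems.columns else dems.index
    classes = taxonomy.reindex(flagged).dropna()
    return classes.value_counts().sort_values(ascending=False)


def pca_scores(dem_matrix: pd.DataFrame, scale: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on differential features (centered, optionally autoscaled).

    Returns scores on the first two components and the explained-variance
    fractions of all components.  Scores are deterministic up to component
    sign.
    """
    if len(dem_matrix) < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = dem_matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S**2
    explained = var / var.sum() if var.sum() > 0 else var
    k = min(2, len(S))
    scores = pd.DataFrame(U[:, :k] * S[:k], index=dem_matrix.index, columns=[f"PC{i+1}" for i in range(k)])
    return scores, explained
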