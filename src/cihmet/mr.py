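"""Two-sample Mendelian randomization estimators and diagnostics, in closed form.

Inputs are harmonized per-SNP summary statistics: the variant's effect on the
exposure (a metabolite) with its standard error, and its effect on the
outcome (a liver-enzyme proxy) with its standard error.  Implemented
estimators:

* Wald ratio — beta_outcome / beta_exposure per SNP, delta-method SE.
* IVW — inverse-variance-weighted meta-analysis of the Wald ratios,
  ``beta = sum(bx*by/sey^2) / sum(bx^2/sey^2)``; the random-effects flavor
  inflates the fixed SE by ``max(1, sqrt(Q/(k-1)))`` (multiplicative model).
* MR-Egger — weighted regression of by on bx with a free intercept
  (directional pleiotropy), exposure effects oriented non-negative first.
* Weighted median — interpolated 50th weighted percentile of the ratios,
  consistent when up to half the instrument weight is invalid; SE by
  parametric bootstrap.
* Cochran's Q and leave-one-out re-estimation as heterogeneity diagnostics.

Confidence intervals are normal-theory (beta +/- 1.96*SE) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "leave_one_out",
    "mr_suite",
]

_Z95 = 1.959963984540054


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    k: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        self.ci_low = self.beta - _Z95 * self.se
        self.ci_high = self.beta + _Z95 * self.se


def _cols(instruments: pd.DataFrame):
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    sex = instruments["se_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sey = instruments["se_outcome"].to_numpy(dtype=float)
    if (sex <= 0).any() or (sey <= 0).any():
        raise ValueError("standard errors must be strictly positive")
    if instruments["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP IDs in instrument set")
    return bx, sex, by, sey


def wald_ratio(bx: float, by: float, sey: float) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if bx == 0:
        raise ValueError("zero exposure effect: Wald ratio undefined (null instrument)")
    beta = by / bx
    se = abs(sey / bx)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(method="wald_ratio", beta=float(beta), se=float(se), p=float(p), k=1)


def ivw(instruments: pd.DataFrame, effects: str = "random") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios."""
    if effects not in ("fixed", "random"):
        raise ValueError("effects must be 'fixed' or 'random'")
    bx, _, by, sey = _cols(instruments)
    k = len(bx)
    if k == 0:
        raise ValueError("empty instrument set")
    w = bx**2 / sey**2
    beta = float(np.sum(bx * by / sey**2) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    ratios = by / bx
    q = float(np.sum(w * (ratios - beta) ** 2))
    se = se_fixed
    if effects == "random" and k > 1:
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(
        method=f"ivw_{effects}",
        beta=beta,
        se=se,
        p=float(p),
        k=k,
        q_stat=q,
        q_df=k - 1,
        q_p=float(stats.chi2.sf(q, k - 1)) if k > 1 else None,
    )


def mr_egger(instruments: pd.DataFrame) -> MREstimate:
    """Weighted regression of outcome on exposure betas with a free intercept.

    Exposure effects are oriented non-negative first (the standard
    orientation convention); a non-zero intercept signals directional
    pleiotropy.  Needs k >= 3 and genuine spread in the exposure betas.
    """
    import statsmodels.api as sm

    bx, _, by, sey = _cols(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError(f"MR-Egger is under-identified with k={k} < 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bxo, byo = bx * flip, by * flip
    if np.ptp(bxo) < 1e-12:
        raise ValueError("degenerate design: no spread in |beta_exposure| (rank deficient)")
    X = sm.add_constant(bxo)
    res = sm.WLS(byo, X, weights=1.0 / sey**2).fit()
    slope, slope_se = float(res.params[1]), float(res.bse[1])
    icpt, icpt_se = float(res.params[0]), float(res.bse[0])
    # t reference with k-2 df for both coefficients
    slope_p = 2.0 * stats.t.sf(abs(slope / slope_se), k - 2)
    icpt_p = 2.0 * stats.t.sf(abs(icpt / icpt_se), k - 2)
    return MREstimate(
        method="mr_egger",
        beta=slope,
        se=slope_se,
        p=float(slope_p),
        k=k,
        intercept=icpt,
        intercept_se=icpt_se,
        intercept_p=float(icpt_p),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Interpolated weighted median of the Wald ratios; bootstrap SE.

    Weights are the inverse delta-method variances of the ratios.  The SE is
    the standard deviation of the estimator over ``n_boot`` parametric
    resamples of the summary statistics (seeded, reproducible).
    """
    bx, sex, by, sey = _cols(instruments)
    k = len(bx)
    if k < 2:
        raise ValueError(f"weighted median needs k >= 2 instruments, got {k}")
    ratios = by / bx
    w = (bx / sey) ** 2
    beta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.normal(0.0, sex)
        byb = by + rng.normal(0.0, sey)
        bxb[bxb == 0] = 1e-12
        boots[b] = _weighted_median(byb / bxb, (bxb / sey) ** 2)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta != 0 else 1.0)
    return MREstimate(method="weighted_median", beta=beta, se=se, p=float(p), k=k)


def cochran_q(instruments: pd.DataFrame, beta_ref: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q of the Wald ratios about ``beta_ref`` (default: IVW fixed).

    Returns (Q, df, p) with df = k - 1 and a chi-square reference.
    """
    bx, _, by, sey = _cols(instruments)
    k = len(bx)
    if beta_ref is None:
        beta_ref = ivw(instruments, effects="fixed").beta
    w = (bx / sey) ** 2
    q = float(np.sum(w * (by / bx - beta_ref) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df)) if df > 0 else 1.0


def leave_one_out(instruments: pd.DataFrame, effects: str = "random") -> pd.DataFrame:
    """Re-estimate IVW dropping each SNP once; flag influential instruments.

    A drop is flagged when the re-estimated beta falls outside the full-set
    95% CI — the single-SNP-dominance diagnostic.
    """
    full = ivw(instruments, effects=effects)
    rows = []
    for snp in instruments["snp_id"]:
        sub = instruments[instruments["snp_id"] != snp]
        est = ivw(sub, effects=effects)
        rows.append(
            {
                "snp_dropped": snp,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "outside_full_ci": not (full.ci_low <= est.beta <= full.ci_high),
            }
        )
    return pd.DataFrame(rows)


def mr_suite(instruments: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """All estimators on one instrument set, as a per-method table."""
    ests = [ivw(instruments, "fixed"), ivw(instruments, "random")]
    if len(instruments) >= 3:
        ests.append(mr_egger(instruments))
    if len(instruments) >= 2:
        ests.append(weighted_median(instruments, seed=seed))
    rows = []
    for e in ests:
        rows.append(
            {
                "method": e.method,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p,
                "k": e.k,
                "Q": e.q_stat,
                "Q_p": e.q_p,
                "egger_intercept": e.intercept,
                "egger_intercept_p": e.intercept_p,
            }
        )
    return pd.DataFrame(rows)
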