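"""Matrix-level metabolomics preprocessing and cohort summaries.

Order of operations (as the data would flow off the instrument): the 80%
rule drops sparsely observed features, per-sample sum normalization converts
intensities to relative abundances, remaining gaps are imputed as half the
feature's observed minimum, and values are log2-transformed.  Duplicate
compounds detected in both ionization modes are collapsed to the mode with
the larger median peak area.  Zeros are treated as missing throughout: a
zero in an intensity table means "not detected", not "absent at zero
abundance".

Matrices are pandas DataFrames, samples x features, NaN = missing.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "apply_80_rule",
    "sum_normalize",
    "impute_and_log2",
    "merge_ion_modes",
    "cohort_summary",
    "feature_cv",
    "preprocess_view",
]

logger = logging.getLogger(__name__)


def _as_missing(m: pd.DataFrame) -> pd.DataFrame:
    """Treat exact zeros as missing (not-detected convention)."""
    return m.mask(m == 0)


def apply_80_rule(
    m: pd.DataFrame,
    threshold: float = 0.8,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Retain features observed (non-missing, non-zero) in >= ``threshold`` of samples.

    With ``groups`` given, a feature is kept when it meets the threshold in
    at least one group (the per-group variant of the rule).  Column order of
    retained features is preserved.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if m.empty:
        logger.warning("apply_80_rule: empty matrix")
        return m.copy()
    obs = _as_missing(m).notna()
    if groups is None:
        keep = obs.mean(axis=0) >= threshold
    else:
        groups = groups.reindex(m.index)
        keep = obs.groupby(groups, observed=True).mean().max(axis=0) >= threshold
    return m.loc[:, keep[keep].index]


def sum_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its non-missing intensities sum to 1.

    Missing entries stay missing.  A sample whose observed total is zero (or
    that is entirely missing, while having measured entries expected) cannot
    be normalized and raises, naming the sample.
    """
    m = _as_missing(m)
    totals = m.sum(axis=1, min_count=1)
    bad = ~(totals > 0)  # catches zero totals and all-missing samples alike
    if bad.any():
        raise ValueError(f"sum_normalize: non-positive total intensity for sample(s) {list(m.index[bad])}")
    return m.div(totals, axis=0)


def impute_and_log2(m: pd.DataFrame) -> pd.DataFrame:
    """Impute missing entries as half the feature's minimum observed value, then log2.

    Every feature must have at least one observed value (guaranteed after the
    80% rule); the output contains no missing entries.
    """
    m = _as_missing(m)
    mins = m.min(axis=0)
    assert not mins.isna().any(), "feature with no observed values reached imputation"
    filled = m.fillna(mins / 2.0)
    return np.log2(filled)


def merge_ion_modes(
    pos: pd.DataFrame,
    neg: pd.DataFrame,
    compound_map: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse compounds measured in both ionization modes to one record.

    ``compound_map`` maps feature ID -> compound ID (features absent from the
    map are their own compound).  When a compound appears in both modes, the
    mode with the larger median peak area is kept.  Returns the merged matrix
    (columns = compound IDs, the set-union of the inputs' compounds) and a
    provenance Series compound ID -> kept mode ("positive"/"negative").
    """
    if compound_map is None:
        compound_map = pd.Series(dtype=object)
    conflicts = [f for f in compound_map.index[compound_map.index.duplicated()]]
    if conflicts:
        raise ValueError(f"conflicting compound map entries for features: {sorted(set(conflicts))}")

    def compounds(cols) -> dict[str, str]:
        return {c: compound_map.get(c, c) for c in cols}

    pos_c, neg_c = compounds(pos.columns), compounds(neg.columns)
    merged: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    for mode, frame, cmap in (("positive", pos, pos_c), ("negative", neg, neg_c)):
        for feat, comp in cmap.items():
            col = frame[feat]
            if comp not in merged:
                merged[comp], provenance[comp] = col, mode
            elif col.median(skipna=True) > merged[comp].median(skipna=True):
                merged[comp], provenance[comp] = col, mode
    out = pd.DataFrame(merged)
    out.index = pos.index.union(neg.index, sort=False) if not pos.index.equals(neg.index) else pos.index
    return out, pd.Series(provenance, name="kept_mode")


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(metadata: pd.DataFrame, stratum: str, cuts=None) -> pd.DataFrame:
    """Cross-tabulate patient counts by group x stratum with whole-cohort percentages.

    ``cuts`` optionally bins a numeric variable (e.g. ``bmi`` at 24, ``age``
    at 60).  Percentages use the full cohort size as denominator and are
    rounded half-away-from-zero to one decimal, the convention of clinical
    characteristics tables.
    """
    if stratum not in metadata.columns:
        raise ValueError(f"unknown stratum variable {stratum!r}")
    values = metadata[stratum]
    if cuts is not None:
        edges = [-np.inf, *cuts, np.inf]
        labels = [f"<{cuts[0]}"] + [f"{lo}-{hi}" for lo, hi in zip(cuts[:-1], cuts[1:])] + [f">={cuts[-1]}"]
        values = pd.cut(values, bins=edges, labels=labels, right=False)
    table = pd.crosstab(values, metadata["group"])
    table.columns = ["normal" if g == 0 else "CIH" for g in table.columns]
    n = len(metadata)
    out = table.copy().astype(float)
    for col in table.columns:
        out[f"{col}_pct"] = [_round_half_up(100.0 * c / n) for c in table[col]]
    out[table.columns] = table
    return out


def feature_cv(m: pd.DataFrame, feature_id: str) -> float:
    """Coefficient of variation (sample SD / mean) of a feature's raw-scale values."""
    x = _as_missing(m)[feature_id].dropna()
    mean = x.mean()
    if mean == 0 or len(x) == 0:
        raise ValueError(f"CV undefined for feature {feature_id!r} (zero mean or no data)")
    if len(x) == 1:
        return 0.0
    return float(x.std(ddof=1) / mean)


def preprocess_view(
    m: pd.DataFrame,
    threshold: float = 0.8,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Full per-view chain: 80% rule -> sum normalization -> imputation -> log2.

    Samples with no observations at all (patients lacking this view) are
    dropped first; they carry no information for this view.
    """
    m = _as_missing(m)
    m = m.loc[m.notna().any(axis=1)]
    return impute_and_log2(sum_normalize(apply_80_rule(m, threshold, groups)))
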