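"""Synthetic multi-tissue metabolomics cohorts with known ground truth.

Emulates the study layout this package targets: a 63-patient colorectal-cancer
cohort (19 chemotherapy-induced-hepatotoxicity cases, 44 normal) measured on
up to three metabolomic views — colorectal tissue (CRT, 54 patients), plasma
(49) and urine (44) — plus pathway sets and harmonized SNP summary statistics
for Mendelian randomization.

The intensity model is log2-normal: on the log2 scale each feature is a
per-feature baseline plus shared latent-factor structure ``Z @ W.T``, a group
mean shift for planted differential features, and Gaussian noise; intensities
are the exponential (base 2) of that.  Planted log2 fold-changes are therefore
exact in expectation, which is what makes every downstream estimate testable.
Group labels are drawn first and effects conditioned on the label
(case-control design).  Missing views are missing completely at random.

Every operation draws from a named sub-stream of the master seed, so a fixed
seed gives byte-identical output and single stages can be re-run in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import substream, write_matrix, write_gmt

__all__ = [
    "CohortSpec",
    "EffectTruth",
    "default_cohort_spec",
    "generate_cohort",
    "plan_truth",
    "generate_views",
    "generate_pathway_sets",
    "generate_mr_dataset",
    "write_dataset",
]

#: View coverage of the emulated study cohort.
DEFAULT_COVERAGE = {"CRT": 54, "plasma": 49, "urine": 44}


@dataclass
class CohortSpec:
    """Cohort layout: sizes, per-view coverage and covariate distributions.

    Parameters
    ----------
    n_total, n_case
        Cohort size and number of hepatotoxicity cases (``n_case < n_total``).
    view_coverage
        Mapping view name -> number of patients with that view measured.
    age_mean, age_sd
        Normal distribution of age in years (clipped to [25, 85]).
    male_frac
        Probability a patient is male.
    bmi_mean, bmi_sd
        Normal distribution of body-mass index (kg/m^2).
    seed
        Master RNG seed; fixed seed means byte-identical output.
    """

    n_total: int = 63
    n_case: int = 19
    view_coverage: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    age_mean: float = 57.0
    age_sd: float = 10.0
    male_frac: float = 0.667
    bmi_mean: float = 23.5
    bmi_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_case < self.n_total:
            raise ValueError(f"n_case must satisfy 0 <= n_case < n_total, got {self.n_case}/{self.n_total}")
        for view, count in self.view_coverage.items():
            if count > self.n_total:
                raise ValueError(f"view {view!r}: coverage {count} exceeds n_total {self.n_total}")
            if count < 0:
                raise ValueError(f"view {view!r}: negative coverage")


@dataclass
class EffectTruth:
    """Planted ground truth for one simulated dataset.

    ``log2fc_planted`` maps view -> {feature_id: signed log2 fold-change
    (case vs. normal)}.  ``biomarker_ids`` lists the features intended to
    drive prediction (their effects also appear in ``log2fc_planted``).
    ``factor_loadings_true`` holds the per-view loading matrices used to
    generate the shared latent structure.  ``mr_truth`` records the causal
    slope, pleiotropy fraction and instrument count of an associated MR set.
    """

    dem_ids: dict[str, list[str]]
    log2fc_planted: dict[str, dict[str, float]]
    factor_loadings_true: dict[str, np.ndarray]
    factor_group_shift: np.ndarray
    biomarker_ids: dict[str, list[str]]
    mr_truth: dict[str, float]
    log2fc_range: tuple[float, float] = (0.16, 0.95)

    def validate(self, feature_ids: Mapping[str, Sequence[str]]) -> None:
        lo, hi = self.log2fc_range
        for view, effects in self.log2fc_planted.items():
            universe = set(feature_ids[view])
            for fid, fc in effects.items():
                if fid not in universe:
                    raise ValueError(f"planted feature {fid!r} not in view {view!r}")
                if fid not in self.biomarker_ids.get(view, ()) and not lo <= abs(fc) <= hi:
                    raise ValueError(f"planted |log2FC|={abs(fc):.3f} outside range {self.log2fc_range}")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study-layout cohort: 63 patients, 19 cases, coverage 54/49/44."""
    return CohortSpec(seed=seed)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw patient metadata and the view-presence mask.

    Returns
    -------
    metadata : DataFrame indexed by patient ID with columns
        ``group`` (1 = case), ``age``, ``gender`` ("male"/"female"), ``bmi``.
    mask : boolean DataFrame patients x views; column sums equal the
        requested coverage exactly.
    """
    rng = substream(spec.seed, "cohort")
    ids = [f"P{i+1:03d}" for i in range(spec.n_total)]
    group = np.zeros(spec.n_total, dtype=int)
    group[rng.choice(spec.n_total, size=spec.n_case, replace=False)] = 1
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, spec.n_total), 25, 85).round(1)
    gender = np.where(rng.random(spec.n_total) < spec.male_frac, "male", "female")
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, spec.n_total), 15, 40).round(1)
    metadata = pd.DataFrame(
        {"group": group, "age": age, "gender": gender, "bmi": bmi}, index=pd.Index(ids, name="patient_id")
    )
    mask = pd.DataFrame(False, index=metadata.index, columns=list(spec.view_coverage))
    for view, count in spec.view_coverage.items():
        present = rng.choice(spec.n_total, size=count, replace=False)
        mask.iloc[present, mask.columns.get_loc(view)] = True
    return metadata, mask


def plan_truth(
    spec: CohortSpec,
    n_features: Mapping[str, int],
    n_dems: Mapping[str, int] | int = 20,
    n_biomarkers: int = 5,
    biomarker_log2fc: float = 1.0,
    biomarker_module_loading: float = 1.5,
    k_factors: int = 3,
    loading_scale: float = 0.5,
    factor_group_shift: float | Sequence[float] = 0.0,
    log2fc_range: tuple[float, float] = (0.16, 0.95),
    mr_truth: Mapping[str, float] | None = None,
) -> EffectTruth:
    """Lay out planted effects, biomarkers and latent-factor loadings.

    Differential effects are drawn uniformly in ``log2fc_range`` with random
    sign — the span observed across the candidate-biomarker effect sizes of
    the emulated study.  Biomarkers are the first ``n_biomarkers`` planted
    features of each view and get the fixed effect ``biomarker_log2fc``
    (standardized effect = biomarker_log2fc / noise_sd of the view model).
    The default ``loading_scale`` of 0.5 puts each latent factor's variance
    share in the 10-20% band typical of a dominant metabolomic factor.
    ``factor_group_shift`` adds a per-factor mean difference between groups,
    making that factor group-discriminative; it defaults to zero so the
    group signal lives entirely in the planted effects and the
    planted-feature ground truth stays interpretable.

    Biomarkers additionally share a latent module: their loading on the
    first factor is ``sign(effect) * biomarker_module_loading``, so they
    form a mutually correlated block — the hub structure that makes real
    candidate biomarkers sit central in correlation networks and carry
    large absolute factor weights.

    Each view emphasizes the factors differently (a geometric activity
    profile rotated across views), mirroring how one latent factor
    dominates one tissue and another tissue loads a different factor.
    This per-view heterogeneity is also what makes the factors
    rotationally identifiable to a fitted model.
    """
    rng = substream(spec.seed, "truth")
    if isinstance(n_dems, int):
        n_dems = {v: n_dems for v in n_features}
    lo, hi = log2fc_range
    dem_ids: dict[str, list[str]] = {}
    fcs: dict[str, dict[str, float]] = {}
    loadings: dict[str, np.ndarray] = {}
    biomarkers: dict[str, list[str]] = {}
    base_activity = 0.6 ** np.arange(k_factors)
    for view_idx, (view, p) in enumerate(n_features.items()):
        feats = [f"{view}_f{j+1:04d}" for j in range(p)]
        k = min(n_dems[view], p)
        planted = feats[:k]  # leading block; position carries no information downstream
        nb = min(n_biomarkers, k)
        biomarkers[view] = planted[:nb]
        eff = {}
        for fid in planted[:nb]:
            eff[fid] = float(rng.choice([-1.0, 1.0]) * biomarker_log2fc)
        for fid in planted[nb:]:
            eff[fid] = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))
        dem_ids[view] = planted
        fcs[view] = eff
        activity = np.roll(base_activity, view_idx)
        W = rng.normal(0.0, loading_scale, size=(p, k_factors)) * activity
        for j, fid in enumerate(planted[:nb]):
            W[j, 0] = np.sign(eff[fid]) * biomarker_module_loading
        loadings[view] = W
    shift = np.broadcast_to(np.atleast_1d(np.asarray(factor_group_shift, dtype=float)), (k_factors,)).copy() \
        if np.ndim(factor_group_shift) == 0 else np.asarray(factor_group_shift, dtype=float)
    if shift.shape != (k_factors,):
        raise ValueError("factor_group_shift must be scalar or length k_factors")
    return EffectTruth(
        dem_ids=dem_ids,
        log2fc_planted=fcs,
        factor_loadings_true=loadings,
        factor_group_shift=shift,
        biomarker_ids=biomarkers,
        mr_truth=dict(mr_truth or {"true_slope": 0.3, "pleiotropy_fraction": 0.0, "k": 50}),
        log2fc_range=log2fc_range,
    )


def generate_views(
    spec: CohortSpec,
    truth: EffectTruth,
    n_features: Mapping[str, int] | None = None,
    noise_sd: float = 1.0,
    missing_rate: float = 0.05,
    baseline_range: tuple[float, float] = (8.0, 12.0),
    metadata: pd.DataFrame | None = None,
    mask: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Generate per-view intensity matrices from the planted truth.

    On the log2 scale each observed entry is::

        baseline_j + (Z @ W_v.T)_ij + group_i * log2fc_planted_j + eps,  eps ~ N(0, noise_sd)

    with Z the shared patient factor scores (standard normal, plus the
    per-factor group shift).  Intensities are ``2**X``.  Rows for patients
    lacking a view are all-NaN; additional entries are set missing at random
    at ``missing_rate`` (before the 80% rule downstream).  The default
    baseline span (2^8 to 2^12) keeps any single feature's share of a
    sample's total intensity small, so downstream sum normalization leaves
    planted log2 fold-changes first-order intact (compositional closure
    stays a second-order effect).

    Returns ``(views, metadata, mask)`` where ``views[v]`` is a samples x
    features intensity DataFrame.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if metadata is None or mask is None:
        metadata, mask = generate_cohort(spec)
    if n_features is None:
        n_features = {v: W.shape[0] for v, W in truth.factor_loadings_true.items()}
    feature_ids = {v: [f"{v}_f{j+1:04d}" for j in range(p)] for v, p in n_features.items()}
    truth.validate(feature_ids)

    rng = substream(spec.seed, "views")
    n = spec.n_total
    k = truth.factor_group_shift.shape[0]
    Z = rng.normal(size=(n, k)) + np.outer(metadata["group"].to_numpy(), truth.factor_group_shift)
    y = metadata["group"].to_numpy()[:, None]

    views: dict[str, pd.DataFrame] = {}
    for view, p in n_features.items():
        W = truth.factor_loadings_true[view]
        if W.shape != (p, k):
            raise ValueError(f"loading matrix for {view!r} has shape {W.shape}, expected {(p, k)}")
        baseline = rng.uniform(*baseline_range, size=p)
        fc = np.zeros(p)
        idx = {fid: j for j, fid in enumerate(feature_ids[view])}
        for fid, effect in truth.log2fc_planted.get(view, {}).items():
            fc[idx[fid]] = effect
        X = baseline + Z @ W.T + y * fc + rng.normal(0.0, noise_sd, size=(n, p))
        intensity = np.exp2(X)
        if missing_rate > 0:
            intensity[rng.random((n, p)) < missing_rate] = np.nan
        df = pd.DataFrame(intensity, index=metadata.index, columns=feature_ids[view])
        df.loc[~mask[view]] = np.nan  # absent view: whole row missing
        views[view] = df
    return views, metadata, mask


def generate_pathway_sets(
    features: Sequence[str],
    n_pathways: int,
    size_range: tuple[int, int] = (5, 20),
    enriched: tuple[str, Sequence[str], float] | None = None,
    seed: int = 0,
    category: str = "metabolism",
) -> pd.DataFrame:
    """Random pathway sets over ``features``, optionally seeding one with DEMs.

    ``enriched`` is ``(pathway_id, dem_ids, dem_fraction)``: that pathway
    takes ``dem_fraction`` of its members from ``dem_ids`` — in the given
    order, so the list's leading entries (the planted disease module) are
    always covered — and the rest at random, giving a known
    over-represented set.  Returns a DataFrame with columns
    pathway_id / category / members (GMT layout).
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(features):
        raise ValueError(f"size_range {size_range} outside [1, {len(features)}]")
    rng = substream(seed, "pathways")
    features = list(features)
    rows = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(features, size=size, replace=False))
        rows.append({"pathway_id": f"PW{i+1:04d}", "category": category, "members": members})
    if enriched is not None:
        pid, dem_ids, frac = enriched
        dem_ids = [f for f in dem_ids if f in set(features)]
        size = max(lo, min(hi, len(dem_ids)))
        n_dem = min(len(dem_ids), int(round(frac * size)))
        members = list(dem_ids[:n_dem])
        pool = [f for f in features if f not in set(members)]
        if size > n_dem:
            members += list(rng.choice(pool, size=size - n_dem, replace=False))
        rows.append({"pathway_id": pid, "category": category, "members": members})
    return pd.DataFrame(rows, columns=["pathway_id", "category", "members"])


def generate_mr_dataset(
    k: int,
    true_slope: float,
    pleiotropy_fraction: float = 0.0,
    pleiotropy_scale: float = 0.1,
    seed: int = 0,
    exposure_beta_range: tuple[float, float] = (0.05, 0.15),
    se_exposure: float = 0.005,
    se_outcome_range: tuple[float, float] = (0.01, 0.03),
) -> pd.DataFrame:
    """Simulate a harmonized two-sample MR instrument table.

    Valid instruments satisfy E[beta_outcome] = true_slope * beta_exposure;
    exactly ``round(k * pleiotropy_fraction)`` instruments additionally get a
    directional outcome offset drawn from N(pleiotropy_scale, pleiotropy_scale/2),
    emulating invalid (horizontally pleiotropic) variants.  Exposure betas are
    positive by construction (effect alleles pre-harmonized to the
    exposure-increasing allele).
    """
    if not 0 <= pleiotropy_fraction < 1:
        raise ValueError("pleiotropy_fraction must be in [0, 1)")
    if k < 1:
        raise ValueError("need at least one instrument")
    rng = substream(seed, "mr")
    bx_true = rng.uniform(*exposure_beta_range, size=k)
    sex = np.full(k, se_exposure)
    sey = rng.uniform(*se_outcome_range, size=k)
    n_invalid = int(round(k * pleiotropy_fraction))
    valid = np.ones(k, dtype=bool)
    if n_invalid:
        valid[rng.choice(k, size=n_invalid, replace=False)] = False
    offset = np.where(valid, 0.0, rng.normal(pleiotropy_scale, pleiotropy_scale / 2, size=k))
    bx = bx_true + rng.normal(0.0, sex)
    by = true_slope * bx_true + offset + rng.normal(0.0, sey)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i+1:06d}" for i in range(k)],
            "beta_exposure": bx,
            "se_exposure": sex,
            "beta_outcome": by,
            "se_outcome": sey,
            "valid_flag": valid,
        }
    )


def write_dataset(
    outdir: str | Path,
    views: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    truth: EffectTruth,
    pathway_sets: pd.DataFrame | None = None,
    mr_set: pd.DataFrame | None = None,
) -> None:
    """Write a simulated dataset: TSV matrices, GMT sets, truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(metadata, outdir / "metadata.tsv")
    for view, df in views.items():
        write_matrix(df, outdir / f"{view}.tsv")
    if pathway_sets is not None:
        write_gmt(pathway_sets, outdir / "pathways.gmt")
    if mr_set is not None:
        mr_set.to_csv(outdir / "mr_instruments.tsv", sep="\t", index=False)
    record = asdict(truth)
    record["factor_loadings_true"] = {v: W.tolist() for v, W in truth.factor_loadings_true.items()}
    record["factor_group_shift"] = truth.factor_group_shift.tolist()
    (outdir / "truth.json").write_text(json.dumps(record, indent=1))
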