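"""Over-representation analysis of differential metabolites on local pathway sets.

The test is the classic hypergeometric upper tail: with a background of N
tested metabolites, a pathway covering K of them and n selected metabolites
of which ``hits`` fall in the pathway,

    p = P(X >= hits),  X ~ Hypergeometric(N, K, n).

Pathways in the "disease" category are excluded before testing.  A pathway
passes when p < 0.05 and it has at least 3 hits.  Each passing pathway also
gets a weight (mean absolute latent-factor weight of its hit metabolites)
and a direction (sign of the mean log2 fold-change of its hits), which is
what downstream candidate selection keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = ["PathwayResult", "enrich", "weight_and_direction", "filter_and_rank", "results_frame"]


@dataclass
class PathwayResult:
    pathway_id: str
    category: str
    hits: list[str]
    n_hits: int
    size: int  # pathway members within the background
    p_value: float
    weight: float = float("nan")
    direction: str = ""
    passes: bool = False


def enrich(
    dems: Sequence[str],
    pathway_sets: pd.DataFrame,
    background: Sequence[str],
    alpha: float = 0.05,
    min_hits: int = 3,
    exclude_categories: Sequence[str] = ("disease",),
) -> list[PathwayResult]:
    """Hypergeometric enrichment of ``dems`` against each pathway.

    ``pathway_sets`` has columns pathway_id / category / members (GMT layout).
    Pathways are intersected with the background before testing; the DEM list
    must be a subset of the background.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    dems = set(dems)
    if not dems <= background:
        raise ValueError(f"DEMs outside the background: {sorted(dems - background)[:5]} ...")
    N, n = len(background), len(dems)
    results = []
    for _, row in pathway_sets.iterrows():
        if str(row["category"]).lower() in {c.lower() for c in exclude_categories}:
            continue
        members = set(row["members"]) & background
        hits = sorted(members & dems)
        K = len(members)
        p = float(stats.hypergeom.sf(len(hits) - 1, N, K, n)) if K else 1.0
        results.append(
            PathwayResult(
                pathway_id=row["pathway_id"],
                category=row["category"],
                hits=hits,
                n_hits=len(hits),
                size=K,
                p_value=min(p, 1.0),
                passes=p < alpha and len(hits) >= min_hits,
            )
        )
    return results


def weight_and_direction(
    result: PathwayResult,
    dem_weights: Mapping[str, float],
    dem_log2fc: Mapping[str, float],
    aggregate: str = "mean",
) -> PathwayResult:
    """Annotate a pathway with weight (aggregated |LF weight| of hits) and direction.

    Direction is "up" when the aggregated log2FC of the hits is positive,
    "down" when negative; an exact zero resolves to "up" with a warning
    (a genuinely balanced pathway).  ``aggregate`` may be mean, median or sum.
    """
    import warnings

    agg = {"mean": pd.Series.mean, "median": pd.Series.median, "sum": pd.Series.sum}[aggregate]
    if not result.hits:
        return replace(result, weight=0.0, direction="")
    w = agg(pd.Series([abs(dem_weights[h]) for h in result.hits]))
    fc = agg(pd.Series([dem_log2fc[h] for h in result.hits]))
    if fc == 0:
        warnings.warn(f"pathway {result.pathway_id}: mean log2FC exactly 0; direction tied, reporting 'up'")
    return replace(result, weight=float(w), direction="up" if fc >= 0 else "down")


def filter_and_rank(results: Sequence[PathwayResult]) -> list[PathwayResult]:
    """Passing pathways sorted by weight descending; ties by smaller p, then ID."""
    passing = [r for r in results if r.passes]
    return sorted(passing, key=lambda r: (-r.weight, r.p_value, r.pathway_id))


def results_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    """Tabular form (classification, name, hits, size, p, weight, direction, pass)."""
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "category": r.category,
                "n_hits": r.n_hits,
                "size": r.size,
                "p_value": r.p_value,
                "weight": r.weight,
                "direction": r.direction,
                "passes": r.passes,
            }
            for r in results
        ]
    )
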