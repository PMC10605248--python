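"""Top-x% overlap between two enrichment rankings, with a hypergeometric null.

Given two rankings of the same N-gene universe (say, genes ranked by
lens enrichment and by 3-D-culture enrichment), the sweep takes the top
K = floor(x * N) genes of each for a grid of fractions x, counts the
observed overlap O(x), and compares it with the independence
expectation E(x) = K^2 / N.  Significance comes from the exact
hypergeometric upper tail: if the two top sets were independent uniform
draws of sizes K_a and K_b from N genes, the overlap X follows
Hypergeometric(N, K_a, K_b).

Two tail conventions are exposed — ``greater`` returns P(X > O) and
``greater_or_equal`` returns P(X >= O) — because published overlap
p-values use either; ``greater`` is the default.  The tail is summed
exactly in log space (stable far beyond double-precision pmf underflow,
e.g. at p ~ 1e-22).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import InputError
from .expression import EnrichmentRanking

__all__ = [
    "OverlapSweep",
    "top_fraction_set",
    "hypergeom_overlap_pvalue",
    "overlap_sweep",
    "set_mean_trajectory",
    "default_x_grid",
]


def default_x_grid(step: float = 0.0025, x_max: float = 0.10) -> np.ndarray:
    """Fractions (0, x_max] in steps of ``step`` (default 0.25% up to 10%)."""
    n = int(round(x_max / step))
    return np.arange(1, n + 1) * step


@dataclass
class OverlapSweep:
    """Observed vs expected overlap of two rankings over a grid of fractions.

    ``table`` columns: x, set_size, observed, expected, p_value;
    ``intersections`` maps each x to the shared gene list at that x.
    """

    universe_size: int
    table: pd.DataFrame
    intersections: dict[float, list[str]]
    tail_convention: str = "greater"


def top_fraction_set(ranking: EnrichmentRanking, x: float) -> pd.Index:
    """The floor(x * N) most enriched genes of a ranking.

    Deterministic under the ranking's tie-break (score descending, then
    gene id).
    """
    if not 0.0 < x <= 1.0:
        raise InputError(f"fraction x must be in (0, 1], got {x}")
    k = int(np.floor(x * len(ranking.table)))
    return ranking.top_genes(k)


def _log_hypergeom_pmf(k: np.ndarray, n_total: int, k_a: int, k_b: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K_a, K_b)."""

    def logc(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return logc(k_a, k) + logc(n_total - k_a, k_b - k) - logc(n_total, k_b)


def hypergeom_overlap_pvalue(
    observed: int,
    k_a: int,
    k_b: int,
    n_total: int,
    convention: str = "greater",
) -> float:
    """Exact upper-tail probability of the overlap of two random subsets.

    ``greater`` gives P(X > observed); ``greater_or_equal`` gives
    P(X >= observed).  Summed exactly in log space.
    """
    if convention not in ("greater", "greater_or_equal"):
        raise InputError("convention must be 'greater' or 'greater_or_equal'")
    if not (0 <= observed <= min(k_a, k_b) <= n_total) or max(k_a, k_b) > n_total:
        raise InputError(
            f"inconsistent counts: observed={observed}, k_a={k_a}, k_b={k_b}, N={n_total}"
        )
    start = observed + 1 if convention == "greater" else observed
    lo = max(start, k_a + k_b - n_total)
    hi = min(k_a, k_b)
    if lo > hi:
        return 0.0
    if lo <= max(0, k_a + k_b - n_total):
        return 1.0
    k = np.arange(lo, hi + 1)
    return float(np.exp(logsumexp(_log_hypergeom_pmf(k, n_total, k_a, k_b))))


def overlap_sweep(
    ranking_a: EnrichmentRanking,
    ranking_b: EnrichmentRanking,
    x_grid: Sequence[float] | None = None,
    convention: str = "greater",
) -> OverlapSweep:
    """Observed/expected overlap and hypergeometric p over a fraction grid.

    Both rankings must cover the same gene universe.  E(x) = K^2/N is
    the independence expectation for equal set sizes K = floor(x * N).
    """
    genes_a = set(ranking_a.table.index)
    if genes_a != set(ranking_b.table.index):
        raise InputError("rankings cover different gene universes")
    n_total = len(genes_a)
    if x_grid is None:
        x_grid = default_x_grid()
    rows = []
    intersections: dict[float, list[str]] = {}
    ordered_a = ranking_a.table.sort_values("rank").index
    ordered_b = ranking_b.table.sort_values("rank").index
    set_b_ranks = {g: r for r, g in enumerate(ordered_b)}
    for x in x_grid:
        if not 0.0 < x <= 1.0:
            raise InputError(f"fraction x must be in (0, 1], got {x}")
        k = int(np.floor(x * n_total))
        top_a = ordered_a[:k]
        shared = sorted(g for g in top_a if set_b_ranks[g] < k)
        observed = len(shared)
        rows.append(
            {
                "x": x,
                "set_size": k,
                "observed": observed,
                "expected": k * k / n_total,
                "p_value": hypergeom_overlap_pvalue(observed, k, k, n_total, convention),
            }
        )
        intersections[float(x)] = shared
    return OverlapSweep(
        universe_size=n_total,
        table=pd.DataFrame(rows),
        intersections=intersections,
        tail_convention=convention,
    )


def set_mean_trajectory(
    gene_sets: Mapping[str, Iterable[str]],
    stage_table: pd.DataFrame,
) -> pd.DataFrame:
    """Mean +/- sd expression of each gene set across developmental stages.

    ``stage_table`` is gene x stage (columns ordered by stage).  Genes
    absent from the table are dropped with a warning column; the result
    has one row per (set, stage).
    """
    rows = []
    for name, genes in gene_sets.items():
        genes = list(genes)
        known = [g for g in genes if g in stage_table.index]
        unknown = sorted(set(genes) - set(known))
        if unknown:
            import warnings

            warnings.warn(
                f"set {name!r}: {len(unknown)} gene(s) not in stage table, dropped",
                stacklevel=2,
            )
        if not known:
            raise InputError(f"set {name!r} has no genes in the stage table")
        sub = stage_table.loc[known]
        for stage in stage_table.columns:
            col = sub[stage].to_numpy(dtype=float)
            rows.append(
                {
                    "set": name,
                    "stage": stage,
                    "mean": col.mean(),
                    "sd": col.std(ddof=1) if len(col) > 1 else 0.0,
                    "n_genes": len(known),
                    "n_dropped": len(unknown),
                }
            )
    return pd.DataFrame(rows)
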