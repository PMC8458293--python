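"""Rank-based two-dimensional annotation enrichment.

Given paired per-gene statistics — here transcriptome and proteome log2
fold changes — each annotation term (GO category, protein complex,
chromosome band, ...) gets a score per dimension,

    s = 2 * (mean rank of members - mean rank of non-members) / n,

bounded in [-1, 1]: +1 when the members occupy the top ranks, -1 when they
occupy the bottom.  Per-dimension two-sided Mann-Whitney p-values are
combined per term by a Bonferroni factor of 2 over the two dimensions and
Benjamini-Hochberg corrected across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationSet", "rank_values", "enrichment_2d"]


@dataclass(frozen=True)
class AnnotationSet:
    """A flat gene set: no ontology structure, just membership."""

    term_id: str
    name: str
    genes: frozenset[str]
    category: str = ""


def rank_values(values: np.ndarray | pd.Series) -> np.ndarray:
    """Ranks 1..n, average ranks for ties (a permutation statistic)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to rank")
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    return stats.rankdata(arr, method="average")


def _dimension_stats(ranks: np.ndarray, member: np.ndarray) -> tuple[float, float]:
    n = len(ranks)
    m = member.sum()
    score = 2.0 * (ranks[member].mean() - ranks[~member].mean()) / n
    # Mann-Whitney on the underlying values; ranks give the identical test
    p = stats.mannwhitneyu(ranks[member], ranks[~member], alternative="two-sided").pvalue
    return float(score), float(p)


def enrichment_2d(
    x: pd.Series,
    y: pd.Series,
    terms: list[AnnotationSet],
    min_size: int = 10,
    fdr_threshold: float = 0.02,
    filter_results: bool = True,
) -> pd.DataFrame:
    """Score every term in two dimensions over a shared gene universe.

    Genes missing either value are dropped before ranking; terms are
    intersected with the remaining universe and those below ``min_size``
    members (or with no non-members) are skipped.  Columns: ``term_id,
    name, category, n_members, score_x, score_y, p_x, p_y, p_value, fdr``.
    When ``filter_results`` is set, only terms with ``fdr < fdr_threshold``
    are returned.
    """
    df = pd.concat({"x": x, "y": y}, axis=1).dropna()
    if len(df) < 2:
        raise ValueError("need at least two genes with both values")
    genes = df.index.to_numpy()
    rx = rank_values(df["x"].to_numpy())
    ry = rank_values(df["y"].to_numpy())

    rows = []
    for term in terms:
        member = np.isin(genes, list(term.genes))
        m = int(member.sum())
        if m < min_size:
            continue
        if m == len(genes):
            raise ValueError(f"term {term.term_id!r} covers the whole universe")
        sx, px = _dimension_stats(rx, member)
        sy, py = _dimension_stats(ry, member)
        p = min(1.0, 2.0 * min(px, py))
        rows.append((term.term_id, term.name, term.category, m, sx, sy, px, py, p))

    result = pd.DataFrame(
        rows,
        columns=["term_id", "name", "category", "n_members",
                 "score_x", "score_y", "p_x", "p_y", "p_value"],
    )
    if len(result) == 0:
        import warnings

        warnings.warn("no term passed the size filter; empty result", stacklevel=2)
        result["fdr"] = pd.Series(dtype=float)
        return result
    result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result = result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    if filter_results:
        result = result[result["fdr"] < fdr_threshold].reset_index(drop=True)
    return result
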