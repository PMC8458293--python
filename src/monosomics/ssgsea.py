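"""Single-sample gene set enrichment (ssGSEA) and somy-group comparison.

For one sample, genes are ranked by expression in decreasing order and the
enrichment score is the running-sum difference between a weighted
empirical distribution of the gene-set members and a uniform distribution
of the non-members:

    ES = sum_j [ P_in(j) - P_out(j) ],

where P_in accumulates |expression|^alpha over member positions
(normalized to 1) and P_out accumulates 1/(n - n_set) over non-member
positions.  A lower score means the set's genes are under-expressed in
that sample relative to the rest of the transcriptome.  Group differences
in scores are assessed with one-sided Wilcoxon rank-sum tests, exact for
small groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SsgseaParams", "ssgsea_score", "score_matrix", "compare_groups"]

#: Largest per-group size for which the rank-sum null is enumerated exactly.
EXACT_MAX_N = 12


@dataclass(frozen=True)
class SsgseaParams:
    """alpha: rank-weighting exponent; normalize: divide each gene set's
    scores by their range across samples."""

    alpha: float = 0.75
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def ssgsea_score(
    expression: pd.Series,
    gene_set: set[str] | frozenset[str],
    params: SsgseaParams | None = None,
) -> float:
    """Enrichment score of one gene set in one sample.

    Ties in expression are broken by gene id so the ranking (and hence the
    score) is deterministic across runs.  Zero-variance samples are
    rejected: every gene at the same value carries no ranking information.
    """
    params = params or SsgseaParams()
    expr = expression.dropna()
    if expr.nunique() <= 1:
        raise ValueError("expression vector has no variance; cannot rank")
    members = frozenset(gene_set) & set(expr.index)
    if not members:
        raise ValueError("gene set does not intersect the expression universe")
    if len(members) == len(expr):
        raise ValueError("gene set covers the whole universe; no background")

    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    values = expr.loc[order].to_numpy(dtype=float)
    in_set = np.array([g in members for g in order])

    weights = np.where(in_set, np.abs(values) ** params.alpha, 0.0)
    total = weights.sum()
    if total == 0:
        # all member expression values are exactly zero: fall back to
        # uniform in-set weights (alpha has nothing to weight by)
        weights = in_set.astype(float)
        total = weights.sum()
    p_in = np.cumsum(weights) / total
    p_out = np.cumsum(~in_set) / (len(order) - len(members))
    return float(np.sum(p_in - p_out))


def score_matrix(
    expression: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Sample x term matrix of enrichment scores.

    ``expression`` is genes x samples.  With ``normalize`` each term's
    scores are divided by their (max - min) across samples, so every term
    spans a unit range when not constant.
    """
    params = params or SsgseaParams()
    if params.normalize and expression.shape[1] < 2:
        raise ValueError("normalization needs at least two samples")
    scores = pd.DataFrame(
        {
            term: [
                ssgsea_score(expression[sample], members, params)
                for sample in expression.columns
            ]
            for term, members in gene_sets.items()
        },
        index=pd.Index(expression.columns, name="sample"),
    )
    if params.normalize:
        span = scores.max(axis=0) - scores.min(axis=0)
        span = span.replace(0.0, 1.0)  # constant term: leave scores as-is
        scores = scores / span
    return scores


def compare_groups(
    scores_a,
    scores_b,
    alternative: str = "less",
) -> float:
    """One-sided Wilcoxon rank-sum p-value for group A versus group B.

    ``alternative="less"`` tests whether A's scores tend to be lower than
    B's.  The exact null distribution is used when both groups have at
    most 12 observations and there are no cross-group ties; larger groups
    use the normal approximation with continuity correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return float(res.pvalue)
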