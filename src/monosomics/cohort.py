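"""Ploidy-based cohort stratification and TP53-alteration enrichment.

Tumor samples (whole-genome-doubled tumors removed upstream) are split by
ABSOLUTE-style ploidy into Monosomy / Disomy / Polysomy with two
thresholds (defaults 1.80 and 2.19; ploidy exactly 2 is always disomic).
Because no clear minima separate the strata, the thresholds are swept over
1.66-1.90 and 2.0-2.27 to check that conclusions do not hinge on a
particular pair.  TP53-alteration enrichment in monosomic samples is
tested with one-sided exact hypergeometric tests (mid-p by default,
classic Fisher optionally); per-cancer-type differences in a score column
(e.g. the TP53 classifier score) use one-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ssgsea import compare_groups

__all__ = [
    "SomyThresholds",
    "EnrichmentResult",
    "classify_somy",
    "tp53_enrichment",
    "threshold_sweep",
    "per_type_score_comparison",
    "aneuploidy_confound_summary",
]

SOMY_CLASSES = ("Monosomy", "Disomy", "Polysomy")


@dataclass(frozen=True)
class SomyThresholds:
    """Ploidy boundaries; samples at a boundary are assigned to Disomy."""

    t_mono: float = 1.80
    t_poly: float = 2.19
    sweep_mono: tuple[float, float] = (1.66, 1.90)
    sweep_poly: tuple[float, float] = (2.0, 2.27)

    def __post_init__(self) -> None:
        if not self.t_mono < self.t_poly:
            raise ValueError("t_mono must be below t_poly")
        if self.sweep_mono[0] > self.sweep_mono[1] or self.sweep_poly[0] > self.sweep_poly[1]:
            raise ValueError("sweep ranges must be ordered")


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: rows (monosomy, other), cols (altered, not)
    odds_ratio: float
    p_value: float
    comparison: str


def classify_somy(ploidy, thresholds: SomyThresholds | None = None) -> pd.Series:
    """Monosomy below t_mono, Polysomy above t_poly, Disomy in between.

    Boundary equality goes to Disomy (a ploidy of exactly 2 must be
    disomic).  Raises on non-positive ploidy values.
    """
    thresholds = thresholds or SomyThresholds()
    values = pd.Series(ploidy, dtype=float)
    if (values <= 0).any():
        raise ValueError("ploidy values must be positive")
    classes = np.where(
        values < thresholds.t_mono,
        "Monosomy",
        np.where(values > thresholds.t_poly, "Polysomy", "Disomy"),
    )
    return pd.Series(classes, index=values.index, name="somy")


def tp53_enrichment(
    somy: pd.Series,
    altered,
    comparison: str = "monosomy_vs_disomy",
    method: str = "midp",
) -> EnrichmentResult:
    """One-sided exact test for alteration excess in Monosomy.

    ``comparison`` is either ``monosomy_vs_disomy`` (polysomic samples
    dropped) or ``monosomy_vs_rest``.  The p-value comes from the
    hypergeometric null of the 2x2 table: ``method="fisher"`` is the
    classic Fisher tail P(X >= x); the default ``method="midp"`` is the
    mid-p variant P(X > x) + P(X = x)/2, which removes most of the
    conditional test's conservatism and keeps the realized type-I error
    near the nominal level.  The odds ratio is the sample (unconditional)
    odds ratio, with a Haldane correction of 0.5 added to every cell when
    any cell is zero.
    """
    somy = pd.Series(somy)
    altered = pd.Series(np.asarray(altered, dtype=bool), index=somy.index)
    if comparison == "monosomy_vs_disomy":
        keep = somy.isin(["Monosomy", "Disomy"])
        somy, altered = somy[keep], altered[keep]
    elif comparison != "monosomy_vs_rest":
        raise ValueError(f"unknown comparison {comparison!r}")
    is_mono = somy == "Monosomy"
    if is_mono.all() or (~is_mono).all():
        raise ValueError("both somy groups must be non-empty")
    table = np.array(
        [
            [int((is_mono & altered).sum()), int((is_mono & ~altered).sum())],
            [int((~is_mono & altered).sum()), int((~is_mono & ~altered).sum())],
        ]
    )
    if altered.all() or (~altered).all():
        raise ValueError("alteration flag is constant; enrichment undefined")
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    if method == "fisher":
        p = stats.fisher_exact(table, alternative="greater")[1]
    elif method == "midp":
        a = table[0, 0]
        null = stats.hypergeom(table.sum(), table[0].sum(), table[:, 0].sum())
        p = null.sf(a) + 0.5 * null.pmf(a)
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(table=table, odds_ratio=float(odds_ratio), p_value=float(p),
                            comparison=comparison)


def threshold_sweep(
    ploidy,
    altered,
    thresholds: SomyThresholds | None = None,
    n_mono: int = 5,
    n_poly: int = 5,
    alpha: float = 0.05,
    comparison: str = "monosomy_vs_disomy",
    method: str = "midp",
) -> tuple[pd.DataFrame, bool]:
    """Evaluate the TP53 enrichment at every point of a threshold grid.

    The grid is the Cartesian product of ``n_mono`` evenly spaced
    monosomy/disomy boundaries and ``n_poly`` disomy/polysomy boundaries
    over the sweep ranges.  Returns the per-point results and a "robust"
    flag: significant at ``alpha`` at every grid point.
    """
    thresholds = thresholds or SomyThresholds()
    mono_grid = np.linspace(*thresholds.sweep_mono, n_mono)
    poly_grid = np.linspace(*thresholds.sweep_poly, n_poly)
    rows = []
    for t_mono, t_poly in itertools.product(mono_grid, poly_grid):
        thr = SomyThresholds(t_mono=float(t_mono), t_poly=float(t_poly),
                             sweep_mono=thresholds.sweep_mono, sweep_poly=thresholds.sweep_poly)
        somy = classify_somy(ploidy, thr)
        res = tp53_enrichment(somy, altered, comparison=comparison, method=method)
        rows.append((t_mono, t_poly, res.odds_ratio, res.p_value, res.p_value < alpha))
    table = pd.DataFrame(rows, columns=["t_mono", "t_poly", "odds_ratio", "p_value", "significant"])
    robust = bool(table["significant"].all())
    return table, robust


def per_type_score_comparison(
    cohort: pd.DataFrame,
    score_column: str = "tp53_score",
    comparisons: tuple[tuple[str, str], ...] = (("Monosomy", "Disomy"), ("Polysomy", "Disomy")),
    alternative: str = "greater",
    min_n: int = 3,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-sided rank-sum test per cancer type for each somy comparison.

    For ``alternative="greater"`` the test asks whether the first class of
    the pair (e.g. Monosomy) has higher scores than the second (Disomy)
    within each cancer type.  Types where either group has fewer than
    ``min_n`` samples are reported ``untested``.  BH correction across
    types is available but off by default; the per-type significance
    counts are reported uncorrected.
    """
    if "somy" not in cohort.columns:
        raise ValueError("cohort table needs a 'somy' column; run classify_somy first")
    rows = []
    for (hi, lo), (ctype, sub) in itertools.product(
        comparisons, cohort.groupby("cancer_type", sort=True)
    ):
        a = sub.loc[sub["somy"] == hi, score_column].to_numpy()
        b = sub.loc[sub["somy"] == lo, score_column].to_numpy()
        if len(a) < min_n or len(b) < min_n:
            rows.append((ctype, f"{hi}_vs_{lo}", len(a), len(b), np.nan, "untested"))
            continue
        p = compare_groups(a, b, alternative=alternative)
        rows.append((ctype, f"{hi}_vs_{lo}", len(a), len(b), p, "tested"))
    result = pd.DataFrame(
        rows, columns=["cancer_type", "comparison", "n_first", "n_second", "p_value", "status"]
    )
    tested = result["status"] == "tested"
    pcol = result["p_value"].copy()
    if bh_correct and tested.any():
        pcol.loc[tested] = multipletests(result.loc[tested, "p_value"], method="fdr_bh")[1]
    result["p_adjusted"] = pcol
    result["significant"] = tested & (result["p_adjusted"] < alpha)
    return result


def aneuploidy_confound_summary(cohort: pd.DataFrame) -> dict:
    """Check whether TP53 enrichment in Monosomy is an SCNA-burden artifact.

    Reports, per somy class, median and IQR of the aneuploidy score and
    the TP53 alteration rate; compares the aneuploidy score between
    Monosomy and Polysomy with a two-sided rank-sum test (comparable
    burden expected) and the alteration rates with a one-sided Fisher test
    (excess in Monosomy expected).
    """
    for col in ("somy", "aneuploidy_score", "tp53_altered"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing column {col!r}")
    per_class = {}
    for cls, sub in cohort.groupby("somy", sort=True):
        scores = sub["aneuploidy_score"].astype(float)
        per_class[cls] = {
            "n": int(len(sub)),
            "aneuploidy_median": float(scores.median()),
            "aneuploidy_iqr": float(scores.quantile(0.75) - scores.quantile(0.25)),
            "tp53_alteration_rate": float(sub["tp53_altered"].mean()),
        }
    mono = cohort[cohort["somy"] == "Monosomy"]
    poly = cohort[cohort["somy"] == "Polysomy"]
    if len(mono) == 0 or len(poly) == 0:
        raise ValueError("need both Monosomy and Polysomy samples")
    aneu_p = float(
        stats.mannwhitneyu(
            mono["aneuploidy_score"], poly["aneuploidy_score"], alternative="two-sided"
        ).pvalue
    )
    table = np.array(
        [
            [int(mono["tp53_altered"].sum()), int((~mono["tp53_altered"].astype(bool)).sum())],
            [int(poly["tp53_altered"].sum()), int((~poly["tp53_altered"].astype(bool)).sum())],
        ]
    )
    alt_p = float(stats.fisher_exact(table, alternative="greater")[1])
    return {
        "per_class": per_class,
        "aneuploidy_mono_vs_poly_p": aneu_p,
        "alteration_mono_vs_poly_p": alt_p,
        "alteration_rate_difference": per_class["Monosomy"]["tp53_alteration_rate"]
        - per_class["Polysomy"]["tp53_alteration_rate"],
    }
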