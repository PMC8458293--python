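"""Per-gene copy-number signal from binned genome coverage.

Low-pass whole-genome sequencing yields a coverage value per fixed-size
genomic bin.  Genes are mapped onto bins by interval overlap, each gene is
summarized by the median of its bins' log2 coverage, and the per-gene
values are centered on the genome-wide median so a disomic gene sits near 0
and a monosomic gene near log2(1/2) = -1.  A simple per-chromosome median
threshold then calls whole-chromosome losses and gains.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SomyCall",
    "assign_bins_to_genes",
    "per_gene_log2_median",
    "center_coverage",
    "call_somy_per_chromosome",
]

#: Loss/gain cutoffs on the centered log2 scale: midpoints between the
#: expected log2 ratios of adjacent copy states (1 vs 2 copies: -1 and 0;
#: 3 vs 2 copies: log2(3/2) ~ 0.585 and 0).
DEFAULT_LOSS_CUTOFF = -0.5
DEFAULT_GAIN_CUTOFF = 0.42


@dataclass(frozen=True)
class SomyCall:
    chromosome: str
    median_log2: float
    call: str  # "loss" | "neutral" | "gain" | "uncallable"
    n_genes: int
    loss_cutoff: float
    gain_cutoff: float


def _check_bins(bins: pd.DataFrame) -> None:
    required = {"chromosome", "start", "end", "coverage"}
    missing = required - set(bins.columns)
    if missing:
        raise ValueError(f"bins table missing columns: {sorted(missing)}")
    if (bins["coverage"] < 0).any():
        raise ValueError("bin coverage must be non-negative")


def assign_bins_to_genes(bins: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign each bin to every gene whose half-open interval it overlaps.

    Overlap of >= 1 bp counts; a bin straddling two genes is assigned to
    both.  Genes with no overlapping bin are dropped (only genes with at
    least one mapped coverage are analyzed downstream).  Returns a long
    frame with columns ``gene, chromosome, coverage``.

    Raises if the annotation references chromosomes absent from the bins.
    """
    _check_bins(bins)
    gene_chroms = set(annotation["chromosome"])
    bin_chroms = set(bins["chromosome"])
    offenders = sorted(gene_chroms - bin_chroms)
    if offenders:
        raise ValueError(f"annotation chromosomes have no coverage bins: {offenders}")

    out_gene, out_chrom, out_cov = [], [], []
    for chrom, gsub in annotation.groupby("chromosome", sort=True):
        bsub = bins[bins["chromosome"] == chrom].sort_values("start")
        starts = bsub["start"].to_numpy()
        ends = bsub["end"].to_numpy()
        cov = bsub["coverage"].to_numpy()
        # bins are sorted and non-overlapping: overlapping bins of [s, e)
        # are those with end > s and start < e
        lo = np.searchsorted(ends, gsub["start"].to_numpy(), side="right")
        hi = np.searchsorted(starts, gsub["end"].to_numpy(), side="left")
        for gene, i, j in zip(gsub["gene"], lo, hi):
            if j > i:
                out_gene.extend([gene] * (j - i))
                out_chrom.extend([chrom] * (j - i))
                out_cov.extend(cov[i:j])
    return pd.DataFrame({"gene": out_gene, "chromosome": out_chrom, "coverage": out_cov})


def per_gene_log2_median(gene_bins: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Median over each gene's bins of log2(coverage + pseudocount).

    The default pseudocount of 1 keeps zero-coverage bins finite
    (log2(1) = 0).  Returns columns ``gene, chromosome, log2_median,
    n_bins``.
    """
    if (gene_bins["coverage"] < 0).any():
        raise ValueError("coverage values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (gene_bins["coverage"] == 0).any():
        raise ValueError("zero coverage with pseudocount 0 would give -inf")
    df = gene_bins.copy()
    df["log2cov"] = np.log2(df["coverage"] + pseudocount)
    agg = (
        df.groupby(["gene", "chromosome"], sort=False)["log2cov"]
        .agg(log2_median="median", n_bins="size")
        .reset_index()
    )
    return agg.rename(columns={"log2cov": "log2_median"})


def center_coverage(gene_log2: pd.DataFrame) -> pd.DataFrame:
    """Subtract the across-gene median so the population centers on 0.

    Input and output carry a ``log2_median`` column; the output adds
    ``log2_centered``.  Centering is idempotent and removes any global
    sequencing-depth scale.
    """
    if len(gene_log2) == 0:
        raise ValueError("cannot center an empty gene set")
    out = gene_log2.copy()
    out["log2_centered"] = out["log2_median"] - out["log2_median"].median()
    return out


def call_somy_per_chromosome(
    gene_coverage: pd.DataFrame,
    loss_cutoff: float = DEFAULT_LOSS_CUTOFF,
    gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
    min_genes: int = 20,
) -> list[SomyCall]:
    """Call loss/neutral/gain per chromosome from centered per-gene values.

    The per-chromosome median of ``log2_centered`` is compared to the
    cutoffs; chromosomes with fewer than ``min_genes`` measured genes are
    flagged ``uncallable`` rather than guessed.
    """
    if loss_cutoff >= gain_cutoff:
        raise ValueError("loss_cutoff must be below gain_cutoff")
    if "log2_centered" not in gene_coverage.columns:
        raise ValueError("expected centered values; run center_coverage first")
    calls = []
    for chrom, sub in gene_coverage.groupby("chromosome", sort=True):
        med = float(sub["log2_centered"].median())
        n = len(sub)
        if n < min_genes:
            call = "uncallable"
        elif med <= loss_cutoff:
            call = "loss"
        elif med >= gain_cutoff:
            call = "gain"
        else:
            call = "neutral"
        calls.append(SomyCall(chrom, med, call, n, loss_cutoff, gain_cutoff))
    return calls
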