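"""Dosage response of monosomic genes at mRNA and protein level.

Losing one of two chromosome copies halves the template for every gene on
the monosome, so under pure dosage scaling the log2 fold change versus the
diploid parental line should be -1.  This module quantifies how far the
data deviate from that expectation: median-shift normalization computed
without the monosomic genes, replicate-median fold changes, per-chromosome
median profiles, a four-way buffering classification at a -0.5 cutoff,
pooled medians across cell lines, protein-complex (CORUM) membership
shifts, and proteins extremely deregulated in several cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import BUFFERING_CATEGORIES, ExpressionMatrix

__all__ = [
    "BufferingParams",
    "BufferingResult",
    "median_shift_normalize",
    "median_shift_normalize_pair",
    "log2_fold_change",
    "build_fold_change_table",
    "chromosome_median_profile",
    "classify_buffering",
    "pooled_monosome_medians",
    "complex_membership_shift",
    "shared_extreme_proteins",
]

#: Fixed histogram grid for reproducible density summaries (log2FC axis).
DENSITY_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class BufferingParams:
    """Cutoff for the four buffering categories.

    ``cutoff`` separates "down" (un-buffered, below) from "up" (buffered,
    above) per modality.  Values exactly at the cutoff go to the "down"
    side by default, which is conservative for buffering claims; set
    ``ties="up"`` to flip.
    """

    cutoff: float = -0.5
    expected_monosome_log2fc: float = -1.0
    ties: str = "down"

    def __post_init__(self) -> None:
        if not (self.expected_monosome_log2fc < self.cutoff < 0.0):
            raise ValueError("cutoff must lie strictly between the expected monosome log2FC and 0")
        if self.ties not in ("down", "up"):
            raise ValueError("ties must be 'down' or 'up'")


@dataclass
class BufferingResult:
    categories: pd.Series  # gene -> category, matched monosomic genes only
    fractions: dict[str, float]
    medians: dict[str, float]  # monosome/disome x mRNA/protein medians
    n_matched: int


def median_shift_normalize(
    matrix: ExpressionMatrix, exclude: set[str] | frozenset[str]
) -> ExpressionMatrix:
    """Shift replicates to a common median computed without excluded genes.

    Each replicate's median over the non-excluded (disomic) genes is moved
    to the grand median of those per-replicate medians by an additive
    constant; excluded (monosomic) genes are shifted by the same constant,
    so a genuine dosage deficit is not normalized away.
    """
    exclude = set(exclude)
    keep = ~matrix.data.index.isin(exclude)
    if not keep.any():
        raise ValueError("exclusion set covers every gene; nothing to normalize against")
    rep_medians = matrix.data.loc[keep].median(axis=0)
    grand = rep_medians.median()
    shifted = matrix.data + (grand - rep_medians)
    return ExpressionMatrix(matrix.modality, matrix.cell_line, shifted)


def median_shift_normalize_pair(
    sample: ExpressionMatrix,
    parental: ExpressionMatrix,
    exclude: set[str] | frozenset[str],
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Normalize the monosomic and parental replicates to one common median.

    All replicates of both lines are shifted to the same non-excluded-gene
    median (the grand median over all six replicates, say).  Normalizing
    the two matrices separately would leave an arbitrary offset between
    them that propagates into every fold change; anchoring them jointly
    pins the disomic fold-change distribution at 0.
    """
    shared = sample.genes.intersection(parental.genes)
    if len(shared) == 0:
        raise ValueError("sample and parental share no genes")
    combined = pd.concat(
        {"sample": sample.data.loc[shared], "parental": parental.data.loc[shared]}, axis=1
    )
    joint = ExpressionMatrix(sample.modality, "combined", combined)
    normalized = median_shift_normalize(joint, exclude)
    s = ExpressionMatrix(sample.modality, sample.cell_line, normalized.data["sample"])
    p = ExpressionMatrix(parental.modality, parental.cell_line, normalized.data["parental"])
    return s, p


def log2_fold_change(sample: ExpressionMatrix, parental: ExpressionMatrix) -> pd.Series:
    """Replicate-median log2 fold change of sample over parental, per gene.

    FC = median over sample replicates - median over parental replicates.
    Genes present in only one matrix get NaN; the result covers the union
    of both gene universes.
    """
    shared = sample.genes.intersection(parental.genes)
    if len(shared) == 0:
        raise ValueError("sample and parental share no genes")
    s_med = sample.data.median(axis=1)
    p_med = parental.data.median(axis=1)
    fc = s_med.sub(p_med, fill_value=np.nan)
    fc = fc.reindex(sample.genes.union(parental.genes))
    fc.name = f"{sample.modality}_log2fc"
    return fc


def build_fold_change_table(
    mrna_fc: pd.Series | None,
    protein_fc: pd.Series | None,
    annotation: pd.DataFrame,
    monosome: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Join modalities with gene annotation into the central analysis table.

    Columns: ``gene, chromosome, mrna_log2fc, protein_log2fc, monosomic,
    corum``.  ``monosomic`` derives from the declared monosome chromosome
    set.  Genes with both modalities quantified form the "matched" subset
    used for joint analyses.
    """
    if mrna_fc is None and protein_fc is None:
        raise ValueError("at least one modality required")
    ann = annotation.set_index("gene")
    genes = ann.index
    table = pd.DataFrame(index=genes)
    table["chromosome"] = ann["chromosome"]
    table["mrna_log2fc"] = mrna_fc.reindex(genes) if mrna_fc is not None else np.nan
    table["protein_log2fc"] = protein_fc.reindex(genes) if protein_fc is not None else np.nan
    table["monosomic"] = table["chromosome"].isin(set(monosome))
    table["corum"] = ann["is_corum"] if "is_corum" in ann.columns else False
    return table.reset_index().rename(columns={"index": "gene"})


def matched_subset(fc: pd.DataFrame) -> pd.DataFrame:
    """Genes with both transcript and protein quantified."""
    return fc.dropna(subset=["mrna_log2fc", "protein_log2fc"])


def chromosome_median_profile(fc: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome median log2FC per modality, on available values."""
    return (
        fc.groupby("chromosome", sort=True)[["mrna_log2fc", "protein_log2fc"]]
        .median()
        .reset_index()
    )


def _category(m: float, p: float, cutoff: float, ties: str) -> str:
    if ties == "down":
        m_up, p_up = m > cutoff, p > cutoff
    else:
        m_up, p_up = m >= cutoff, p >= cutoff
    return f"{'up' if m_up else 'down'};{'up' if p_up else 'down'}"


def classify_buffering(fc: pd.DataFrame, params: BufferingParams | None = None) -> BufferingResult:
    """Assign matched monosomic genes to the four buffering categories.

    up;up: both modalities above the cutoff (transcriptionally adjusted);
    down;up: transcript down, protein buffered posttranscriptionally;
    down;down: neither buffered; up;down: transcript buffered, protein
    down.  Fractions are reported over the matched monosomic gene set.
    """
    params = params or BufferingParams()
    matched = matched_subset(fc)
    mono = matched[matched["monosomic"]]
    if len(mono) == 0:
        raise ValueError("no matched monosomic genes to classify")
    cats = pd.Series(
        [
            _category(m, p, params.cutoff, params.ties)
            for m, p in zip(mono["mrna_log2fc"], mono["protein_log2fc"])
        ],
        index=pd.Index(mono["gene"], name="gene"),
        name="category",
    )
    n = len(cats)
    fractions = {c: float((cats == c).sum()) / n for c in BUFFERING_CATEGORIES}
    diso = matched[~matched["monosomic"]]
    medians = {
        "monosome_mrna": float(mono["mrna_log2fc"].median()),
        "monosome_protein": float(mono["protein_log2fc"].median()),
        "disome_mrna": float(diso["mrna_log2fc"].median()) if len(diso) else np.nan,
        "disome_protein": float(diso["protein_log2fc"].median()) if len(diso) else np.nan,
    }
    return BufferingResult(categories=cats, fractions=fractions, medians=medians, n_matched=n)


def pooled_monosome_medians(
    fc_tables: list[pd.DataFrame],
    exclude_chromosomes: set[str] = frozenset({"chrX", "X"}),
) -> tuple[float, float]:
    """Pool matched monosomic genes across cell lines; return medians.

    Pooling is record-level: a gene monosomic in two cell lines contributes
    two records.  Chromosome X is excluded by default because X loss is
    masked by X inactivation.  Returns (mRNA median, protein median).
    """
    if len(fc_tables) == 0:
        raise ValueError("no fold-change tables supplied")
    records = []
    for fc in fc_tables:
        sub = matched_subset(fc)
        sub = sub[sub["monosomic"] & ~sub["chromosome"].isin(set(exclude_chromosomes))]
        records.append(sub[["mrna_log2fc", "protein_log2fc"]])
    pooled = pd.concat(records, axis=0, ignore_index=True)
    if len(pooled) == 0:
        raise ValueError("no monosomic matched genes after chromosome exclusion")
    return float(pooled["mrna_log2fc"].median()), float(pooled["protein_log2fc"].median())


def _hist(values: pd.Series) -> list[int]:
    counts, _ = np.histogram(values.dropna(), bins=DENSITY_GRID)
    return counts.astype(int).tolist()


def complex_membership_shift(fc: pd.DataFrame) -> dict:
    """Protein FC medians for complex-subunit (CORUM) vs other proteins.

    Computed separately on monosomic and disomic genes; the density
    summaries are histogram counts on a fixed grid (width 0.1 log2 units
    over [-3, 3]) so they are reproducible across runs.
    """
    matched = matched_subset(fc)
    out: dict = {"grid": DENSITY_GRID.tolist()}
    for name, sub in (("monosome", matched[matched["monosomic"]]),
                      ("disome", matched[~matched["monosomic"]])):
        corum = sub[sub["corum"].astype(bool)]
        other = sub[~sub["corum"].astype(bool)]
        if len(corum) == 0 or len(other) == 0:
            raise ValueError(f"{name}: need both CORUM and non-CORUM proteins")
        out[name] = {
            "corum_median": float(corum["protein_log2fc"].median()),
            "non_corum_median": float(other["protein_log2fc"].median()),
            "corum_hist": _hist(corum["protein_log2fc"]),
            "non_corum_hist": _hist(other["protein_log2fc"]),
            "n_corum": len(corum),
            "n_non_corum": len(other),
        }
    return out


def shared_extreme_proteins(
    protein_fc_by_line: dict[str, pd.Series],
    threshold: float = 1.5,
    min_lines: int = 2,
) -> tuple[list[str], list[str]]:
    """Proteins extremely deregulated in the same direction in >= min_lines.

    "Up" requires FC strictly greater than ``threshold`` in at least
    ``min_lines`` cell lines; "down" requires FC strictly below
    ``-threshold``.  The direction must agree across the counted lines, so
    a protein up in one line and down in another appears in neither list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(protein_fc_by_line) < min_lines:
        raise ValueError(f"need at least {min_lines} cell lines")
    wide = pd.DataFrame(protein_fc_by_line)
    n_up = (wide > threshold).sum(axis=1)
    n_down = (wide < -threshold).sum(axis=1)
    up = sorted(wide.index[n_up >= min_lines])
    down = sorted(wide.index[n_down >= min_lines])
    return up, down
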