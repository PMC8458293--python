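"""Readers and writers for the plain-text formats the pipeline exchanges.

BED-style interval tables (0-based half-open), TSV expression matrices
(genes x replicates, log2), GMT gene-set files, two-column CSV polysome
traces and TSV cohort tables.  Floats are written with a fixed format so
repeated runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .simulate import ExpressionMatrix, PolysomeProfile

FLOAT_FMT = "%.6g"


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    bins[["chromosome", "start", "end", "coverage"]].to_csv(
        path, sep="\t", header=False, index=False, float_format=FLOAT_FMT
    )


def read_bins_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start", "end", "coverage"]
    )


def write_gene_bed(annotation: pd.DataFrame, path) -> None:
    """BED6+2: chrom, start, end, name, score, strand, is_rpg, is_corum."""
    out = annotation.copy()
    df = pd.DataFrame(
        {
            "chromosome": out["chromosome"],
            "start": out["start"],
            "end": out["end"],
            "gene": out["gene"],
            "score": 0,
            "strand": ".",
            "is_rpg": out.get("is_rpg", False).astype(int),
            "is_corum": out.get("is_corum", False).astype(int),
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "gene", "score", "strand", "is_rpg", "is_corum"],
    )
    df["is_rpg"] = df["is_rpg"].astype(bool)
    df["is_corum"] = df["is_corum"].astype(bool)
    return df[["gene", "chromosome", "start", "end", "is_rpg", "is_corum"]]


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_expression_tsv(path, modality: str, cell_line: str) -> ExpressionMatrix:
    data = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionMatrix(modality, cell_line, data)


def write_gmt(gene_sets: dict[str, list[str]] | list[AnnotationSet], path) -> None:
    lines = []
    if isinstance(gene_sets, dict):
        for term, genes in gene_sets.items():
            lines.append("\t".join([term, term, *sorted(genes)]))
    else:
        for term in gene_sets:
            lines.append("\t".join([term.term_id, term.name or term.term_id,
                                    *sorted(term.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> list[AnnotationSet]:
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        terms.append(AnnotationSet(term_id=fields[0], name=fields[1],
                                   genes=frozenset(fields[2:])))
    return terms


def write_trace_csv(profile: PolysomeProfile, path) -> None:
    pd.DataFrame({"position": profile.positions, "absorbance": profile.absorbance}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_trace_csv(path, label: str = "") -> PolysomeProfile:
    df = pd.read_csv(path)
    return PolysomeProfile(df["position"].to_numpy(), df["absorbance"].to_numpy(),
                           label=label or Path(path).stem)


def write_cohort_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "tp53_altered" in df.columns:
        df["tp53_altered"] = df["tp53_altered"].astype(bool)
    return df


def write_fold_change_tsv(fc: pd.DataFrame, path) -> None:
    fc.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_fold_change_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
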