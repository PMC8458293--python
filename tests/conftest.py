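import numpy as np
import pandas as pd
import pytest

from monosomics.dosage import (build_fold_change_table, log2_fold_change,
                               median_shift_normalize_pair)
from monosomics.simulate import (BufferingMixture, SimGenome, simulate_annotation,
                                 simulate_expression)


@pytest.fixture(scope="session")
def small_annotation():
    genome = SimGenome(
        chromosomes=(("chr1", 1_000_000), ("chr2", 1_000_000), ("chr3", 1_000_000)),
        genes_per_chromosome=100,
        seed=42,
    )
    return simulate_annotation(genome)


def make_fold_change_table(annotation, monosome, mix=None, seed=0):
    """Simulate paired expression and run normalization + fold changes."""
    mix = mix or BufferingMixture()
    sim = simulate_expression(annotation, monosome, mix, seed=seed)
    mono_genes = set(annotation.loc[annotation["chromosome"].isin(monosome), "gene"])
    fcs = {}
    for modality, sample, parental in (
        ("mrna", sim.mrna, sim.mrna_parental),
        ("protein", sim.protein, sim.protein_parental),
    ):
        s, p = median_shift_normalize_pair(sample, parental, mono_genes)
        fcs[modality] = log2_fold_change(s, p)
    fc = build_fold_change_table(fcs["mrna"], fcs["protein"], annotation, monosome)
    return fc, sim


@pytest.fixture()
def fc_table(small_annotation):
    fc, sim = make_fold_change_table(small_annotation, {"chr2"}, seed=3)
    return fc


def expression_matrix(values: dict, modality="mRNA", line="test"):
    """Build an ExpressionMatrix from {gene: [rep values]}."""
    from monosomics.simulate import ExpressionMatrix

    df = pd.DataFrame.from_dict(values, orient="index")
    df.index.name = "gene"
    df.columns = [f"rep{i + 1}" for i in range(df.shape[1])]
    return ExpressionMatrix(modality, line, df)
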