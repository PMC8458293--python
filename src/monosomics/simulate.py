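"""Synthetic data generators for every stage of the monosomy analysis pipeline.

Chromosome loss halves the DNA copy number of every gene on the affected
chromosome.  The generators here emulate the signals such a loss leaves in
the data types the pipeline consumes:

* binned genome coverage with a halved read depth on the monosome,
* paired mRNA/protein log2 intensity matrices in which monosomic genes fall
  into four dosage-compensation ("buffering") categories,
* sucrose-gradient polysome traces as Gaussian peaks on a baseline,
* a tumor cohort with ploidy strata, TP53-alteration enrichment and a
  pathway-level expression shift in monosomic samples.

Every generator is deterministic under a fixed seed and returns the ground
truth (category labels, strata, true peak heights) alongside the data so
parameter-recovery tests never have to reverse-engineer their own input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimGenome",
    "BufferingMixture",
    "CohortSpec",
    "ExpressionMatrix",
    "PolysomeProfile",
    "SimulatedExpression",
    "SimulatedCohort",
    "BUFFERING_CATEGORIES",
    "simulate_annotation",
    "simulate_read_depth",
    "simulate_expression",
    "simulate_polysome_trace",
    "simulate_cohort",
]

#: The four dosage-compensation categories, "<mRNA side>;<protein side>",
#: where "down" means log2FC below the buffering cutoff (default -0.5).
BUFFERING_CATEGORIES = ("up;up", "down;up", "down;down", "up;down")


@dataclass(frozen=True)
class SimGenome:
    """Layout of a synthetic genome used to place genes.

    ``rpg_free_chromosomes`` mirrors the fact that nearly every human
    chromosome carries at least one ribosomal protein gene; chromosomes in
    this set (by default chr7) carry none.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 2_000_000),
        ("chr2", 2_000_000),
        ("chr3", 2_000_000),
    )
    genes_per_chromosome: int = 100
    rpg_per_chromosome: int = 1
    corum_fraction: float = 0.3
    rpg_free_chromosomes: frozenset[str] = frozenset({"chr7"})
    seed: int = 0

    def validate(self) -> None:
        if len(self.chromosomes) == 0:
            raise ValueError("genome must contain at least one chromosome")
        if self.genes_per_chromosome <= 0:
            raise ValueError("genes_per_chromosome must be positive")
        if self.rpg_per_chromosome < 0:
            raise ValueError("rpg_per_chromosome must be >= 0")
        if not 0.0 <= self.corum_fraction <= 1.0:
            raise ValueError("corum_fraction must be in [0, 1]")
        for name, length in self.chromosomes:
            if length < self.genes_per_chromosome:
                raise ValueError(f"chromosome {name} too short for requested gene count")


@dataclass(frozen=True)
class BufferingMixture:
    """Four-component mixture of (mRNA, protein) dosage responses.

    Component means on the log2 fold-change scale:
    up;up -> (mu_up, mu_up); down;up -> (mu_down, mu_up);
    down;down -> (mu_down, mu_down); up;down -> (mu_up, mu_down).
    ``mu_down`` defaults to -1, the pure 50% dosage expectation; ``mu_up``
    defaults to 0, full compensation back to the diploid level.
    """

    p_uu: float = 0.30
    p_du: float = 0.45
    p_dd: float = 0.20
    p_ud: float = 0.05
    mu_down: float = -1.0
    mu_up: float = 0.0
    sigma_gene: float = 0.2
    sigma_rep: float = 0.1
    n_replicates: int = 3

    @property
    def probabilities(self) -> tuple[float, float, float, float]:
        return (self.p_uu, self.p_du, self.p_dd, self.p_ud)

    def validate(self) -> None:
        probs = self.probabilities
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("mixture probabilities must be in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("mixture probabilities must sum to 1")
        if self.sigma_gene <= 0 or self.sigma_rep <= 0:
            raise ValueError("sigmas must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic tumor cohort stratified by ploidy.

    Default ploidy strata are well separated around the classification
    boundaries 1.80 / 2.19 so that ground-truth recovery is nearly exact;
    the TP53 alteration probabilities enrich alterations in the monosomy
    stratum, and ``pathway_effect`` down-shifts pathway-gene expression in
    monosomic samples (log2 units).
    """

    n_samples: int = 400
    somy_fractions: tuple[float, float, float] = (0.12, 0.76, 0.12)
    ploidy_means: tuple[float, float, float] = (1.70, 2.00, 2.26)
    ploidy_sds: tuple[float, float, float] = (0.05, 0.06, 0.04)
    tp53_alt_prob: tuple[float, float, float] = (0.60, 0.25, 0.25)
    tp53_score_shift: tuple[float, float, float] = (1.2, 0.0, 0.3)
    aneuploidy_means: tuple[float, float, float] = (12.0, 4.0, 12.0)
    pathway_effect: float = -0.5
    n_cancer_types: int = 15
    n_genes: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.somy_fractions) - 1.0) > 1e-9:
            raise ValueError("somy_fractions must sum to 1")
        if any(f < 0 for f in self.somy_fractions):
            raise ValueError("somy_fractions must be non-negative")
        if any(m <= 0 for m in self.ploidy_means):
            raise ValueError("ploidy means must be positive")
        if any(not 0 <= p <= 1 for p in self.tp53_alt_prob):
            raise ValueError("tp53_alt_prob entries must be in [0, 1]")
        if self.n_cancer_types < 1:
            raise ValueError("n_cancer_types must be >= 1")


@dataclass
class ExpressionMatrix:
    """Gene x replicate matrix of log2 intensities for one modality."""

    modality: str  # "mRNA" or "protein"
    cell_line: str
    data: pd.DataFrame  # index: gene ids, columns: replicate names

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValueError("expression matrix needs at least one replicate")
        if not self.data.index.is_unique:
            raise ValueError("gene ids must be unique")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.modality, self.cell_line, self.data.copy())


@dataclass
class PolysomeProfile:
    """An ordered (position, absorbance) sucrose-gradient trace."""

    positions: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.shape != self.absorbance.shape:
            raise ValueError("positions and absorbance must have equal length")
        if self.positions.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def copy(self) -> "PolysomeProfile":
        return PolysomeProfile(self.positions.copy(), self.absorbance.copy(), self.label)


@dataclass
class SimulatedExpression:
    """Paired matrices for one monosomic line and its parental control."""

    mrna: ExpressionMatrix
    mrna_parental: ExpressionMatrix
    protein: ExpressionMatrix
    protein_parental: ExpressionMatrix
    truth: pd.DataFrame  # gene, chromosome, monosomic, category, true FCs
    monosome: frozenset[str]


@dataclass
class SimulatedCohort:
    table: pd.DataFrame  # sample, ploidy, tp53_altered, tp53_score, aneuploidy_score, cancer_type
    expression: pd.DataFrame  # genes x samples, log2
    truth: pd.DataFrame  # sample, stratum


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_annotation(spec: SimGenome) -> pd.DataFrame:
    """Place non-overlapping half-open gene intervals on each chromosome.

    Returns a data frame with columns ``gene, chromosome, start, end,
    is_rpg, is_corum``, sorted by (chromosome, start).  Each chromosome is
    cut into equal slots, one gene per slot, with jittered boundaries so
    interval lengths vary.
    """
    spec.validate()
    rng = _rng(spec.seed)
    rows = []
    for chrom, length in spec.chromosomes:
        n = spec.genes_per_chromosome
        slot = length // n
        for i in range(n):
            lo = i * slot
            start = lo + int(rng.integers(0, max(1, slot // 4)))
            end = lo + slot - int(rng.integers(0, max(1, slot // 4)))
            if end <= start:  # degenerate slot; keep at least 1 bp
                end = start + 1
            rows.append((f"{chrom}_g{i:04d}", chrom, start, min(end, length)))
    ann = pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])

    ann["is_rpg"] = False
    for chrom, _ in spec.chromosomes:
        if chrom in spec.rpg_free_chromosomes or spec.rpg_per_chromosome == 0:
            continue
        idx = ann.index[ann["chromosome"] == chrom]
        chosen = rng.choice(idx, size=min(spec.rpg_per_chromosome, len(idx)), replace=False)
        ann.loc[chosen, "is_rpg"] = True
    ann["is_corum"] = rng.random(len(ann)) < spec.corum_fraction
    ann = ann.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
    return ann


def simulate_read_depth(
    annotation: pd.DataFrame,
    karyotype: dict[str, int],
    bin_size: int = 10_000,
    mean_depth: float = 100.0,
    dispersion: float = 0.0,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tile each chromosome with half-open bins and draw count-like coverage.

    Expected bin coverage is ``mean_depth * copy / 2``.  Noise is negative
    binomial with variance ``m + dispersion * m**2`` (Poisson when
    ``dispersion`` is 0); ``dispersion=None`` disables noise entirely and
    returns the expectation in every bin.  Chromosome lengths default to the
    largest annotated gene end per chromosome.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bad = {c: k for c, k in karyotype.items() if not (isinstance(k, (int, np.integer)) and k >= 0)}
    if bad:
        raise ValueError(f"copy numbers must be non-negative integers, got {bad}")
    if chrom_lengths is None:
        chrom_lengths = annotation.groupby("chromosome")["end"].max().to_dict()
    rng = _rng(seed)
    rows = []
    for chrom in sorted(karyotype):
        copy = karyotype[chrom]
        length = int(chrom_lengths[chrom])
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        m = mean_depth * copy / 2.0
        if dispersion is None:
            cov = np.full(len(starts), m)
        elif dispersion == 0:
            cov = rng.poisson(m, size=len(starts)).astype(float)
        else:
            # NB with mean m, variance m + dispersion * m^2
            if m == 0:
                cov = np.zeros(len(starts))
            else:
                r = 1.0 / dispersion
                p = r / (r + m)
                cov = rng.negative_binomial(r, p, size=len(starts)).astype(float)
        for s, e, c in zip(starts, ends, cov):
            rows.append((chrom, int(s), int(e), float(c)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "coverage"])


def simulate_expression(
    annotation: pd.DataFrame,
    monosome: set[str] | frozenset[str],
    mix: BufferingMixture | None = None,
    baseline: float = 10.0,
    baseline_sd: float = 1.5,
    replicate_shift_sd: float = 0.3,
    cell_line: str = "RM_sim",
    seed: int = 0,
) -> SimulatedExpression:
    """Draw paired mRNA/protein replicate matrices for a monosomic line.

    Each gene gets a baseline log2 intensity shared by the sample and the
    parental line.  Monosomic genes receive a category-specific (mRNA,
    protein) fold-change mean from the four-component mixture plus
    gene-level noise; disomic genes get gene-level noise around 0.  Each
    replicate carries a global additive shift (``replicate_shift_sd``) that
    the median-shift normalization downstream is expected to remove, plus
    per-measurement noise ``sigma_rep``.
    """
    mix = mix or BufferingMixture()
    mix.validate()
    monosome = frozenset(monosome)
    if not monosome:
        raise ValueError("monosome chromosome set must not be empty")
    known = set(annotation["chromosome"])
    missing = monosome - known
    if missing:
        raise ValueError(f"monosome chromosomes not in annotation: {sorted(missing)}")

    rng = _rng(seed)
    genes = annotation["gene"].to_numpy()
    chroms = annotation["chromosome"].to_numpy()
    n = len(genes)
    is_mono = np.isin(chroms, list(monosome))

    base = baseline + rng.normal(0.0, baseline_sd, size=n)

    cat_means = {
        "up;up": (mix.mu_up, mix.mu_up),
        "down;up": (mix.mu_down, mix.mu_up),
        "down;down": (mix.mu_down, mix.mu_down),
        "up;down": (mix.mu_up, mix.mu_down),
    }
    category = np.array([""] * n, dtype=object)
    n_mono = int(is_mono.sum())
    draws = rng.choice(len(BUFFERING_CATEGORIES), size=n_mono, p=list(mix.probabilities))
    category[is_mono] = np.array(BUFFERING_CATEGORIES, dtype=object)[draws]

    true_fc_m = np.zeros(n)
    true_fc_p = np.zeros(n)
    mu_m = np.zeros(n)
    mu_p = np.zeros(n)
    for cat, (mm, mp) in cat_means.items():
        sel = category == cat
        mu_m[sel] = mm
        mu_p[sel] = mp
    true_fc_m = mu_m + rng.normal(0.0, mix.sigma_gene, size=n)
    true_fc_p = mu_p + rng.normal(0.0, mix.sigma_gene, size=n)

    def _matrix(modality: str, line: str, offset: np.ndarray) -> ExpressionMatrix:
        cols = {}
        for r in range(mix.n_replicates):
            shift = rng.normal(0.0, replicate_shift_sd)
            cols[f"rep{r + 1}"] = base + offset + shift + rng.normal(0.0, mix.sigma_rep, size=n)
        df = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        return ExpressionMatrix(modality, line, df)

    zero = np.zeros(n)
    sim = SimulatedExpression(
        mrna=_matrix("mRNA", cell_line, true_fc_m),
        mrna_parental=_matrix("mRNA", "parental", zero),
        protein=_matrix("protein", cell_line, true_fc_p),
        protein_parental=_matrix("protein", "parental", zero),
        truth=pd.DataFrame(
            {
                "gene": genes,
                "chromosome": chroms,
                "monosomic": is_mono,
                "category": category,
                "true_mrna_log2fc": true_fc_m,
                "true_protein_log2fc": true_fc_p,
                "is_corum": annotation["is_corum"].to_numpy(),
            }
        ),
        monosome=monosome,
    )
    return sim


def simulate_polysome_trace(
    peak_positions: tuple[float, ...] = (20.0, 32.0, 45.0, 65.0),
    peak_heights: tuple[float, ...] = (0.15, 0.25, 0.6, 0.35),
    peak_widths: tuple[float, ...] = (2.0, 2.0, 2.5, 6.0),
    baseline: float = 0.05,
    noise_sd: float = 0.01,
    n_points: int = 2000,
    x_range: tuple[float, float] = (0.0, 100.0),
    label: str = "trace",
    seed: int = 0,
) -> tuple[PolysomeProfile, dict]:
    """Sum-of-Gaussians absorbance trace with white noise.

    Default peaks emulate 40S, 60S, 80S and a broad polysome region along a
    sucrose gradient.  Returns the profile and a ground-truth dict with the
    true peak positions/heights (above baseline).
    """
    positions = np.asarray(peak_positions, dtype=float)
    heights = np.asarray(peak_heights, dtype=float)
    widths = np.asarray(peak_widths, dtype=float)
    if not (len(positions) == len(heights) == len(widths)):
        raise ValueError("peak parameter lists must have equal length")
    if np.any(widths <= 0):
        raise ValueError("peak widths must be positive")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("peak positions must be strictly increasing")
    if np.any((positions < x_range[0]) | (positions > x_range[1])):
        raise ValueError("peak positions must lie within the trace range")
    if n_points < 2:
        raise ValueError("n_points too small")

    x = np.linspace(x_range[0], x_range[1], n_points)
    y = np.full(n_points, float(baseline))
    for p, h, w in zip(positions, heights, widths):
        y = y + h * np.exp(-0.5 * ((x - p) / w) ** 2)
    if noise_sd > 0:
        y = y + _rng(seed).normal(0.0, noise_sd, size=n_points)
    truth = {
        "positions": positions.tolist(),
        "heights": heights.tolist(),
        "widths": widths.tolist(),
        "baseline": baseline,
    }
    return PolysomeProfile(x, y, label=label), truth


STRATA = ("Monosomy", "Disomy", "Polysomy")


def simulate_cohort(
    spec: CohortSpec,
    pathway_gene_sets: dict[str, list[str]] | None = None,
) -> SimulatedCohort:
    """Draw a ploidy-stratified cohort with expression and TP53 annotations.

    Samples are assigned to Monosomy/Disomy/Polysomy strata; ploidy is
    normal per stratum, TP53 alteration is Bernoulli per stratum, the TP53
    classifier score is a logistic transform of a stratum-shifted latent
    normal, and the aneuploidy score is Poisson per stratum.  Genes in
    ``pathway_gene_sets`` are shifted by ``pathway_effect`` in monosomic
    samples.
    """
    spec.validate()
    rng = _rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    universe = set(genes)
    pathway_gene_sets = pathway_gene_sets or {}
    for term, members in pathway_gene_sets.items():
        extra = set(members) - universe
        if extra:
            raise ValueError(
                f"pathway {term!r} contains genes outside the expression universe: {sorted(extra)[:5]}"
            )

    strata = rng.choice(3, size=spec.n_samples, p=list(spec.somy_fractions))
    means = np.asarray(spec.ploidy_means)[strata]
    sds = np.asarray(spec.ploidy_sds)[strata]
    ploidy = rng.normal(means, sds)
    ploidy = np.clip(ploidy, 0.2, None)  # ploidy draws must stay positive
    altered = rng.random(spec.n_samples) < np.asarray(spec.tp53_alt_prob)[strata]
    latent = rng.normal(np.asarray(spec.tp53_score_shift)[strata], 1.0)
    tp53_score = 1.0 / (1.0 + np.exp(-latent))
    aneu = rng.poisson(np.asarray(spec.aneuploidy_means, dtype=float)[strata])
    cancer_type = rng.integers(0, spec.n_cancer_types, size=spec.n_samples)

    samples = [f"s{i:04d}" for i in range(spec.n_samples)]
    table = pd.DataFrame(
        {
            "sample": samples,
            "ploidy": ploidy,
            "tp53_altered": altered,
            "tp53_score": tp53_score,
            "aneuploidy_score": aneu,
            "cancer_type": [f"T{t:02d}" for t in cancer_type],
        }
    )

    expr = rng.normal(8.0, 1.0, size=(spec.n_genes, spec.n_samples))
    pathway_members = sorted({g for members in pathway_gene_sets.values() for g in members})
    if pathway_members and spec.pathway_effect != 0.0:
        gidx = [genes.index(g) for g in pathway_members]
        mono = strata == 0
        expr[np.ix_(gidx, np.where(mono)[0])] += spec.pathway_effect
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)

    truth = pd.DataFrame({"sample": samples, "stratum": [STRATA[s] for s in strata]})
    return SimulatedCohort(table=table, expression=expression, truth=truth)
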