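"""End-to-end orchestration: simulate -> copy number -> dosage ->
enrichment -> ssGSEA -> polysome -> cohort.

A single config dict (typically loaded from YAML) drives every stage; one
global seed fans out to per-stage seeds by stable hashing, so a run is
reproducible end to end and two runs with the same config and seed
produce byte-identical outputs and manifests.  Each stage records the
checksums of its outputs in ``manifest.json``, so an unchanged rerun can
be verified (and its outputs reused) by comparing manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .cohort import (SomyThresholds, aneuploidy_confound_summary, classify_somy,
                     per_type_score_comparison, threshold_sweep, tp53_enrichment)
from .copy_number import (assign_bins_to_genes, call_somy_per_chromosome,
                          center_coverage, per_gene_log2_median)
from .dosage import (BufferingParams, build_fold_change_table, chromosome_median_profile,
                     classify_buffering, log2_fold_change, median_shift_normalize_pair)
from .enrichment import AnnotationSet, enrichment_2d
from .polysome import (SmoothingParams, locate_subunit_peaks, scale_to_reference,
                       smooth_profile, subunit_ratios)
from .simulate import (BufferingMixture, CohortSpec, SimGenome, simulate_annotation,
                       simulate_cohort, simulate_expression, simulate_polysome_trace,
                       simulate_read_depth)
from .ssgsea import SsgseaParams, compare_groups, score_matrix

STAGES = ("simulate", "cnv", "dosage", "enrich2d", "ssgsea", "polysome", "cohort")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "genome": {
        "chromosomes": [["chr1", 2_000_000], ["chr2", 2_000_000], ["chr3", 2_000_000],
                        ["chr4", 2_000_000]],
        "genes_per_chromosome": 200,
        "rpg_per_chromosome": 2,
        "corum_fraction": 0.3,
    },
    "monosome": ["chr2"],
    "read_depth": {"bin_size": 10_000, "mean_depth": 100.0, "dispersion": 0.05},
    "mixture": {},
    "buffering": {"cutoff": -0.5},
    "enrichment": {"min_size": 10, "fdr_threshold": 0.02, "filter_results": False},
    "polysome": {
        "window": 57,
        "polyorder": 3,
        "noise_sd": 0.005,
        "search_windows": {"40S": [14, 26], "60S": [27, 38], "80S": [39, 52]},
        "monosome_heights": [0.18, 0.35, 0.6, 0.45],
    },
    "cohort": {},
    "ssgsea": {"alpha": 0.75, "normalize": False},
    "thresholds": {},
    "pathways": {"n_sets": 3, "set_size": 30},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    import copy

    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    """Validate parameter blocks before any stage runs."""
    unknown = set(config.get("stages", [])) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    SimGenome(
        chromosomes=tuple((c, int(l)) for c, l in config["genome"]["chromosomes"]),
        genes_per_chromosome=config["genome"]["genes_per_chromosome"],
        rpg_per_chromosome=config["genome"]["rpg_per_chromosome"],
        corum_fraction=config["genome"]["corum_fraction"],
    ).validate()
    BufferingMixture(**config.get("mixture", {})).validate()
    BufferingParams(**config.get("buffering", {}))
    SmoothingParams(window=config["polysome"]["window"],
                    polyorder=config["polysome"]["polyorder"])
    SomyThresholds(**config.get("thresholds", {}))
    SsgseaParams(**config.get("ssgsea", {}))
    CohortSpec(**config.get("cohort", {})).validate()
    if not set(config["genome"].keys()) >= {"chromosomes", "genes_per_chromosome"}:
        raise ValueError("genome block incomplete")
    missing = [m for m in config["monosome"]
               if m not in {c for c, _ in config["genome"]["chromosomes"]}]
    if missing:
        raise ValueError(f"monosome chromosomes not in genome: {missing}")
    for path_key in ("bins_file", "genes_file"):
        path = config.get(path_key)
        if path is not None and not Path(path).exists():
            raise ValueError(f"{path_key} does not exist: {path}")


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the selected stages into ``out_dir``; return the manifest."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    cfg_hash = _config_hash(config)

    manifest_path = out / "manifest.json"
    manifest = {"config_hash": cfg_hash, "seed": seed, "stages": {}}
    summary: dict = {}

    stages = config.get("stages", list(STAGES))
    state: dict = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            outputs = runner(config, out, seed, state, summary)
        except PipelineError:
            raise
        except Exception as exc:  # abort with stage name and cause
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "seed": stage_seed(seed, stage),
            "outputs": {f: _checksum(out / f) for f in outputs},
        }

    _write_json(summary, out / "summary.json")
    manifest["outputs"] = {"summary.json": _checksum(out / "summary.json")}
    _write_json(manifest, manifest_path)
    return manifest


# --- stage implementations -------------------------------------------------

def _stage_simulate(config, out, seed, state, summary):
    genome = SimGenome(
        chromosomes=tuple((c, int(l)) for c, l in config["genome"]["chromosomes"]),
        genes_per_chromosome=config["genome"]["genes_per_chromosome"],
        rpg_per_chromosome=config["genome"]["rpg_per_chromosome"],
        corum_fraction=config["genome"]["corum_fraction"],
        seed=stage_seed(seed, "simulate"),
    )
    annotation = simulate_annotation(genome)
    karyotype = {c: (1 if c in config["monosome"] else 2)
                 for c, _ in config["genome"]["chromosomes"]}
    bins = simulate_read_depth(annotation, karyotype, seed=stage_seed(seed, "simulate.depth"),
                               **config["read_depth"])
    mixture = BufferingMixture(**config.get("mixture", {}))
    expr = simulate_expression(annotation, set(config["monosome"]), mixture,
                               seed=stage_seed(seed, "simulate.expression"))
    poly_cfg = config["polysome"]
    reference, _ = simulate_polysome_trace(noise_sd=poly_cfg["noise_sd"], label="parental",
                                           seed=stage_seed(seed, "simulate.trace.ref"))
    sample, _ = simulate_polysome_trace(
        peak_heights=tuple(poly_cfg["monosome_heights"]), noise_sd=poly_cfg["noise_sd"],
        label="monosome", seed=stage_seed(seed, "simulate.trace.sample"))
    cohort_spec = CohortSpec(**{**config.get("cohort", {}),
                                "seed": stage_seed(seed, "simulate.cohort")})
    n_sets, set_size = config["pathways"]["n_sets"], config["pathways"]["set_size"]
    rng = np.random.default_rng(stage_seed(seed, "simulate.pathways"))
    genes = [f"g{i:05d}" for i in range(cohort_spec.n_genes)]
    pathway_sets = {
        f"pathway_{k}": sorted(rng.choice(genes, size=set_size, replace=False))
        for k in range(n_sets)
    }
    cohort_sim = simulate_cohort(cohort_spec, pathway_sets)

    mio.write_gene_bed(annotation, out / "genes.bed")
    mio.write_bins_bed(bins, out / "bins.bed")
    for name, matrix in (("mrna", expr.mrna), ("mrna_parental", expr.mrna_parental),
                         ("protein", expr.protein), ("protein_parental", expr.protein_parental)):
        mio.write_expression_tsv(matrix, out / f"{name}.tsv")
    expr.truth.to_csv(out / "expression.truth.tsv", sep="\t", index=False,
                      float_format=mio.FLOAT_FMT)
    mio.write_trace_csv(reference, out / "trace_parental.csv")
    mio.write_trace_csv(sample, out / "trace_monosome.csv")
    mio.write_cohort_tsv(cohort_sim.table, out / "cohort.tsv")
    cohort_sim.expression.to_csv(out / "cohort_expression.tsv", sep="\t",
                                 float_format=mio.FLOAT_FMT)
    cohort_sim.truth.to_csv(out / "cohort.truth.tsv", sep="\t", index=False)
    mio.write_gmt(pathway_sets, out / "pathways.gmt")

    state.update(annotation=annotation, bins=bins, expr=expr, karyotype=karyotype,
                 reference_trace=reference, sample_trace=sample,
                 cohort=cohort_sim, pathway_sets=pathway_sets)
    return ["genes.bed", "bins.bed", "mrna.tsv", "mrna_parental.tsv", "protein.tsv",
            "protein_parental.tsv", "expression.truth.tsv", "trace_parental.csv",
            "trace_monosome.csv", "cohort.tsv", "cohort_expression.tsv",
            "cohort.truth.tsv", "pathways.gmt"]


def _require(state, key, stage, hint):
    if key not in state:
        raise PipelineError(stage, f"missing input {key!r}; run the {hint} stage first "
                                   "or point the config at existing files")
    return state[key]


def _stage_cnv(config, out, seed, state, summary):
    if "bins" not in state and config.get("bins_file"):
        state["bins"] = mio.read_bins_bed(config["bins_file"])
        state["annotation"] = mio.read_gene_bed(config["genes_file"])
    bins = _require(state, "bins", "cnv", "simulate")
    annotation = _require(state, "annotation", "cnv", "simulate")
    gene_bins = assign_bins_to_genes(bins, annotation)
    log2 = per_gene_log2_median(gene_bins)
    centered = center_coverage(log2)
    calls = call_somy_per_chromosome(centered)
    centered.to_csv(out / "gene_coverage.tsv", sep="\t", index=False,
                    float_format=mio.FLOAT_FMT)
    calls_df = pd.DataFrame([vars(c) for c in calls])
    calls_df.to_csv(out / "somy_calls.tsv", sep="\t", index=False, float_format=mio.FLOAT_FMT)
    summary["somy_calls"] = {c.chromosome: c.call for c in calls}
    state["somy_calls"] = calls
    return ["gene_coverage.tsv", "somy_calls.tsv"]


def _stage_dosage(config, out, seed, state, summary):
    expr = _require(state, "expr", "dosage", "simulate")
    annotation = _require(state, "annotation", "dosage", "simulate")
    monosome = set(config["monosome"])
    mono_genes = set(annotation.loc[annotation["chromosome"].isin(monosome), "gene"])
    fc_cols = {}
    for modality, sample, parental in (("mrna", expr.mrna, expr.mrna_parental),
                                       ("protein", expr.protein, expr.protein_parental)):
        s_norm, p_norm = median_shift_normalize_pair(sample, parental, mono_genes)
        fc_cols[modality] = log2_fold_change(s_norm, p_norm)
    fc = build_fold_change_table(fc_cols["mrna"], fc_cols["protein"], annotation, monosome)
    params = BufferingParams(**config.get("buffering", {}))
    result = classify_buffering(fc, params)
    profile = chromosome_median_profile(fc)
    fc_out = fc.copy()
    fc_out["category"] = fc_out["gene"].map(result.categories)
    mio.write_fold_change_tsv(fc_out, out / "fold_changes.tsv")
    profile.to_csv(out / "chromosome_medians.tsv", sep="\t", index=False,
                   float_format=mio.FLOAT_FMT)
    dosage_summary = {"fractions": result.fractions, "medians": result.medians,
                      "n_matched_monosomic": result.n_matched}
    _write_json(dosage_summary, out / "dosage_summary.json")
    summary["buffering"] = dosage_summary
    state["fc"] = fc
    return ["fold_changes.tsv", "chromosome_medians.tsv", "dosage_summary.json"]


def _stage_enrich2d(config, out, seed, state, summary):
    fc = _require(state, "fc", "enrich2d", "dosage")
    annotation = _require(state, "annotation", "enrich2d", "simulate")
    terms = [
        AnnotationSet(term_id=f"chrom:{chrom}", name=chrom,
                      genes=frozenset(sub["gene"]), category="chromosome")
        for chrom, sub in annotation.groupby("chromosome")
    ]
    terms.append(AnnotationSet("CORUM", "complex subunits",
                               frozenset(annotation.loc[annotation["is_corum"], "gene"]),
                               "complex"))
    terms.append(AnnotationSet("RPG", "ribosomal protein genes",
                               frozenset(annotation.loc[annotation["is_rpg"], "gene"]),
                               "ribosome"))
    cfg = config["enrichment"]
    matched = fc.dropna(subset=["mrna_log2fc", "protein_log2fc"]).set_index("gene")
    result = enrichment_2d(matched["mrna_log2fc"], matched["protein_log2fc"], terms,
                           min_size=cfg["min_size"], fdr_threshold=cfg["fdr_threshold"],
                           filter_results=cfg["filter_results"])
    result.to_csv(out / "enrichment_2d.tsv", sep="\t", index=False, float_format=mio.FLOAT_FMT)
    summary["enrichment_2d"] = {
        "n_terms": int(len(result)),
        "significant_terms": result.loc[result["fdr"] < cfg["fdr_threshold"], "term_id"].tolist(),
    }
    return ["enrichment_2d.tsv"]


def _stage_ssgsea(config, out, seed, state, summary):
    cohort_sim = _require(state, "cohort", "ssgsea", "simulate")
    pathway_sets = _require(state, "pathway_sets", "ssgsea", "simulate")
    params = SsgseaParams(**config.get("ssgsea", {}))
    scores = score_matrix(cohort_sim.expression, {k: set(v) for k, v in pathway_sets.items()},
                          params)
    scores.to_csv(out / "pathway_scores.tsv", sep="\t", float_format=mio.FLOAT_FMT)
    thresholds = SomyThresholds(**config.get("thresholds", {}))
    somy = classify_somy(cohort_sim.table.set_index("sample")["ploidy"], thresholds)
    pvals = {}
    for term in scores.columns:
        mono = scores.loc[somy == "Monosomy", term]
        diso = scores.loc[somy == "Disomy", term]
        pvals[term] = compare_groups(mono, diso, alternative="less")
    _write_json(pvals, out / "ssgsea_group_tests.json")
    summary["ssgsea_monosomy_vs_disomy_p"] = pvals
    state["somy"] = somy
    state["pathway_scores"] = scores
    return ["pathway_scores.tsv", "ssgsea_group_tests.json"]


def _stage_polysome(config, out, seed, state, summary):
    reference = _require(state, "reference_trace", "polysome", "simulate")
    sample = _require(state, "sample_trace", "polysome", "simulate")
    cfg = config["polysome"]
    params = SmoothingParams(window=cfg["window"], polyorder=cfg["polyorder"])
    windows = {k: tuple(v) for k, v in cfg["search_windows"].items()}
    results = {}
    ref_smooth = smooth_profile(reference, params)
    for label, trace in (("parental", reference), ("monosome", sample)):
        sm = smooth_profile(trace, params)
        if label != "parental":
            sm = scale_to_reference(sm, ref_smooth, windows, params, smoothed=True)
        peaks = locate_subunit_peaks(sm, windows)
        ratios = subunit_ratios(peaks)
        mio.write_trace_csv(sm, out / f"trace_{label}.smoothed.csv")
        results[label] = {"peaks": {k: v for k, v in peaks.peaks.items()}, "ratios": ratios}
    _write_json(results, out / "polysome_peaks.json")
    summary["polysome"] = {label: res["ratios"] for label, res in results.items()}
    return ["trace_parental.smoothed.csv", "trace_monosome.smoothed.csv", "polysome_peaks.json"]


def _stage_cohort(config, out, seed, state, summary):
    cohort_sim = _require(state, "cohort", "cohort", "simulate")
    thresholds = SomyThresholds(**config.get("thresholds", {}))
    table = cohort_sim.table.copy()
    table["somy"] = classify_somy(table["ploidy"], thresholds).to_numpy()
    enrich = tp53_enrichment(table["somy"], table["tp53_altered"])
    sweep, robust = threshold_sweep(table["ploidy"], table["tp53_altered"], thresholds)
    per_type = per_type_score_comparison(table)
    confound = aneuploidy_confound_summary(table)
    table.to_csv(out / "cohort_classified.tsv", sep="\t", index=False,
                 float_format=mio.FLOAT_FMT)
    sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False, float_format=mio.FLOAT_FMT)
    per_type.to_csv(out / "per_type_tests.tsv", sep="\t", index=False,
                    float_format=mio.FLOAT_FMT)
    cohort_summary = {
        "class_counts": table["somy"].value_counts().to_dict(),
        "tp53_odds_ratio": enrich.odds_ratio,
        "tp53_p_value": enrich.p_value,
        "sweep_robust": robust,
        "per_type_significant": {
            comp: int(sub["significant"].sum())
            for comp, sub in per_type.groupby("comparison")
        },
        "aneuploidy_confound": confound,
    }
    _write_json(cohort_summary, out / "cohort_summary.json")
    summary["cohort"] = cohort_summary
    return ["cohort_classified.tsv", "threshold_sweep.tsv", "per_type_tests.tsv",
            "cohort_summary.json"]


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "cnv": _stage_cnv,
    "dosage": _stage_dosage,
    "enrich2d": _stage_enrich2d,
    "ssgsea": _stage_ssgsea,
    "polysome": _stage_polysome,
    "cohort": _stage_cohort,
}
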