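"""End-to-end orchestration: union -> consensus -> regenotype -> CCC ->
population statistics -> validation, over synthetic or file inputs.

Each stage is an importable function; :func:`run_pipeline` chains them
on a simulated study, writes every stage artifact (VCF/TSV/JSON) to an
output directory, and records a JSON manifest with seeds, thresholds
and record counts so reruns can be compared digest-by-digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import ccc as ccc_mod
from . import popstats, validation
from .consensus import (
    DEFAULT_THRESHOLD,
    apply_consensus,
    build_covariates,
    label_training,
    regenotype,
    train_consensus_model,
)
from .core import GenotypeMatrix, IndelRecord, MAX_INDEL_LENGTH, left_align, split_complex
from .simulate import RawCall, SimulatedStudy, SimulationConfig, simulate_study
from .union import merge_union
from .popstats import alt_allele_frequency

logger = logging.getLogger("exindel")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "normalize_raw_calls",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Knobs of the downstream pipeline (not of the data generator)."""

    consensus_threshold: float = DEFAULT_THRESHOLD
    rf_trees: int = 500
    training_fraction: float = 0.5  # union share overlapping the truth data
    genotype_error_rate: float = 0.02
    n_validation_sites: int = 800
    max_validation_carriers: int = 5
    rare_aaf_threshold: float = 0.01  # "rare" means AAF at or below this

    def __post_init__(self):
        if not 0.0 <= self.consensus_threshold <= 1.0:
            raise ValueError(
                f"consensus threshold {self.consensus_threshold} outside [0, 1]"
            )


def normalize_raw_calls(
    raw_calls: list[RawCall], caller: str, reference
) -> list[IndelRecord]:
    """Split, left-align and filter one caller's raw output lines.

    SNP-only lines and oversized alleles are dropped; duplicate keys
    after normalization collapse to one record (first quality wins).
    """
    seen: dict = {}
    n_dropped = 0
    for call in raw_calls:
        try:
            _, indel = split_complex(
                call.chrom,
                call.pos,
                call.ref,
                call.alt,
                reference=reference,
                caller_support=frozenset([caller]),
                caller_quals={caller: call.qual},
            )
        except ValueError:
            n_dropped += 1
            continue
        if indel is None or abs(indel.length) >= MAX_INDEL_LENGTH:
            n_dropped += 1
            continue
        indel = left_align(indel, reference)
        seen.setdefault(indel.key(), indel)
    if n_dropped:
        logger.info("%s: dropped %d non-INDEL records", caller, n_dropped)
    return list(seen.values())


@dataclass
class PipelineResult:
    """In-memory results of a full pipeline run."""

    union: list
    union_probs: np.ndarray
    consensus_records: list
    consensus_matrix: GenotypeMatrix
    model_seed: int
    ccc_population: ccc_mod.CCCSummary
    ccc_individual: ccc_mod.CCCSummary
    random_ccc_pct: float
    stats: dict
    validation_summary: dict
    label_fdr_union: float
    label_fdr_consensus: float
    label_tp_retention: float
    manifest: dict


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _label_fdr(records, truth_keys: set) -> float:
    labels = [rec.key() in truth_keys for rec in records]
    return 1.0 - (sum(labels) / len(labels)) if labels else float("nan")


def run_pipeline(
    study: SimulatedStudy | None = None,
    config: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute all downstream stages on a (possibly freshly simulated) study.

    ``seed`` drives the simulation (when ``study`` is not supplied), the
    forest, and the validation-site selection. With ``outdir`` set, each
    stage writes its artifact and a manifest JSON is produced.
    """
    config = config or PipelineConfig()
    if study is None:
        study = simulate_study(sim_config, seed=seed)
    reference = study.reference
    truth_keys = study.truth_key_set

    # stage 1: normalization + union merge
    callsets = {
        caller: normalize_raw_calls(raw, caller, reference)
        for caller, raw in study.raw_callsets.items()
    }
    union = merge_union(callsets, study.targets, study.evidence)
    logger.info("union: %d alleles from %d callers", len(union), len(callsets))

    # stage 2: train on the truth-covered share of the union, score all.
    # The truth standard only covers part of the data in practice, so the
    # model is fit on a random union subset and applied everywhere.
    train_rng = np.random.default_rng(seed + 7)
    n_train = max(2, int(round(config.training_fraction * len(union))))
    train_idx = train_rng.choice(len(union), size=n_train, replace=False)
    training_union = [union[i] for i in sorted(train_idx)]
    labeled = label_training(training_union, study.training_truth_keys, reference)
    model = train_consensus_model(labeled, seed=seed, n_trees=config.rf_trees)
    consensus_records, probs = apply_consensus(
        union, model, reference, config.consensus_threshold
    )
    logger.info(
        "consensus: %d of %d alleles at threshold %.2f",
        len(consensus_records), len(union), config.consensus_threshold,
    )

    # stage 3: regenotype kept sites, prune uncalled loci
    sites = [rec.indel for rec in consensus_records]
    depth = np.array([study.depth_matrix[rec.key()] for rec in consensus_records])
    vreads = np.array(
        [study.variant_read_matrix[rec.key()] for rec in consensus_records]
    )
    consensus_matrix = regenotype(
        sites, study.samples, depth, vreads,
        error_rate=config.genotype_error_rate,
    )
    logger.info(
        "regenotype: %d sites retained of %d", consensus_matrix.n_loci, len(sites)
    )

    # stage 4: CCC classification + random length-matched control
    ccc_pop, ccc_ind = ccc_mod.ccc_profile(consensus_matrix, reference)
    length_hist: dict[int, float] = {}
    for rec in consensus_matrix.loci:
        length_hist[rec.length] = length_hist.get(rec.length, 0) + 1
    random_set = ccc_mod.simulate_random_indels(
        length_hist, study.targets, reference,
        n=min(5000, 2 * consensus_matrix.n_loci), seed=seed + 1,
    )
    random_flags = [
        ccc_mod.classify_ccc(r, reference) == "CCC" for r in random_set
    ]
    random_ccc_pct = 100.0 * float(np.mean(random_flags))

    # stage 5: per-individual statistics
    region_bp = study.targets.total_bp()
    carried = consensus_matrix.genotypes > 0
    spectrum = popstats.density_by_af_bin(consensus_matrix, region_bp)
    aafs = np.array(
        [alt_allele_frequency(consensus_matrix.genotypes[i])
         for i in range(consensus_matrix.n_loci)]
    )
    fs_overall, fs_per_ind = popstats.frameshift_fraction(
        consensus_matrix.loci, consensus_matrix
    )
    stats = {
        "n_consensus_loci": consensus_matrix.n_loci,
        "region_mb": region_bp / 1e6,
        "indel_density_per_mb": popstats.variant_density(
            carried.sum(axis=0), region_bp
        ),
        "density_by_af_bin": spectrum.densities.tolist(),
        "pct_rare": 100.0 * float(
            (aafs <= config.rare_aaf_threshold).mean()
        ),
        "indels_per_exome": float(carried.sum(axis=0).mean()),
        "pct_heterozygous": popstats.percent_heterozygous(consensus_matrix),
        "pct_frameshift_loci": 100.0 * fs_overall,
        "pct_frameshift_per_exome": 100.0 * fs_per_ind,
        "deletion_insertion_ratio": popstats.deletion_insertion_ratio(
            consensus_matrix
        ),
    }

    # stage 6: validation of the union against simulated read evidence
    union_keys = [rec.key() for rec in union]
    truth_index = {r.key(): i for i, r in enumerate(study.truth.loci)}
    union_aafs = []
    union_gt_codes = []
    key_to_record = {}
    for rec in union:
        key = rec.key()
        key_to_record[key] = rec.indel
        d = study.depth_matrix[key]
        v = study.variant_read_matrix[key]
        if key in truth_keys:
            g = study.truth.genotypes[truth_index[key]]
            carriers = np.flatnonzero(g > 0)
            union_gt_codes.append(int(g[carriers[0]]) if carriers.size else 1)
            aaf = alt_allele_frequency(g)
        else:
            union_gt_codes.append(0)
            with np.errstate(invalid="ignore"):
                ratio = np.where(d > 0, v / np.maximum(d, 1), 0.0)
            aaf = max(
                float((ratio > 0.04).sum()) / (2 * len(d)), 1.0 / (2 * len(d))
            )
        union_aafs.append(aaf)
    carriers_map = {k: [] for k in union_keys}
    picks = validation.select_validation_sites(
        union_keys, union_aafs, carriers_map,
        n=min(config.n_validation_sites, len(union_keys)),
        max_carriers=config.max_validation_carriers, seed=seed + 2,
    )
    picked_keys = [k for k, _ in picks]
    is_true = np.array([k in truth_keys for k in picked_keys])
    key_index = {k: i for i, k in enumerate(union_keys)}
    gt_codes = np.array([union_gt_codes[key_index[k]] for k in picked_keys])
    from .simulate import simulate_validation_evidence

    evid = simulate_validation_evidence(
        [key_to_record[k] for k in picked_keys],
        is_true,
        gt_codes,
        depth=study.config.validation_depth,
        error_rate=study.config.validation_error_rate,
        seed=seed + 3,
        design_fail_frac=study.config.design_fail_frac,
    )
    union_counts = validation.tally(evid, scope="union")
    consensus_key_set = {rec.key() for rec in consensus_records}
    cons_mask = [k in consensus_key_set for k in picked_keys]
    cons_counts = validation.tally(
        [e for e, m in zip(evid, cons_mask) if m], scope="consensus"
    )
    fdr_union = validation.estimate_fdr(union_counts)
    fdr_consensus = validation.estimate_fdr(cons_counts)
    s_consensus = validation.relative_sensitivity(
        cons_counts.TP, union_counts.TP
    )
    validation_summary = {
        "union": vars(union_counts),
        "consensus": vars(cons_counts),
        "fdr_union": fdr_union,
        "fdr_consensus": fdr_consensus,
        "relative_sensitivity": s_consensus,
        "detectable_indels": validation.detectable_indels(
            union_counts.TP, cons_counts.AMBG, cons_counts.FAIL, s_consensus
        ),
        "planted_fp_fraction": float(np.mean(~is_true)),
    }

    # ground-truth (label) operating points
    label_fdr_union = _label_fdr([r.indel for r in union], truth_keys)
    label_fdr_consensus = _label_fdr(
        [r.indel for r in consensus_records], truth_keys
    )
    union_tp = sum(1 for r in union if r.key() in truth_keys)
    cons_tp = sum(1 for r in consensus_records if r.key() in truth_keys)
    retention = cons_tp / union_tp if union_tp else float("nan")

    manifest = {
        "seed": seed,
        "consensus_threshold": config.consensus_threshold,
        "rf_trees": config.rf_trees,
        "n_union": len(union),
        "n_consensus": len(consensus_records),
        "n_consensus_regenotyped": consensus_matrix.n_loci,
        "label_fdr_union": label_fdr_union,
        "label_fdr_consensus": label_fdr_consensus,
        "label_tp_retention": retention,
        "artifacts": {},
    }

    result = PipelineResult(
        union=union,
        union_probs=probs,
        consensus_records=consensus_records,
        consensus_matrix=consensus_matrix,
        model_seed=seed,
        ccc_population=ccc_pop,
        ccc_individual=ccc_ind,
        random_ccc_pct=random_ccc_pct,
        stats=stats,
        validation_summary=validation_summary,
        label_fdr_union=label_fdr_union,
        label_fdr_consensus=label_fdr_consensus,
        label_tp_retention=retention,
        manifest=manifest,
    )
    if outdir is not None:
        _write_artifacts(result, study, evid, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, study, evid, outdir: Path) -> None:
    from . import vcfio

    outdir.mkdir(parents=True, exist_ok=True)
    reference = study.reference
    vcfio.write_reference_fasta(reference, outdir / "reference.fa")
    from .regions import write_bed

    write_bed(study.targets, outdir / "targets.bed")

    union_records = [r.indel for r in result.union]
    vcfio.write_callset_vcf(
        union_records,
        reference,
        outdir / "union.vcf",
        info_fields={
            "CALLERS": {
                "meta": (".", "String", "Supporting callers"),
                "values": {
                    r.key(): ",".join(sorted(r.indel.caller_support))
                    for r in result.union
                },
            },
            "NQUAL": {
                "meta": (1, "Float", "Mean rank-normalized caller quality"),
                "values": {r.key(): r.norm_qual_mean for r in result.union},
            },
        },
    )
    covariates = build_covariates(result.union, reference)
    covariates.insert(0, "key", ["%s:%d:%s:%s" % k for k in
                                 (r.key() for r in result.union)])
    covariates.to_csv(outdir / "union_covariates.tsv", sep="\t", index=False)

    prob_map = {
        r.key(): float(p) for r, p in zip(result.union, result.union_probs)
    }
    ccc_values = {}
    motif_values = {}
    for rec in result.consensus_matrix.loci:
        ctx = ccc_mod.repeat_context(rec, reference)
        ccc_values[rec.key()] = 1 if ctx.is_ccc else 0
        motif_values[rec.key()] = ctx.motif
    vcfio.write_genotype_vcf(
        result.consensus_matrix,
        reference,
        outdir / "consensus.vcf",
        info_fields={
            "PROB": {
                "meta": (1, "Float", "Consensus classifier probability"),
                "values": prob_map,
            },
            "CCC": {
                "meta": (1, "Integer", "Change-in-copy-count INDEL (1=yes)"),
                "values": ccc_values,
            },
            "MOTIF": {
                "meta": (1, "String", "Smallest repeat motif of the allele"),
                "values": motif_values,
            },
        },
    )
    pop, ind = result.ccc_population, result.ccc_individual
    with open(outdir / "ccc_summary.tsv", "w") as fh:
        fh.write("level\tccc_ins\tnccc_ins\tccc_del\tnccc_del\n")
        for level, s in (("population", pop), ("individual", ind)):
            fh.write(
                f"{level}\t{s.ccc_insertion_pct:.2f}\t{s.nccc_insertion_pct:.2f}"
                f"\t{s.ccc_deletion_pct:.2f}\t{s.nccc_deletion_pct:.2f}\n"
            )
    with open(outdir / "popstats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2)
    vcfio.write_evidence_tsv(evid, outdir / "validation_evidence.tsv")
    with open(outdir / "validation_summary.json", "w") as fh:
        json.dump(result.validation_summary, fh, indent=2)

    artifacts = {}
    for name in (
        "reference.fa", "targets.bed", "union.vcf", "union_covariates.tsv",
        "consensus.vcf", "ccc_summary.tsv", "popstats.json",
        "validation_evidence.tsv", "validation_summary.json",
    ):
        artifacts[name] = _digest(outdir / name)
    result.manifest["artifacts"] = artifacts
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
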