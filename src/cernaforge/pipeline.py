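"""End-to-end orchestration: simulate -> filter -> DE -> targets -> modules
-> ceRNA network, with truth-table recovery accounting.

Each stage consumes the previous stage's in-memory objects; ``run_all`` is
what the ``run-all`` CLI subcommand and the acceptance checks drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cerna_network, coexpr_modules, expression_de, lncrna_annotation
from .expression_de import DEThresholds, ExpressionMatrix
from .io_formats import AnnotationSet, PipelineConfig, SeqRecord, logger
from .smallrna_filter import FilterReport, filter_reads, quantify_mirna
from .synthetic_data import GeneratorParams, SimulatedStudy, simulate
from .target_rules import scan_many

BETWEEN_GENOTYPE = tuple(
    f"wild_{leaf}_vs_mutant_{leaf}" for leaf in ("flag", "second", "third")
)


@dataclass
class PipelineResult:
    study: SimulatedStudy
    filter_reports: dict[str, FilterReport]
    mirna_tpm: ExpressionMatrix
    de_tables: dict[str, pd.DataFrame]          # per feature class
    de_sets: dict[str, set[str]]                # DE in >=1 gated contrast
    lnc_classes: pd.DataFrame
    mrna_hits: pd.DataFrame
    lnc_hits: pd.DataFrame
    modules: list[coexpr_modules.CoexprModule]
    module_trait: pd.DataFrame
    senescence_module: str
    mirna_mrna_pairs: pd.DataFrame
    mirna_lnc_pairs: pd.DataFrame
    triplets: list[cerna_network.CeRNATriplet]
    triplets_in_module: list[cerna_network.CeRNATriplet]


def run_all(
    params: GeneratorParams | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole analysis on a freshly simulated study."""
    cfg = config or PipelineConfig(seed=seed)
    study = simulate(params, seed=seed)
    p = study.params

    # small-RNA: clean tags -> counts -> TPM
    reports: dict[str, FilterReport] = {}
    clean = {}
    for sample, reads in study.smallrna_reads.items():
        clean[sample], reports[sample] = filter_reads(
            reads, adapter3=p.adapter3, adapter5=p.adapter5
        )
    counts = quantify_mirna(clean, [m.as_rna() for m in study.mirnas])
    counts_assigned = counts.drop(index="unassigned")
    mirna_counts = ExpressionMatrix(
        values=counts_assigned.astype(float),
        metadata=study.mrna_expr.metadata,
        unit="count",
    )
    mirna_tpm = expression_de.tpm_small(mirna_counts)

    # differential expression, nine contrasts per feature class
    th = DEThresholds(
        fdr_alpha=cfg.fdr_alpha, log2fc_min=cfg.log2fc_min,
        p_mirna=cfg.p_mirna, pseudocount=cfg.pseudocount,
    )
    contrasts = expression_de.enumerate_contrasts(study.mrna_expr.metadata)
    de_tables: dict[str, pd.DataFrame] = {}
    for feature_class, matrix in (
        ("mRNA", study.mrna_expr),
        ("lncRNA", study.lnc_expr),
        ("miRNA", mirna_tpm),
    ):
        tables = [
            expression_de.call_de(
                matrix, ga, gb, feature_class=feature_class,
                thresholds=th, contrast=label,
            )
            for label, (ga, gb) in contrasts.items()
        ]
        de_tables[feature_class] = pd.concat(tables, ignore_index=True)
    gate = (
        list(BETWEEN_GENOTYPE) if cfg.de_gate == "between_genotype" else None
    )
    de_sets = {
        cls: expression_de.de_feature_set([tab], contrasts=gate)
        for cls, tab in de_tables.items()
    }

    # lncRNA screening + classification
    lnc_annot = AnnotationSet(
        features=study.annotation.by_biotype("lncRNA_candidate")
    )
    coding = AnnotationSet(features=study.annotation.by_biotype("coding"))
    screened = lncrna_annotation.screen_candidates(
        lnc_annot, min_length=cfg.min_lnc_length
    )
    lnc_classes = lncrna_annotation.classify_all(
        screened, coding, bidir_window=cfg.bidir_window
    )

    # target prediction
    mirnas_rna = [m.as_rna() for m in study.mirnas]
    coding_ids = {t.id for t in coding}
    mrna_seqs = [t for t in study.transcripts if t.id in coding_ids]
    lnc_seqs = [t for t in study.transcripts if t.id not in coding_ids]
    mfe = cfg.mfe_ratio_a if cfg.ruleset == "A" else cfg.mfe_ratio_b
    mrna_hits = scan_many(mirnas_rna, mrna_seqs, ruleset=cfg.ruleset, mfe_threshold=mfe)
    lnc_hits = scan_many(mirnas_rna, lnc_seqs, ruleset=cfg.ruleset, mfe_threshold=mfe)

    # co-expression modules on the log2 mRNA matrix
    filtered = coexpr_modules.variance_prefilter(
        expression_de.log2_transform(study.mrna_expr, cfg.pseudocount),
        drop_fraction=cfg.drop_fraction,
    )
    adjacency = coexpr_modules.soft_adjacency(filtered, beta=cfg.beta)
    tom = coexpr_modules.tom_similarity(adjacency)
    modules = coexpr_modules.detect_modules(
        tom, filtered, min_size=cfg.min_module_size, merge_cut=cfg.merge_cut
    )
    trait_table = coexpr_modules.module_trait(modules, study.mrna_expr.metadata)
    senescence_module = _pick_senescence_module(trait_table)
    module_genes = {
        g for m in modules if m.label == senescence_module for g in m.genes
    }

    # ceRNA assembly
    mm_pairs = cerna_network.filter_pairs(
        mrna_hits, mirna_tpm, study.mrna_expr,
        de_mirnas=de_sets["miRNA"], de_targets=de_sets["mRNA"],
        scc_threshold=cfg.scc_threshold,
    )
    ml_pairs = cerna_network.filter_pairs(
        lnc_hits, mirna_tpm, study.lnc_expr,
        de_mirnas=de_sets["miRNA"], de_targets=de_sets["lncRNA"],
        scc_threshold=cfg.scc_threshold,
    )
    triplets = cerna_network.assemble_triplets(
        mm_pairs, ml_pairs, study.lnc_expr, study.mrna_expr,
        pcc_threshold=cfg.pcc_threshold,
    )
    triplets_in_module = cerna_network.assemble_triplets(
        mm_pairs, ml_pairs, study.lnc_expr, study.mrna_expr,
        pcc_threshold=cfg.pcc_threshold, module_genes=module_genes,
    )

    result = PipelineResult(
        study=study, filter_reports=reports, mirna_tpm=mirna_tpm,
        de_tables=de_tables, de_sets=de_sets, lnc_classes=lnc_classes,
        mrna_hits=mrna_hits, lnc_hits=lnc_hits, modules=modules,
        module_trait=trait_table, senescence_module=senescence_module,
        mirna_mrna_pairs=mm_pairs, mirna_lnc_pairs=ml_pairs,
        triplets=triplets, triplets_in_module=triplets_in_module,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def _pick_senescence_module(trait_table: pd.DataFrame) -> str:
    """The non-grey module most correlated with mutant second/third leaves."""
    sel = trait_table[
        (trait_table["module"] != coexpr_modules.GREY)
        & (trait_table["trait"].isin(["mutant_second", "mutant_third"]))
    ]
    if sel.empty or sel["r"].isna().all():
        return coexpr_modules.GREY
    return sel.loc[sel["r"].idxmax(), "module"]


def recovery_report(result: PipelineResult) -> dict[str, float]:
    """Compare emitted triplets against the planted truth."""
    truth = {
        (t.lncrna, t.mirna, t.mrna)
        for t in result.study.truth.triplets.itertuples(index=False)
    }
    emitted = {(t.lncrna, t.mirna, t.mrna) for t in result.triplets}
    return {
        "n_planted": len(truth),
        "n_recovered": len(truth & emitted),
        "n_spurious": len(emitted - truth),
    }


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"sample": s, **r.as_dict()} for s, r in result.filter_reports.items()]
    ).to_csv(out / "smallrna_filter_report.tsv", sep="\t", index=False)
    result.mirna_tpm.values.to_csv(out / "mirna_tpm.tsv", sep="\t")
    for cls, tab in result.de_tables.items():
        tab.to_csv(out / f"de_{cls}.tsv", sep="\t", index=False)
    result.lnc_classes.to_csv(out / "lncrna_classes.tsv", sep="\t", index=False)
    result.mrna_hits.to_csv(out / "target_hits_mrna.tsv", sep="\t", index=False)
    result.lnc_hits.to_csv(out / "target_hits_lncrna.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene": g, "module": m.label}
            for m in result.modules for g in m.genes
        ]
    ).to_csv(out / "module_membership.tsv", sep="\t", index=False)
    result.module_trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    cerna_network.triplet_table(result.triplets).to_csv(
        out / "cerna_triplets.tsv", sep="\t", index=False
    )
    cerna_network.export_network(
        result.triplets, str(out / "cerna_network.sif"),
        str(out / "cerna_network.graphml"),
    )
    logger.info("write_results: outputs in %s", out)
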