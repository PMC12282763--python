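"""End-to-end orchestration: alignments in, refined CHIP predictions out.

Stage order for one subject: track -> merge (with any external call sets) ->
consequence annotation + functional filter -> featurize -> predict ->
refine -> credible intervals.  Multi-subject cohorts add the cohort filter
after refinement.  Per-stage record counts are collected so conservation
(records out + records filtered == records in) is auditable; identical
inputs, configuration and seeds give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .classifier import VariantClassifier
from .feature_annot import (
    Consequence,
    FUNCTIONAL_CONSEQUENCES,
    GeneModel,
    ResourceTables,
    build_feature_vector,
    classify_consequence,
)
from .meta_caller import MergedCall, merge_callsets
from .refine_ci import (
    BackgroundModel,
    Prediction,
    RefineFlag,
    RefinementConfig,
    chip_posterior,
    rescue_rules,
)
from .variant_model import VariantType
from .vartracker import CallRecord, PileupConfig, genotype_candidates, pileup_sites

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_final_vcf"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs for a single-subject run; every stochastic step is seeded."""

    pileup: PileupConfig = field(default_factory=PileupConfig)
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    min_alt_reads: int = 1
    rng_seed: int = 0


@dataclass
class PipelineResult:
    """Everything a downstream consumer needs from one subject's run."""

    merged: list[MergedCall]
    consequences: dict
    predictions: list[tuple[MergedCall, Prediction]]
    stage_counts: dict[str, int]
    features: Mapping[str, pd.DataFrame]

    def chip_calls(self) -> list[tuple[MergedCall, Prediction]]:
        """Calls whose effective label after refinement is CHIP."""
        keep = []
        for mc, pred in self.predictions:
            if (
                pred.label == "CHIP" and pred.refined_flag != RefineFlag.GERMLINE_BY_VAF
            ) or pred.refined_flag in (
                RefineFlag.PUTATIVE_CHIP_RESCUED,
                RefineFlag.PUTATIVE_CHIP_VAF_REVIEW,
            ):
                keep.append((mc, pred))
        return keep


def run_pipeline(
    alignments,
    ref_seqs: Mapping[str, str],
    gene_model: GeneModel,
    models: Mapping[str, VariantClassifier],
    resources: ResourceTables,
    external_callsets: Sequence[tuple[str, Sequence[CallRecord]]] = (),
    background: BackgroundModel | None = None,
    region: tuple[str, int, int] | None = None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full single-subject discovery chain.

    ``models`` maps variant type ("SNV", "INDEL") to a fitted classifier;
    variant types without a model are dropped at the featurize stage (and
    counted).  ``background`` enables credible intervals on CHIP calls.
    """
    cfg = cfg or PipelineConfig()
    counts: dict[str, int] = {}

    # 1. track
    sites = pileup_sites(alignments, ref_seqs, region=region, cfg=cfg.pileup)
    tracker = genotype_candidates(
        sites, ref_seqs, min_alt_reads=cfg.min_alt_reads, rng_seed=cfg.rng_seed
    )
    counts["tracker_calls"] = len(tracker)

    # 2. merge
    callsets = [("TRACKER", tracker), *external_callsets]
    merged, summary = merge_callsets(callsets, ref_seqs)
    counts["merge_input_records"] = summary.records_in
    counts["merge_skipped"] = summary.records_skipped
    counts["merged_calls"] = len(merged)

    # 3. annotate + functional filter
    consequences: dict = {}
    functional: list[MergedCall] = []
    for mc in merged:
        cq = classify_consequence(mc.variant, gene_model, ref_seqs)
        consequences[mc.key] = cq
        if cq in FUNCTIONAL_CONSEQUENCES:
            functional.append(mc)
    counts["functional_calls"] = len(functional)
    counts["nonfunctional_filtered"] = len(merged) - len(functional)

    # 4. featurize (SNV and INDEL streams separately)
    streams: dict[str, list[MergedCall]] = {"SNV": [], "INDEL": []}
    for mc in functional:
        vt = "SNV" if mc.variant.vtype is VariantType.SNV else "INDEL"
        streams[vt].append(mc)
    features: dict[str, pd.DataFrame] = {}
    dropped_no_model = 0
    for vt, calls in streams.items():
        if not calls:
            continue
        if vt not in models:
            dropped_no_model += len(calls)
            continue
        vecs = [
            build_feature_vector(mc, mc.site, consequences[mc.key], resources, ref_seqs)
            for mc in calls
        ]
        features[vt] = pd.DataFrame(vecs).reset_index(drop=True)
    counts["featurized"] = sum(len(df) for df in features.values())
    counts["dropped_no_model"] = dropped_no_model

    # 5. predict, 6. refine, 7. credible intervals
    predictions: list[tuple[MergedCall, Prediction]] = []
    for vt, df in features.items():
        clf = models[vt]
        proba = clf.predict_proba(df)
        labels = clf.predict(df)
        for mc, lab, p in zip(streams[vt], labels, proba):
            pred = Prediction(
                label=str(lab),
                prob_chip=float(p[0]),
                prob_germline=float(p[1]),
                prob_artifact=float(p[2]),
            )
            gene = gene_model.gene_at(mc.variant.chrom, mc.variant.pos)
            pred = rescue_rules(pred, mc, gene, resources, cfg.refinement)
            if background is not None and (
                pred.label == "CHIP"
                or pred.refined_flag
                in (RefineFlag.PUTATIVE_CHIP_RESCUED, RefineFlag.PUTATIVE_CHIP_VAF_REVIEW)
            ):
                best = mc.best_evidence
                params = background.params_for(mc.key.chrom, mc.key.pos, gene)
                posterior, ci = chip_posterior(
                    best.alt_count, best.depth, params, background.chip_incidence
                )
                pred = Prediction(
                    pred.label,
                    pred.prob_chip,
                    pred.prob_germline,
                    pred.prob_artifact,
                    pred.refined_flag,
                    posterior_chip=posterior,
                    ci95=ci,
                )
            predictions.append((mc, pred))
    predictions.sort(key=lambda t: (t[0].key.chrom, t[0].key.pos))
    counts["predictions"] = len(predictions)
    for stage, n in counts.items():
        logger.info("stage %s: %d records", stage, n)
    return PipelineResult(merged, consequences, predictions, counts, features)


def write_final_vcf(
    result: PipelineResult, path: str, contigs: Mapping[str, int]
) -> None:
    """Write refined predictions as VCF v4.2 with prediction INFO fields."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("PRED", 1, "String", "Predicted class")
    header.info.add("PPROB", 3, "Float", "P(CHIP), P(GERMLINE), P(ARTIFACT)")
    header.info.add("REFINE", 1, "String", "Refinement flag")
    header.info.add("PCHIP", 1, "Float", "Posterior clone probability")
    header.info.add("CI95LO", 1, "Float", "Clone VAF credible interval, lower")
    header.info.add("CI95HI", 1, "Float", "Clone VAF credible interval, upper")
    header.info.add("STATUS", 1, "Integer", "Number of callers")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for mc, pred in result.predictions:
            rec = vcf.new_record(
                contig=mc.variant.chrom,
                start=mc.variant.pos - 1,
                alleles=(mc.variant.ref, mc.variant.alt),
            )
            rec.info["PRED"] = pred.label
            rec.info["PPROB"] = (pred.prob_chip, pred.prob_germline, pred.prob_artifact)
            rec.info["REFINE"] = pred.refined_flag.value
            if pred.posterior_chip is not None:
                rec.info["PCHIP"] = pred.posterior_chip
                rec.info["CI95LO"] = pred.ci95[0]
                rec.info["CI95HI"] = pred.ci95[1]
            rec.info["STATUS"] = mc.status
            vcf.write(rec)
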