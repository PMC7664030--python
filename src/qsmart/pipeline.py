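"""End-to-end pipeline: assembly -> features -> interactions -> screening
-> selection -> model -> evaluation.

Each cancer group gets its own training set and model. Given a fixed
seed the whole run is deterministic, and every artifact embeds the
configuration hash and seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import cohort, features as feats, interactions as inter
from .config import PipelineConfig
from .evaluation import evaluate
from .io import FeatureMatrix
from .model import escalation_schedule, fit_linear, network_spec_from
from .properties import AminoAcidPropertyTable
from .selection import LassoBicSelector, vif_stepwise_screen
from .simulate import Bundle

log = logging.getLogger("qsmart")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return wrapped
    return deco


@_stage("assembly")
def _assemble(config: PipelineConfig, bundle: Bundle):
    ann = bundle.drug_annotations
    pki_ids = []
    for rec in ann.itertuples(index=False):
        labels = frozenset(
            str(rec.action_labels).split(";")) if rec.action_labels else frozenset()
        control = getattr(rec, "kinomescan_control", None)
        record = cohort.DrugAnnotationRecord(
            drug_id=str(rec.drug_id),
            molecular_weight=float(rec.molecular_weight),
            action_labels=labels,
            kinomescan_control=None if pd.isna(control) else float(control))
        if cohort.classify_pki(record, mw_max=config.mw_max,
                               control_max=config.kinomescan_control_max):
            pki_ids.append(record.drug_id)
    responses = bundle.responses[
        bundle.responses["drug_id"].isin(pki_ids)].reset_index(drop=True)

    responses, exclusions = cohort.merge_duplicate_assays(
        responses, r_min=config.duplicate_r_min)

    cell_recs = [cohort.CellLineRecord(
        cell_line_id=str(r.cell_line_id), wgs_flag=int(r.wgs_flag),
        has_expression=int(r.has_expression),
        primary_site=str(r.primary_site),
        primary_histology=str(getattr(r, "primary_histology", "")),
        histology_subtype=str(getattr(r, "histology_subtype", "")))
        for r in bundle.cell_lines.itertuples(index=False)]
    kept_lines, removal = cohort.filter_cell_lines(
        cell_recs, responses, bundle.mutations,
        min_responses=config.min_cell_line_responses)
    responses = responses[
        responses["cell_line_id"].isin(kept_lines)].reset_index(drop=True)

    groups, excluded = cohort.assign_cancer_groups(
        [r for r in cell_recs if r.cell_line_id in set(kept_lines)],
        responses, min_group_responses=config.min_group_responses)
    responses = responses.assign(cancer_group=groups.to_numpy())
    responses = responses.dropna(subset=["cancer_group"]).reset_index(drop=True)
    return responses, {"excluded_drugs": exclusions,
                       "cell_line_removals": removal,
                       "excluded_groups": excluded}


@_stage("features")
def _build_matrix(bundle: Bundle, responses: pd.DataFrame) -> FeatureMatrix:
    lines = sorted(responses["cell_line_id"].unique())
    props = AminoAcidPropertyTable()
    residue = feats.residue_delta_features(bundle.mutations, props, lines)
    counts, count_tags = feats.rollup_features(bundle.mutations,
                                               bundle.annotations, lines)
    gene_block = feats.gene_level_features(bundle.mutations,
                                           bundle.expression, bundle.cnv,
                                           lines)
    sample = bundle.sample_table.set_index("cell_line_id").reindex(lines)
    dummies, _ = feats.dummy_code(sample)
    cell_block = pd.concat([residue, counts, gene_block, dummies], axis=1)

    fp = bundle.drug_fingerprints.set_index("drug_id")
    per_resp = pd.concat([
        fp.reindex(responses["drug_id"]).reset_index(drop=True),
        cell_block.reindex(responses["cell_line_id"]).reset_index(drop=True),
    ], axis=1)
    per_resp["From_Sanger"] = responses["source_flag"].to_numpy(float)
    per_resp.index = responses.index

    levels: dict[str, str] = {}
    for c in per_resp.columns:
        if c in fp.columns:
            levels[c] = "drug"
        elif c in residue.columns:
            levels[c] = "residue"
        elif c in counts.columns:
            levels[c] = count_tags[c]
        elif c.startswith(("EXP_", "CNV_", "MUTCOUNT_")):
            levels[c] = "gene"
        else:
            levels[c] = "sample"

    # constant columns carry no information within the group
    keep = [c for c in per_resp.columns if per_resp[c].nunique() > 1]
    dropped = len(per_resp.columns) - len(keep)
    if dropped:
        log.info("dropped %d constant feature column(s)", dropped)
    return FeatureMatrix(per_resp[keep].astype(float),
                         {c: levels[c] for c in keep})


@_stage("interactions")
def _interactions(config: PipelineConfig, bundle: Bundle,
                  matrix: FeatureMatrix, y: np.ndarray):
    candidates = inter.build_drug_mutation_terms(matrix)
    candidates += inter.build_ppi_terms(
        matrix, bundle.ppi_edges, bundle.kinase_genes,
        score_min=config.ppi_score_min)
    namespaces = dict(zip(bundle.annotations["entity_id"],
                          bundle.annotations["entity_level"]))
    namespaces = {k: v for k, v in namespaces.items()
                  if v in inter.SETLEVEL_TYPES}
    candidates += inter.build_setlevel_terms(matrix, namespaces,
                                             bundle.hierarchy)
    values, tested = inter.score_terms(matrix, candidates, y,
                                      min_nonzero=config.min_nonzero)
    retained = inter.filter_terms(tested, alpha=config.fdr_alpha,
                                  min_nonzero=config.min_nonzero)
    levels = {t.name: "interaction" for t in retained}
    for t in retained:  # carry component metadata alongside the terms
        for comp in t.components:
            levels.setdefault(comp, matrix.levels[comp])
    block = FeatureMatrix(values[[t.name for t in retained]], levels,
                          {t.name: t.components for t in retained})
    return block, inter.stats_table(tested)


@_stage("screening")
def _screen(config: PipelineConfig, matrix: FeatureMatrix):
    drug_cols = [c for c in matrix.feature_names
                 if matrix.levels[c] == "drug"]
    expr_cols = [c for c in matrix.feature_names if c.startswith("EXP_")]
    keep = set(matrix.feature_names)
    reports = {}
    if len(drug_cols) > 1:
        kept, rep = vif_stepwise_screen(
            matrix.values[drug_cols],
            priority=feats.rank_drug_features(drug_cols),
            vif_max=config.vif_max)
        keep -= set(drug_cols) - set(kept)
        reports["drug"] = rep
    if len(expr_cols) > 1:
        kept, rep = vif_stepwise_screen(matrix.values[expr_cols],
                                        vif_max=config.vif_max)
        keep -= set(expr_cols) - set(kept)
        reports["expression"] = rep
    screened = matrix.select([c for c in matrix.feature_names if c in keep])
    return screened, reports


def run_pipeline(config: PipelineConfig, bundle: Bundle,
                 train_networks: bool = True) -> dict:
    """Run every stage on a bundle; one model per retained cancer group.

    Returns a dict with per-group models (linear view always; network
    view when ``train_networks``), evaluation reports, interaction
    statistics, screening reports, and assembly bookkeeping. Deterministic
    given ``config.seed``.
    """
    meta = {"config_hash": config.hash(), "seed": config.seed}
    responses, assembly_info = _assemble(config, bundle)
    result = {"models": {}, "reports": {}, "interaction_stats": {},
              "screening": {}, "schedule_traces": {}, "designs": {},
              "assembly": assembly_info, **meta}
    if responses.empty:
        log.warning("no responses survive assembly; empty model set")
        return result

    for group in sorted(responses["cancer_group"].unique()):
        sub = responses[responses["cancer_group"] == group]
        sub = sub.reset_index(drop=True)
        y = sub["log_ic50"].to_numpy(float)
        matrix = _build_matrix(bundle, sub)
        term_block, stats = _interactions(config, bundle, matrix, y)
        screened, screen_reports = _screen(config, matrix)
        design = screened.concat(term_block)

        selector = LassoBicSelector().fit(design.values, y)
        selected = design.values[selector.selected_features_]

        model = fit_linear(selected, y, metadata={
            **meta, "group": group, "bic": selector.bic_,
            "k": selector.k_, "n": selector.n_})
        trace = None
        if train_networks and selector.k_ > 0:
            net, trace = escalation_schedule(
                selected, y, schedule=config.iteration_schedule,
                threshold=config.performance_threshold, seed=config.seed,
                cv=config.cv_folds, l1_grid=config.l1_grid)
            model = network_spec_from(net, base=model)
            preds = net.predict(selected)
            report = evaluate(preds, y, config.roc_thresholds,
                              metadata={**meta, "group": group,
                                        "cv_r2": net.cv_r2_})
        else:
            preds = model.predict(selected, view="linear")
            report = evaluate(preds, y, config.roc_thresholds,
                              metadata={**meta, "group": group})
        result["models"][group] = model
        result["designs"][group] = selected
        result["reports"][group] = report
        result["interaction_stats"][group] = stats
        result["screening"][group] = screen_reports
        result["schedule_traces"][group] = trace
    return result
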