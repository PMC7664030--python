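"""Synthetic input bundles with known ground truth.

The generator emulates every table the pipeline consumes — drug
fingerprints and annotations, drug responses from two assay centers,
cell-line mutation profiles mapped to reference-PKA positions, expression
and copy-number matrices, gene -> entity annotation maps with an ontology
hierarchy, and a scored PPI edge list — and plants a known response
surface on top of them: a handful of main effects, an additive batch
effect on the assay-source flag, one interaction term of each buildable
class (drug x mutation, expression-weighted PPI, GO-process product), and
an exactly collinear fingerprint block that the VIF screen must remove.

Responses follow the linear structure-mutation-activity form evaluated on
the generated features plus Gaussian noise; the noise standard deviation
defaults to the value giving a signal-to-noise ratio of 10. The planted
truth (coefficients, realized noiseless signal, noise sigma) is emitted
alongside the bundle so recovery is a well-posed measurement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feats
from .properties import AminoAcidPropertyTable

log = logging.getLogger("qsmart")

# charge-changing substitutions planted at the hot-spot position
_HOTSPOT_SUBS = [("L", "R"), ("E", "K"), ("G", "R"), ("L", "K")]
_NEUTRAL_SUBS = [("L", "V"), ("A", "T"), ("I", "V"), ("S", "T"),
                 ("F", "Y"), ("M", "I"), ("V", "A"), ("T", "S")]

HOTSPOT_POSITION = 187  # reference-PKA activation-segment position


@dataclass
class PlantedInteraction:
    term_type: str
    components: tuple[str, str]
    coefficient: float

    @property
    def name(self) -> str:
        a, b = self.components
        if self.term_type == "drug_mutation":
            return f"{a}_X_{b}"
        lo, hi = sorted(self.components)
        return f"{lo}_X_{hi}"


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic bundle."""

    n_drugs: int = 40
    n_cell_lines: int = 50
    n_fingerprint_bits: int = 16
    n_genes: int = 25          # first n_kinases are kinases
    n_kinases: int = 15
    n_go_terms: int = 6
    n_reactions: int = 3
    n_pathways: int = 3
    intercept: float = -2.0  # places log-IC50 across the ROC thresholds
    main_effects: dict[str, float] = field(default_factory=lambda: {
        "Fingerprint_800": 1.0, "EXP_KIN03": 0.6})
    batch_effect: float = -0.5  # From_Sanger coefficient
    interactions: list[PlantedInteraction] = field(default_factory=lambda: [
        PlantedInteraction("drug_mutation",
                           (f"PKA_{HOTSPOT_POSITION}_CHA", "Fingerprint_805"),
                           1.2),
        PlantedInteraction("ppi", ("EXP_GEN03", "EXP_KIN07"), 1.0),
        PlantedInteraction("go_process", ("GO_0030324", "GO_0048675"), 0.8),
    ])
    hotspot_rate: float = 0.35  # cell lines mutated at the hot-spot
    fingerprint_p: float = 0.4
    mutations_per_line: float = 2.0  # Poisson rate on top of 1 guaranteed
    expression_sigma: float = 0.8
    noise_sigma: float | None = None  # derived from snr when None
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma is not None and self.noise_sigma <= 0:
            raise ValueError("noise sigma must be positive")
        if self.n_kinases > self.n_genes:
            raise ValueError("n_kinases cannot exceed n_genes")


@dataclass
class Bundle:
    """Complete synthetic input set plus planted ground truth."""

    responses: pd.DataFrame
    drug_fingerprints: pd.DataFrame  # drug_id x Fingerprint_* bits
    drug_annotations: pd.DataFrame
    cell_lines: pd.DataFrame
    mutations: pd.DataFrame
    expression: pd.DataFrame         # genes x cell lines
    cnv: pd.DataFrame
    annotations: pd.DataFrame        # gene, entity_id, entity_level
    hierarchy: pd.DataFrame          # child, parent
    ppi_edges: pd.DataFrame          # protein1, protein2, combined_score
    sample_table: pd.DataFrame
    kinase_genes: set[str]
    ground_truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("responses", "drug_fingerprints", "drug_annotations",
                     "cell_lines", "mutations", "annotations", "hierarchy",
                     "ppi_edges", "sample_table"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        self.expression.to_csv(outdir / "expression.csv")
        self.cnv.to_csv(outdir / "cnv.csv")
        truth = dict(self.ground_truth)
        truth["signal"] = list(map(float, truth["signal"]))
        truth["kinase_genes"] = sorted(self.kinase_genes)
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def _fingerprint_bit_ids(n: int) -> tuple[list[int], dict[int, int]]:
    """Bit indices: planted/independent bits plus an exactly collinear
    pair at low positions (copies of higher-priority bits)."""
    special = [800, 805, 810, 820]
    fillers = [100 + 10 * i for i in range(max(n - 6, 0))]
    independent = special + fillers
    collinear = {5: 810, 6: 820}  # low bit -> source bit it duplicates
    return independent, collinear


def simulate_bundle(spec: SimulationSpec | None = None) -> Bundle:
    """Generate a full input bundle under the planted response model."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    props = AminoAcidPropertyTable()

    drugs = [f"D{i:02d}" for i in range(1, spec.n_drugs + 1)]
    lines = [f"CL{i:03d}" for i in range(1, spec.n_cell_lines + 1)]
    kinases = [f"KIN{i:02d}" for i in range(1, spec.n_kinases + 1)]
    others = [f"GEN{i:02d}" for i in
              range(1, spec.n_genes - spec.n_kinases + 1)]
    genes = kinases + others

    # --- drugs -----------------------------------------------------------
    indep_bits, collinear = _fingerprint_bit_ids(spec.n_fingerprint_bits)
    fp = pd.DataFrame(index=pd.Index(drugs, name="drug_id"))
    for b in indep_bits:
        fp[f"Fingerprint_{b}"] = rng.binomial(1, spec.fingerprint_p,
                                              spec.n_drugs)
    for low, src in collinear.items():
        fp[f"Fingerprint_{low}"] = fp[f"Fingerprint_{src}"]
    fp = fp[[c for c in sorted(fp.columns,
                               key=lambda c: feats.fingerprint_bit(c))]]
    drug_ann = pd.DataFrame({
        "drug_id": drugs,
        "molecular_weight": rng.uniform(350, 650, spec.n_drugs).round(1),
        "action_labels": "inhibitor",
        "kinomescan_control": rng.uniform(0.1, 4.0, spec.n_drugs).round(2),
    })

    # --- mutations -------------------------------------------------------
    positions = [p for p in range(20, 20 + 40) if p != HOTSPOT_POSITION]
    mut_rows = []
    for cl in lines:
        n_mut = 1 + rng.poisson(spec.mutations_per_line)
        for _ in range(n_mut):
            gene = kinases[rng.integers(len(kinases))]
            wild, mutant = _NEUTRAL_SUBS[rng.integers(len(_NEUTRAL_SUBS))]
            pos = positions[rng.integers(len(positions))]
            mut_rows.append((cl, gene, wild, mutant, pos))
        if rng.random() < spec.hotspot_rate:
            gene = kinases[rng.integers(len(kinases))]
            wild, mutant = _HOTSPOT_SUBS[rng.integers(len(_HOTSPOT_SUBS))]
            mut_rows.append((cl, gene, wild, mutant, HOTSPOT_POSITION))
    mutations = pd.DataFrame(
        mut_rows, columns=["cell_line_id", "gene", "wild", "mutant",
                           "pka_position"])
    mutations["pka_position"] = mutations["pka_position"].astype(float)

    # --- omics -----------------------------------------------------------
    expression = pd.DataFrame(
        np.exp(rng.normal(0.0, spec.expression_sigma,
                          (len(genes), len(lines)))).round(6),
        index=pd.Index(genes, name="gene"), columns=lines)
    cnv = pd.DataFrame(
        rng.choice([1, 2, 2, 2, 3], (len(genes), len(lines))).astype(float),
        index=pd.Index(genes, name="gene"), columns=lines)

    # --- annotations and hierarchy --------------------------------------
    ann_rows = []
    go_ids = ["GO_0030324", "GO_0048675", "GO_0060479"] + [
        f"GO_{9000000 + i}" for i in range(max(spec.n_go_terms - 3, 0))]
    go_sets = {"GO_0030324": kinases[0:3], "GO_0048675": kinases[3:6],
               # child term annotated to a subset of its parent's genes
               "GO_0060479": kinases[0:2]}
    for gid in go_ids[3:]:
        size = int(rng.integers(2, 5))
        go_sets[gid] = list(rng.choice(kinases, size, replace=False))
    for gid, members in go_sets.items():
        ann_rows += [(g, gid, "go") for g in members]
    for i in range(spec.n_reactions):
        members = rng.choice(kinases, int(rng.integers(2, 5)), replace=False)
        ann_rows += [(g, f"REC_{i + 1:03d}", "reaction") for g in members]
    for i in range(spec.n_pathways):
        members = rng.choice(kinases, int(rng.integers(2, 5)), replace=False)
        ann_rows += [(g, f"PWY_{i + 1:03d}", "pathway") for g in members]
    annotations = pd.DataFrame(ann_rows,
                               columns=["gene", "entity_id", "entity_level"])
    hierarchy = pd.DataFrame({"child": ["GO_0060479"],
                              "parent": ["GO_0030324"]})

    # --- PPI edges -------------------------------------------------------
    ppi_rows = [("GEN03", "KIN07", 950)]  # the planted edge
    while len(ppi_rows) < 12:
        a, b = rng.choice(genes, 2, replace=False)
        ppi_rows.append((a, b, int(rng.integers(720, 999))))
    ppi_rows += [("KIN01", "KIN01", 980),   # self edge: must be rejected
                 ("KIN02", "GEN01", 650)]   # below score threshold
    ppi_edges = pd.DataFrame(ppi_rows,
                             columns=["protein1", "protein2",
                                      "combined_score"])

    # --- cell lines and samples ------------------------------------------
    cell_lines = pd.DataFrame({
        "cell_line_id": lines, "wgs_flag": 1, "has_expression": 1,
        "primary_site": "lung", "primary_histology": "carcinoma",
        "histology_subtype": "adenocarcinoma",
    })
    sample_table = pd.DataFrame({
        "cell_line_id": lines,
        "msi_status": rng.choice(["MSS", "MSI"], len(lines), p=[0.8, 0.2]),
    })

    # --- responses from the planted linear form --------------------------
    responses = pd.DataFrame(
        [(d, cl) for d in drugs for cl in lines],
        columns=["drug_id", "cell_line_id"])
    responses["source_flag"] = rng.binomial(1, 0.5, len(responses))

    residue = feats.residue_delta_features(mutations, props, lines)
    go_counts, _ = feats.rollup_features(mutations, annotations, lines)
    gene_block = feats.gene_level_features(mutations, expression, cnv, lines)
    cell_feats = pd.concat([residue, go_counts, gene_block], axis=1)

    per_resp = pd.concat([
        fp.reindex(responses["drug_id"]).reset_index(drop=True),
        cell_feats.reindex(responses["cell_line_id"]).reset_index(drop=True),
    ], axis=1)
    per_resp["From_Sanger"] = responses["source_flag"].to_numpy(float)

    coefficients = dict(spec.main_effects)
    coefficients["From_Sanger"] = spec.batch_effect
    signal = np.full(len(responses), spec.intercept)
    for name, beta in coefficients.items():
        if name not in per_resp.columns:
            raise ValueError(f"planted effect {name!r} absent from schema")
        signal = signal + beta * per_resp[name].to_numpy(float)
    for pi in spec.interactions:
        a, b = pi.components
        for comp in (a, b):
            if comp not in per_resp.columns:
                raise ValueError(
                    f"planted interaction component {comp!r} absent from schema")
        term = per_resp[a].to_numpy(float) * per_resp[b].to_numpy(float)
        signal = signal + pi.coefficient * term
        coefficients[pi.name] = pi.coefficient

    sigma = spec.noise_sigma
    if sigma is None:
        sigma = float(np.sqrt(signal.var() / spec.snr))
    responses["log_ic50"] = (signal
                             + rng.normal(0.0, sigma, len(responses)))

    truth = {
        "intercept": spec.intercept,
        "coefficients": coefficients,
        "planted_features": sorted(coefficients),
        "interaction_terms": [pi.name for pi in spec.interactions],
        "collinear_bits": {f"Fingerprint_{lo}": f"Fingerprint_{src}"
                           for lo, src in collinear.items()},
        "noise_sigma": sigma,
        "signal": signal,
        "seed": spec.seed,
    }
    return Bundle(responses=responses, drug_fingerprints=fp.reset_index(),
                  drug_annotations=drug_ann, cell_lines=cell_lines,
                  mutations=mutations, expression=expression, cnv=cnv,
                  annotations=annotations, hierarchy=hierarchy,
                  ppi_edges=ppi_edges, sample_table=sample_table,
                  kinase_genes=set(kinases), ground_truth=truth)


def recovery_harness(spec: SimulationSpec, config=None,
                     train_networks: bool = False) -> dict:
    """Run the full pipeline on a simulated bundle; score recovery.

    Returns support precision/recall against the planted features, sign
    agreement and RMSE of the recovered linear-view coefficients, and the
    pipeline report.
    """
    from .pipeline import run_pipeline
    from .config import PipelineConfig

    config = config or PipelineConfig(seed=spec.seed)
    config.seed = spec.seed
    bundle = simulate_bundle(spec)
    result = run_pipeline(config, bundle, train_networks=train_networks)
    planted = {k: v for k, v in
               bundle.ground_truth["coefficients"].items()}

    selected: set[str] = set()
    coef_map: dict[str, float] = {}
    for group, model in result["models"].items():
        selected |= set(model.feature_names)
        coef_map.update(model.coefficients)

    hits = [f for f in planted if f in selected]
    recall = len(hits) / len(planted)
    precision = (len(hits) / len(selected)) if selected else np.nan
    signs = [np.sign(coef_map[f]) == np.sign(planted[f]) for f in hits]
    sign_agreement = float(np.mean(signs)) if signs else np.nan
    errors = [coef_map[f] - planted[f] for f in hits]
    coef_rmse = float(np.sqrt(np.mean(np.square(errors)))) if errors else np.nan
    return {
        "support_recall": recall, "support_precision": precision,
        "sign_agreement": sign_agreement, "coefficient_rmse": coef_rmse,
        "n_selected": len(selected), "planted": sorted(planted),
        "recovered": sorted(hits), "pipeline_result": result,
    }


def reduced_training_check(bundle: Bundle, config=None,
                           fraction: float = 0.9, seed: int = 0) -> dict:
    """Feature-selection stability under a 10% sample reduction.

    Runs selection on the full bundle and on a seeded ``fraction``
    subsample of responses; reports the fraction of fully-trained
    selected features re-selected in the reduced set.
    """
    from .pipeline import run_pipeline
    from .config import PipelineConfig

    config = config or PipelineConfig(seed=seed)
    full = run_pipeline(config, bundle, train_networks=False)
    rng = np.random.default_rng(seed)
    n = len(bundle.responses)
    keep = rng.choice(n, int(round(fraction * n)), replace=False)
    reduced_bundle = Bundle(
        responses=bundle.responses.iloc[np.sort(keep)].reset_index(drop=True),
        drug_fingerprints=bundle.drug_fingerprints,
        drug_annotations=bundle.drug_annotations,
        cell_lines=bundle.cell_lines, mutations=bundle.mutations,
        expression=bundle.expression, cnv=bundle.cnv,
        annotations=bundle.annotations, hierarchy=bundle.hierarchy,
        ppi_edges=bundle.ppi_edges, sample_table=bundle.sample_table,
        kinase_genes=bundle.kinase_genes,
        ground_truth=bundle.ground_truth)
    reduced = run_pipeline(config, reduced_bundle, train_networks=False)

    full_sel: set[str] = set()
    red_sel: set[str] = set()
    for model in full["models"].values():
        full_sel |= set(model.feature_names)
    for model in reduced["models"].values():
        red_sel |= set(model.feature_names)
    overlap = (len(full_sel & red_sel) / len(full_sel)) if full_sel else np.nan
    return {"overlap": overlap, "full_selected": sorted(full_sel),
            "reduced_selected": sorted(red_sel)}
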