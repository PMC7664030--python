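"""Cohort assembly: kinase-inhibitor definition, duplicate-assay merging,
cell-line filtering, and cancer-group assignment.

Training sets are cancer-type-centric. A drug qualifies as a small-molecule
protein kinase inhibitor (PKI) below 900 Da if it carries an inhibitory
action label from the drug-kinase association sources or a KINOMEscan
percent-of-control below 5. Assays screened by both contributing centers
are merged by weighted mean only when the two centers' log-IC50 profiles
correlate (Pearson r > 0.7) across shared cell lines; otherwise the drug
is excluded. Cell lines must be whole-genome sequenced, have expression
data, at least 30 response entries, and at least one mutation mapping to
the reference PKA coordinate system. Groups are primary sites, with the
haematopoietic-and-lymphoid and lung groups split by histology, and groups
below 1000 responses excluded for low statistical power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger("qsmart")

INHIBITORY_LABELS = frozenset({"inhibitor", "antagonist", "suppressor"})

#: Lung histology subtypes that constitute non-small cell lung cancer.
NSCLC_SUBTYPES = frozenset({
    "adenocarcinoma",
    "non-small cell carcinoma",
    "squamous cell carcinoma",
    "large cell carcinoma",
    "giant cell carcinoma",
    "mixed adenosquamous carcinoma",
})

HAEM_LYMPH_SITE = "haematopoietic_and_lymphoid_tissue"


@dataclass(frozen=True)
class DrugAnnotationRecord:
    drug_id: str
    molecular_weight: float
    action_labels: frozenset[str] = frozenset()
    kinomescan_control: float | None = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.drug_id}: molecular weight must be positive")


@dataclass(frozen=True)
class CellLineRecord:
    cell_line_id: str
    wgs_flag: int
    has_expression: int
    primary_site: str
    primary_histology: str = ""
    histology_subtype: str = ""

    def __post_init__(self) -> None:
        if self.wgs_flag not in (0, 1) or self.has_expression not in (0, 1):
            raise ValueError(f"{self.cell_line_id}: flags must be 0/1")


def classify_pki(rec: DrugAnnotationRecord, *, mw_max: float = 900.0,
                 control_max: float = 5.0) -> bool:
    """True iff the drug is a small-molecule protein kinase inhibitor.

    Requires molecular weight strictly below ``mw_max`` daltons and either
    an inhibitory action label (inhibitor / antagonist / suppressor) or a
    KINOMEscan percent-of-control strictly below ``control_max``.
    """
    if rec.molecular_weight >= mw_max:
        return False
    labels = {str(x).lower() for x in rec.action_labels}
    if labels & INHIBITORY_LABELS:
        return True
    return (rec.kinomescan_control is not None
            and rec.kinomescan_control < control_max)


def merge_duplicate_assays(
    responses: pd.DataFrame, *, r_min: float = 0.7, min_shared: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge drug x cell-line pairs assayed by both sources.

    ``responses`` columns: drug_id, cell_line_id, log_ic50, source_flag,
    optional weight (replicate count; defaults to 1, giving the arithmetic
    mean). For each drug present under both source flags, the Pearson r of
    log-IC50 over shared cell lines decides its fate: r > ``r_min`` merges
    each shared pair by weighted mean, anything else (including fewer than
    ``min_shared`` shared lines) excludes the drug entirely.

    Returns (merged responses, exclusion table with columns drug_id,
    pearson_r, reason). Merging is idempotent: data with a single source
    per pair passes through untouched.
    """
    df = responses.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    exclusions: list[dict] = []
    keep_parts: list[pd.DataFrame] = []

    # a duplicate drug has at least one cell line assayed by both sources
    pair_sources = df.groupby(["drug_id", "cell_line_id"])["source_flag"].nunique()
    duplicate_drugs = set(
        pair_sources.index[pair_sources > 1].get_level_values(0))

    for drug, grp in df.groupby("drug_id", sort=True):
        if drug not in duplicate_drugs:
            keep_parts.append(grp)
            continue
        shared = [cl for cl, g in grp.groupby("cell_line_id")
                  if g["source_flag"].nunique() > 1]
        if len(shared) < 3:
            exclusions.append({"drug_id": drug, "pearson_r": np.nan,
                               "reason": "insufficient overlap"})
            continue
        shared_rows = grp[grp["cell_line_id"].isin(shared)]
        wide = shared_rows.pivot_table(index="cell_line_id",
                                       columns="source_flag",
                                       values="log_ic50")
        r = float(np.corrcoef(wide[0].to_numpy(float),
                              wide[1].to_numpy(float))[0, 1])
        if not r > r_min:
            exclusions.append({"drug_id": drug, "pearson_r": r,
                               "reason": f"correlation <= {r_min}"})
            continue
        merged = []
        for cl, rows in grp.groupby("cell_line_id"):
            w = rows["weight"].to_numpy(float)
            y = rows["log_ic50"].to_numpy(float)
            merged.append({
                "drug_id": drug, "cell_line_id": cl,
                "log_ic50": float(np.average(y, weights=w)),
                # a genuinely merged pair spans both centers: tag Sanger-side
                "source_flag": (1 if rows["source_flag"].nunique() > 1
                                else int(rows["source_flag"].iloc[0])),
                "weight": float(w.sum()),
            })
        part = pd.DataFrame(merged)
        for col in grp.columns:
            if col not in part.columns:
                part[col] = grp[col].iloc[0]
        keep_parts.append(part[grp.columns])
        log.info("merged duplicate drug %s (r=%.3f, %d shared lines)",
                 drug, r, len(shared))

    out = (pd.concat(keep_parts, ignore_index=True) if keep_parts
           else df.iloc[0:0].copy())
    excl = pd.DataFrame(exclusions, columns=["drug_id", "pearson_r", "reason"])
    return out.reset_index(drop=True), excl


def filter_cell_lines(
    cells: Iterable[CellLineRecord],
    responses: pd.DataFrame,
    mutations: pd.DataFrame,
    *, min_responses: int = 30,
) -> tuple[list[str], dict[str, int]]:
    """Retain cell lines passing all four quality criteria.

    Criteria: (1) mutation profile from whole-genome sequencing, (2) at
    least ``min_responses`` drug-response entries, (3) expression profile
    available, (4) at least one mutation mapping to a reference PKA
    position. Returns (retained ids, per-criterion removal counts).
    ``mutations`` needs columns cell_line_id and pka_position (NaN when
    unmapped).
    """
    n_resp = responses.groupby("cell_line_id").size()
    mapped = mutations.dropna(subset=["pka_position"])
    has_mapped = set(mapped["cell_line_id"])
    removed = {"no_wgs": 0, "few_responses": 0, "no_expression": 0,
               "no_mapped_mutation": 0}
    kept: list[str] = []
    for rec in cells:
        ok = True
        if rec.wgs_flag != 1:
            removed["no_wgs"] += 1
            ok = False
        if int(n_resp.get(rec.cell_line_id, 0)) < min_responses:
            removed["few_responses"] += 1
            ok = False
        if rec.has_expression != 1:
            removed["no_expression"] += 1
            ok = False
        if rec.cell_line_id not in has_mapped:
            removed["no_mapped_mutation"] += 1
            ok = False
        if ok:
            kept.append(rec.cell_line_id)
    return kept, removed


def _group_for(rec: CellLineRecord) -> str:
    site = rec.primary_site.strip().lower().replace(" ", "_")
    if site == HAEM_LYMPH_SITE:
        hist = rec.primary_histology.strip().lower()
        return "haematopoietic" if "haematopoietic" in hist else "lymphoid"
    if site == "lung":
        if rec.histology_subtype.strip().lower() in NSCLC_SUBTYPES:
            return "lung_nsclc"
        return "lung_others"
    return site


def assign_cancer_groups(
    cells: Iterable[CellLineRecord],
    responses: pd.DataFrame,
    *, min_group_responses: int = 1000,
) -> tuple[pd.Series, list[str]]:
    """Assign a cancer-group label to every response; drop small groups.

    Group = primary site, except the haematopoietic-and-lymphoid split by
    primary histology and the lung split into NSCLC (six listed subtypes)
    versus "lung_others". Groups with fewer than ``min_group_responses``
    responses are excluded. Returns (labels aligned to responses, with NaN
    for excluded groups; list of excluded group names).
    """
    group_of = {rec.cell_line_id: _group_for(rec) for rec in cells}
    labels = responses["cell_line_id"].map(group_of)
    sizes = labels.value_counts()
    excluded = sorted(sizes.index[sizes < min_group_responses])
    if excluded:
        log.info("excluding groups below %d responses: %s",
                 min_group_responses, excluded)
    labels = labels.where(~labels.isin(excluded))
    return labels, excluded
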