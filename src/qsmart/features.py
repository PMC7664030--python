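"""Drug and multi-omics cell-line feature engineering.

The design matrix has a drug block and a seven-level cell-line block:

* residue level — per reference-PKA position, the summed physicochemical
  perturbation of that cell line's kinase mutations mapping there
  (``PKA_<pos>_<PROP>`` with PROP in MUT/CHA/POL/HYD/ASA/VOL/ENE/BLO);
* motif / domain / family / pathway (reaction, pathway, GO process)
  levels — per annotation entity, the number of the cell line's kinase
  mutations annotated to that entity;
* gene level — per-gene mutation count plus expression and copy-number
  passthrough;
* sample level — dummy-coded categorical sample descriptors.

Drug features are fingerprint bits and chemical descriptors consumed as a
table, with a priority order (later fingerprint bits encode more complex
substructures and outrank earlier bits; all fingerprints outrank
descriptors) used downstream by collinearity screening.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .properties import AminoAcidPropertyTable, PROPERTY_CODES

log = logging.getLogger("qsmart")

_FP_RE = re.compile(r"^Fingerprint_(\d+)$")

#: annotation entity level -> FeatureMatrix level tag
ENTITY_LEVEL_TAG = {
    "motif": "motif", "domain": "domain", "family": "family",
    "reaction": "pathway", "pathway": "pathway", "go": "pathway",
}


def residue_delta_features(
    mutations: pd.DataFrame,
    props: AminoAcidPropertyTable | None = None,
    cell_lines: list[str] | None = None,
) -> pd.DataFrame:
    """Residue-level mutation perturbation features per cell line.

    ``mutations`` columns: cell_line_id, wild, mutant, pka_position.
    For each observed (position, property) the value is the sum over that
    cell line's mutations at the position of property(mutant) -
    property(wild); BLO is the BLOSUM62 score of the substitution and MUT
    the mutation count. Mutations with no mapped position or a
    non-canonical residue letter are skipped and logged.
    """
    props = props or AminoAcidPropertyTable()
    rows: dict[str, dict[str, float]] = {}
    n_skipped = 0
    for rec in mutations.itertuples(index=False):
        pos = rec.pka_position
        if pd.isna(pos):
            n_skipped += 1
            continue
        wild, mutant = str(rec.wild), str(rec.mutant)
        if not (props.is_canonical(wild) and props.is_canonical(mutant)):
            log.warning("skipping non-canonical substitution %s->%s in %s",
                        wild, mutant, rec.cell_line_id)
            continue
        pos = int(pos)
        cell = rows.setdefault(str(rec.cell_line_id), {})
        for prop in PROPERTY_CODES:
            name = f"PKA_{pos}_{prop}"
            if prop == "MUT":
                val = 1.0
            elif prop == "BLO":
                val = props.substitution_score(wild, mutant)
            else:
                val = props.delta(prop, wild, mutant)
            cell[name] = cell.get(name, 0.0) + val
    if n_skipped:
        log.info("skipped %d mutation(s) without a reference PKA position",
                 n_skipped)
    index = cell_lines if cell_lines is not None else sorted(rows)
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(index)
    out = out.fillna(0.0).sort_index(axis=1)
    out.index.name = "cell_line_id"
    return out


def rollup_features(
    mutations: pd.DataFrame,
    annotations: pd.DataFrame,
    cell_lines: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Count-per-annotation-entity features per cell line.

    ``annotations`` columns: gene, entity_id, entity_level (motif, domain,
    family, reaction, pathway, go). The value of entity feature E for a
    cell line is the number of that line's kinase mutations in genes
    annotated to E ("mutations perturbing" the entity). Genes with no
    annotation contribute only to gene-level features. Returns the count
    block and a column -> FeatureMatrix level-tag map.
    """
    bad = set(annotations["entity_level"]) - set(ENTITY_LEVEL_TAG)
    if bad:
        raise ValueError(f"unknown annotation entity levels: {sorted(bad)}")
    gene_mut = (mutations.groupby(["cell_line_id", "gene"]).size()
                .rename("n_mut").reset_index())
    joined = gene_mut.merge(annotations, on="gene", how="inner")
    counts = (joined.groupby(["cell_line_id", "entity_id"])["n_mut"].sum()
              .unstack(fill_value=0))
    index = (cell_lines if cell_lines is not None
             else sorted(set(mutations["cell_line_id"])))
    counts = counts.reindex(index).fillna(0.0).sort_index(axis=1)
    counts.index.name = "cell_line_id"
    level_of_entity = (annotations.drop_duplicates("entity_id")
                       .set_index("entity_id")["entity_level"])
    tags = {c: ENTITY_LEVEL_TAG[level_of_entity[c]] for c in counts.columns}
    return counts, tags


def gene_level_features(
    mutations: pd.DataFrame,
    expression: pd.DataFrame,
    cnv: pd.DataFrame | None = None,
    cell_lines: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mutation counts plus expression / copy-number passthrough.

    ``expression`` and ``cnv`` are genes x cell-lines tables; missing
    values are zero-filled after logging. Columns are named
    ``MUTCOUNT_<gene>``, ``EXP_<gene>``, ``CNV_<gene>``.
    """
    index = (cell_lines if cell_lines is not None
             else sorted(set(mutations["cell_line_id"])))
    mut_counts = (mutations.groupby(["cell_line_id", "gene"]).size()
                  .unstack(fill_value=0).reindex(index).fillna(0.0))
    mut_counts.columns = [f"MUTCOUNT_{g}" for g in mut_counts.columns]
    blocks = [mut_counts]
    for prefix, table in (("EXP", expression), ("CNV", cnv)):
        if table is None:
            continue
        t = table.T.reindex(index)
        n_missing = int(t.isna().sum().sum())
        if n_missing:
            log.warning("%s block: zero-filled %d missing value(s)",
                        prefix, n_missing)
        t = t.fillna(0.0)
        t.columns = [f"{prefix}_{g}" for g in t.columns]
        blocks.append(t)
    out = pd.concat(blocks, axis=1).sort_index(axis=1)
    out.index.name = "cell_line_id"
    return out


def dummy_code(
    categoricals: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, dict[str, str]]]:
    """Dummy-code categorical sample columns into k-1 indicators.

    The reference level is the lexicographically first; single-level
    columns are dropped with a log message. Returns the indicator block
    and, per original column, the level -> indicator-column mapping (the
    reference level maps to the empty string), enabling exact decoding.
    """
    blocks: list[pd.DataFrame] = []
    mapping: dict[str, dict[str, str]] = {}
    for col in categoricals.columns:
        levels = sorted(categoricals[col].astype(str).unique())
        if len(levels) < 2:
            log.info("dropping single-level categorical column %r", col)
            continue
        ref, rest = levels[0], levels[1:]
        mapping[col] = {ref: ""}
        sub = pd.DataFrame(index=categoricals.index)
        for lv in rest:
            name = f"{col}={lv}"
            sub[name] = (categoricals[col].astype(str) == lv).astype(float)
            mapping[col][lv] = name
        blocks.append(sub)
    out = (pd.concat(blocks, axis=1) if blocks
           else pd.DataFrame(index=categoricals.index))
    return out, mapping


def decode_dummies(indicators: pd.DataFrame,
                   mapping: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Invert :func:`dummy_code` exactly."""
    out = pd.DataFrame(index=indicators.index)
    for col, level_map in mapping.items():
        ref = next(lv for lv, name in level_map.items() if name == "")
        decoded = pd.Series(ref, index=indicators.index)
        for lv, name in level_map.items():
            if name:
                decoded[indicators[name] == 1] = lv
        out[col] = decoded
    return out


def fingerprint_bit(name: str) -> int | None:
    """Bit position of a fingerprint column name, or None for descriptors."""
    m = _FP_RE.match(name)
    return int(m.group(1)) if m else None


def rank_drug_features(names: list[str]) -> list[str]:
    """Priority order for drug features.

    All fingerprint bits precede all descriptors; within fingerprints,
    higher (later, more structurally complex) bit positions come first;
    descriptors keep their input order.
    """
    fps = [(n, fingerprint_bit(n)) for n in names]
    fingerprints = sorted((n for n, b in fps if b is not None),
                          key=lambda n: -fingerprint_bit(n))
    descriptors = [n for n, b in fps if b is None]
    return fingerprints + descriptors
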