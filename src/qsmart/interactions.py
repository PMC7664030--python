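"""Interaction-term construction, F-testing, and FDR filtering.

Five classes of product interaction terms enter the response model:

* drug x mutation — fingerprint bit x residue-level feature, e.g.
  ``PKA_187_CHA_X_Fingerprint_791`` (only residues mapped to the reference
  PKA structure interact with drugs);
* protein-protein interaction — expression(A) x expression(B) for STRING
  edges with combined score > 700, non-self, touching at least one kinase;
* reaction, pathway, and GO-process pairs — products of same-namespace
  mutation-count features, excluding pairs related by ancestry in the
  ontology hierarchy (at any depth), which would be unexplainable.

Each candidate is tested individually by the nested-model F-test (full:
intercept + both components + product; reduced: intercept + both
components). Benjamini-Hochberg adjustment is applied across all tested
terms of a training set, and a term is retained iff FDR q < alpha and it
has at least ``min_nonzero`` non-zero values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .features import fingerprint_bit
from .io import FeatureMatrix

log = logging.getLogger("qsmart")

#: raw annotation namespace -> interaction term type
SETLEVEL_TYPES = {"reaction": "reaction", "pathway": "pathway",
                  "go": "go_process"}


@dataclass
class InteractionTerm:
    name: str
    term_type: str  # drug_mutation | ppi | reaction | pathway | go_process
    components: tuple[str, str]
    f_stat: float = np.nan
    p_value: float = np.nan
    fdr_q: float = np.nan
    nonzero_count: int = 0


def build_drug_mutation_terms(matrix: FeatureMatrix) -> list[InteractionTerm]:
    """All fingerprint-bit x residue-feature product candidates.

    Residue-level features are the only cell-line features allowed to
    interact with drug substructures; products with higher-level features
    are never formed.
    """
    fps = [c for c in matrix.feature_names
           if matrix.levels[c] == "drug" and fingerprint_bit(c) is not None]
    residues = matrix.residue_columns()
    return [InteractionTerm(f"{res}_X_{fp}", "drug_mutation", (res, fp))
            for res in residues for fp in fps]


def build_ppi_terms(
    matrix: FeatureMatrix,
    ppi_edges: pd.DataFrame,
    kinase_genes: set[str],
    *, score_min: float = 700.0,
) -> list[InteractionTerm]:
    """Expression-weighted PPI candidates from a STRING-style edge list.

    ``ppi_edges`` columns: protein1, protein2, combined_score. An edge
    survives iff score > ``score_min`` (strict), it is not a self-edge,
    at least one endpoint is a kinase, and both endpoints have expression
    columns; its term is the product of the two expression levels.
    """
    have_expr = {c[len("EXP_"):] for c in matrix.feature_names
                 if c.startswith("EXP_")}
    seen: set[tuple[str, str]] = set()
    out: list[InteractionTerm] = []
    for rec in ppi_edges.itertuples(index=False):
        a, b = str(rec.protein1), str(rec.protein2)
        if a == b or not float(rec.combined_score) > score_min:
            continue
        if not ({a, b} & kinase_genes):
            continue
        if a not in have_expr or b not in have_expr:
            continue
        lo, hi = sorted((a, b))
        if (lo, hi) in seen:
            continue
        seen.add((lo, hi))
        out.append(InteractionTerm(f"EXP_{lo}_X_EXP_{hi}", "ppi",
                                   (f"EXP_{lo}", f"EXP_{hi}")))
    return out


def ancestor_closure(hierarchy_edges: pd.DataFrame) -> dict[str, set[str]]:
    """Transitive ancestor sets from a child -> parent edge list.

    Raises on a cyclic hierarchy, naming the cycle.
    """
    g = nx.DiGraph()
    for rec in hierarchy_edges.itertuples(index=False):
        g.add_edge(str(rec.child), str(rec.parent))
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValueError(f"cyclic ontology hierarchy: {cycle}")
    return {node: nx.descendants(g, node) for node in g.nodes}


def build_setlevel_terms(
    matrix: FeatureMatrix,
    entity_namespaces: dict[str, str],
    hierarchy_edges: pd.DataFrame | None = None,
) -> list[InteractionTerm]:
    """Same-namespace count x count candidates with ancestor pairs removed.

    ``entity_namespaces`` maps count-feature column -> raw namespace
    (reaction / pathway / go); pairs are formed within a namespace only.
    A pair is excluded when either member is an ancestor of the other at
    any depth in ``hierarchy_edges`` (child, parent columns).
    """
    ancestors = (ancestor_closure(hierarchy_edges)
                 if hierarchy_edges is not None else {})
    out: list[InteractionTerm] = []
    by_ns: dict[str, list[str]] = {}
    for col, ns in entity_namespaces.items():
        if col in matrix.levels:
            by_ns.setdefault(ns, []).append(col)
    for ns, cols in sorted(by_ns.items()):
        ttype = SETLEVEL_TYPES[ns]
        cols = sorted(cols)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                if (b in ancestors.get(a, ()) or a in ancestors.get(b, ())):
                    continue
                out.append(InteractionTerm(f"{a}_X_{b}", ttype, (a, b)))
    return out


def ftest_term(
    y: np.ndarray, term: np.ndarray, comp_a: np.ndarray, comp_b: np.ndarray,
) -> tuple[float, float]:
    """Nested-model F-test of one product interaction.

    Full model: intercept + both components + product; reduced model:
    intercept + both components. F = ((RSS_red - RSS_full) / 1) /
    (RSS_full / (n - p_full)); p from F(1, n - p_full). Raises on a
    zero-variance term (no testable interaction).
    """
    y = np.asarray(y, float)
    n = y.shape[0]
    if np.ptp(term) == 0:
        raise ValueError("zero-variance interaction term")
    ones = np.ones(n)
    x_red = np.column_stack([ones, comp_a, comp_b])
    x_full = np.column_stack([ones, comp_a, comp_b, term])
    beta_r, _, rank_r, _ = np.linalg.lstsq(x_red, y, rcond=None)
    beta_f, _, rank_f, _ = np.linalg.lstsq(x_full, y, rcond=None)
    if rank_f <= rank_r:  # product collinear with main effects
        raise ValueError("interaction term collinear with its components")
    rss_r = float(np.sum((y - x_red @ beta_r) ** 2))
    rss_f = float(np.sum((y - x_full @ beta_f) ** 2))
    df_denom = n - rank_f
    if df_denom <= 0:
        raise ValueError("not enough observations for the F-test")
    if rss_f <= 0:
        return np.inf, 0.0
    f = max(rss_r - rss_f, 0.0) / (rss_f / df_denom)
    p = float(stats.f.sf(f, 1, df_denom))
    return float(f), p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def score_terms(
    matrix: FeatureMatrix,
    candidates: list[InteractionTerm],
    y: np.ndarray,
    *, min_nonzero: int = 30,
) -> tuple[pd.DataFrame, list[InteractionTerm]]:
    """Compute, support-prefilter, and F-test candidate terms.

    Candidates whose product column has fewer than ``min_nonzero``
    non-zero values are skipped before testing (they could never pass the
    retention filter). Returns (term values for tested candidates, tested
    candidates annotated with F/p/nonzero).
    """
    vals: dict[str, np.ndarray] = {}
    tested: list[InteractionTerm] = []
    v = matrix.values
    for t in candidates:
        a = v[t.components[0]].to_numpy(float)
        b = v[t.components[1]].to_numpy(float)
        prod = a * b
        t.nonzero_count = int(np.count_nonzero(prod))
        if t.nonzero_count < min_nonzero:
            continue
        try:
            t.f_stat, t.p_value = ftest_term(y, prod, a, b)
        except ValueError as err:
            log.debug("dropping term %s: %s", t.name, err)
            continue
        vals[t.name] = prod
        tested.append(t)
    values = pd.DataFrame(vals, index=matrix.values.index)
    return values, tested


def filter_terms(
    tested: list[InteractionTerm],
    *, alpha: float = 0.05, min_nonzero: int = 30,
) -> list[InteractionTerm]:
    """Retain terms with BH FDR q < alpha and >= min_nonzero support.

    Adjustment is computed across all tested terms of the training set.
    """
    if not tested:
        return []
    q = bh_adjust(np.array([t.p_value for t in tested]))
    for t, qv in zip(tested, q):
        t.fdr_q = float(qv)
    return [t for t in tested
            if t.fdr_q < alpha and t.nonzero_count >= min_nonzero]


def stats_table(terms: list[InteractionTerm]) -> pd.DataFrame:
    """Statistics table (term, type, components, F, p, q, nonzero)."""
    return pd.DataFrame(
        [{"term": t.name, "type": t.term_type,
          "component_a": t.components[0], "component_b": t.components[1],
          "f_stat": t.f_stat, "p_value": t.p_value, "fdr_q": t.fdr_q,
          "nonzero_count": t.nonzero_count} for t in terms])
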