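"""Directed ligand-receptor crosstalk between joint tissues.

For each subtype and each directed tissue pair (source → target, including
self-pairs — nine directions over cartilage, synovium and subchondral bone),
every ligand-receptor pair in the database is scored by its occurrence
ratio: the fraction of evaluable patients (sampled in both tissues) whose
ligand CPM in the source tissue and receptor CPM in the target tissue both
reach the expression threshold.  Pairs with occurrence ratio above
``min_or_expressed`` count as expressed; above ``tau_or`` as highly
expressed.  Highly-expressed-pair counts per direction form a directed
weighted network over the three tissues, and the genes involved are tested
for gene-set over-representation with a one-sided hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import TISSUES, ValidationError

NINE_DIRECTIONS = tuple((s, t) for s in TISSUES for t in TISSUES)

TAU_EXPR = 1.0          # CPM at which a gene counts as expressed in a patient
MIN_OR_EXPRESSED = 0.5  # occurrence ratio for an "expressed" pair
TAU_OR = 0.9            # occurrence ratio for a "highly expressed" pair


def patient_matrix(expr: pd.DataFrame, meta: pd.DataFrame, tissue: str,
                   status: str = "OA") -> pd.DataFrame:
    """Re-key a tissue CPM matrix from sample ids to patient ids."""
    sel = meta[(meta["tissue"] == tissue) & (meta["status"] == status)]
    sel = sel[sel["sample_id"].isin(expr.columns)]
    out = expr[sel["sample_id"].tolist()].copy()
    out.columns = sel["patient_id"].tolist()
    return out


def evaluate_pair(cpm_source: pd.DataFrame, cpm_target: pd.DataFrame,
                  ligand: str, receptor: str, patients,
                  tau_expr: float = TAU_EXPR):
    """Per-patient co-expression indicator and occurrence ratio for one pair.

    Both matrices are patient-keyed CPM for their tissue.  A patient is
    evaluable iff present in both; the indicator requires ligand CPM in the
    source tissue and receptor CPM in the target tissue to both reach
    ``tau_expr``.  Returns ``(indicator Series over evaluable patients,
    occurrence ratio or None when no patient is evaluable)``.
    """
    if ligand not in cpm_source.index:
        raise ValidationError(f"ligand {ligand!r} absent from source tissue matrix")
    if receptor not in cpm_target.index:
        raise ValidationError(f"receptor {receptor!r} absent from target tissue matrix")
    evaluable = [p for p in patients
                 if p in cpm_source.columns and p in cpm_target.columns]
    if not evaluable:
        return pd.Series(dtype=bool), None
    lig = cpm_source.loc[ligand, evaluable].to_numpy(dtype=float)
    rec = cpm_target.loc[receptor, evaluable].to_numpy(dtype=float)
    ind = pd.Series((lig >= tau_expr) & (rec >= tau_expr), index=evaluable)
    return ind, float(ind.mean())


@dataclass
class CrosstalkResult:
    """Occurrence-ratio table for one (subtype, source → target) direction."""

    subtype: str
    source: str
    target: str
    table: pd.DataFrame  # ligand, receptor, n_evaluable, n_expressed, occurrence_ratio, expressed, high
    n_evaluable_patients: int
    tau_expr: float
    min_or_expressed: float
    tau_or: float | None = None
    no_evaluable: bool = False

    @property
    def expressed_pairs(self) -> int:
        return int(self.table["expressed"].sum())

    @property
    def high_pairs(self) -> int:
        if "high" not in self.table.columns:
            return 0
        return int(self.table["high"].fillna(False).sum())


def count_expressed_pairs(exprs: dict[str, pd.DataFrame], patients,
                          db: pd.DataFrame, source: str, target: str,
                          subtype: str = "all", tau_expr: float = TAU_EXPR,
                          min_or_expressed: float = MIN_OR_EXPRESSED) -> CrosstalkResult:
    """Score every database pair for one directed tissue pair and subtype.

    ``exprs`` maps tissue name to a patient-keyed CPM matrix; ``patients``
    restricts to the subtype's patients.  Patients missing either tissue are
    excluded pair-wise; if none remain the result is flagged
    ``no_evaluable`` rather than treated as zero.
    """
    for t in (source, target):
        if t not in exprs:
            raise ValidationError(f"tissue {t!r} not provided")
    cpm_s, cpm_t = exprs[source], exprs[target]
    evaluable = [p for p in patients
                 if p in cpm_s.columns and p in cpm_t.columns]
    rows = []
    for ligand, receptor in db[["ligand", "receptor"]].itertuples(index=False):
        if evaluable:
            ind, ratio = evaluate_pair(cpm_s, cpm_t, ligand, receptor,
                                       evaluable, tau_expr)
            n_expr = int(ind.sum())
        else:
            ratio, n_expr = np.nan, 0
        rows.append({"ligand": ligand, "receptor": receptor,
                     "n_evaluable": len(evaluable), "n_expressed": n_expr,
                     "occurrence_ratio": ratio})
    table = pd.DataFrame(rows)
    table["expressed"] = (table["occurrence_ratio"] >= min_or_expressed
                          ).fillna(False) if len(table) else pd.Series(dtype=bool)
    return CrosstalkResult(
        subtype=subtype, source=source, target=target, table=table,
        n_evaluable_patients=len(evaluable), tau_expr=tau_expr,
        min_or_expressed=min_or_expressed, no_evaluable=not evaluable)


def select_high_pairs(result: CrosstalkResult, tau_or: float = TAU_OR) -> CrosstalkResult:
    """Mark expressed pairs whose occurrence ratio reaches ``tau_or`` as high."""
    table = result.table.copy()
    table["high"] = table["expressed"] & (table["occurrence_ratio"] >= tau_or)
    return CrosstalkResult(
        subtype=result.subtype, source=result.source, target=result.target,
        table=table, n_evaluable_patients=result.n_evaluable_patients,
        tau_expr=result.tau_expr, min_or_expressed=result.min_or_expressed,
        tau_or=tau_or, no_evaluable=result.no_evaluable)


def build_network(results: list[CrosstalkResult]) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Directed weighted tissue graph: edge weight = highly-expressed-pair count.

    All nine directions appear in the edge list; directions with no
    evaluable patients carry weight 0 and ``available=False``.
    """
    by_dir = {(r.source, r.target): r for r in results}
    graph = nx.DiGraph()
    graph.add_nodes_from(TISSUES)
    rows = []
    for source, target in NINE_DIRECTIONS:
        r = by_dir.get((source, target))
        available = r is not None and not r.no_evaluable
        weight = r.high_pairs if available else 0
        graph.add_edge(source, target, weight=weight, available=available)
        rows.append({"source": source, "target": target, "weight": weight,
                     "available": available})
    return graph, pd.DataFrame(rows)


def crosstalk_genes(result: CrosstalkResult) -> set[str]:
    """Union of ligand and receptor genes of the highly expressed pairs."""
    if "high" not in result.table.columns:
        return set()
    high = result.table[result.table["high"].fillna(False)]
    return set(high["ligand"]) | set(high["receptor"])


def enrich_crosstalk_genes(query_genes, genesets: dict[str, list[str]],
                           background) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene query in each gene set.

    One-sided tail P(X >= overlap) with the population restricted to the
    background universe; BH FDR across sets.
    """
    background = set(background)
    query = set(query_genes)
    if not query:
        raise ValidationError("empty crosstalk gene query")
    if not query <= background:
        raise ValidationError("query genes missing from background universe")
    M, n_query = len(background), len(query)
    rows = []
    for name, members in genesets.items():
        members_bg = set(members) & background
        overlap = len(members_bg & query)
        # P(X >= overlap), X ~ Hypergeom(M, |set|, |query|)
        p = float(scipy.stats.hypergeom.sf(overlap - 1, M, len(members_bg), n_query))
        rows.append({"set": name, "set_size": len(members_bg),
                     "overlap": overlap, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
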