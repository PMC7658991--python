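"""Marker-gene detection and pairwise differential expression.

Markers are found per cluster against the rest of the cohort: each gene is
scored by the AUROC of its expression as a classifier of cluster membership
(Mann–Whitney formulation, ties at half weight) with a two-sided Wilcoxon
rank-sum p-value, BH-adjusted across genes within each cluster.  A gene is
reported for at most one cluster — the one where its AUROC is maximal.

Differential expression between two sample groups uses a Welch t-test on
log2(CPM+1) with pseudocount-1 fold changes on the CPM scale and BH FDR
across tested genes; defaults retain |fold change| > 4 at FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .qc import cpm as cpm_normalize


def auroc(values, in_group) -> float:
    """AUROC of `values` for separating in-group from out-group samples.

    Mann–Whitney formulation: the fraction of (in, out) pairs where the
    in-group value is larger, counting ties as half.
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n_in, n_out = int(in_group.sum()), int((~in_group).sum())
    if n_in == 0 or n_out == 0:
        raise ValidationError("AUROC needs non-empty in- and out-groups")
    ranks = scipy.stats.rankdata(values)
    u = ranks[in_group].sum() - n_in * (n_in + 1) / 2.0
    return float(u / (n_in * n_out))


def _cluster_stats(X: np.ndarray, mask: np.ndarray):
    """Vectorized per-gene AUROC and two-sided rank-sum p for one cluster."""
    res = scipy.stats.mannwhitneyu(X[:, mask], X[:, ~mask], axis=1,
                                   alternative="two-sided", method="asymptotic")
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    aur = res.statistic / (n_in * n_out)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # all-tied genes
    return aur, p


def find_markers(expr: pd.DataFrame, labels: pd.Series, p_adj_max: float = 0.05,
                 auroc_min: float = 0.6) -> pd.DataFrame:
    """Cluster-vs-rest marker table over a genes×samples expression matrix.

    Returns columns (gene, subtype, auroc, p, p_adj), one row per retained
    gene, ranked within each subtype by AUROC descending then gene id.
    """
    labels = labels.loc[expr.columns]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValidationError("marker detection needs >=2 clusters")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValidationError(f"clusters with <2 samples: {dict(small)}")

    X = expr.to_numpy(dtype=float)
    aur = np.zeros((len(clusters), X.shape[0]))
    pvals = np.zeros_like(aur)
    padj = np.zeros_like(aur)
    for i, c in enumerate(clusters):
        mask = (labels == c).to_numpy()
        aur[i], pvals[i] = _cluster_stats(X, mask)
        padj[i] = multipletests(pvals[i], method="fdr_bh")[1]

    best = aur.argmax(axis=0)  # each gene reported only for its best cluster
    rows = []
    for g in range(X.shape[0]):
        i = best[g]
        if padj[i, g] < p_adj_max and aur[i, g] > auroc_min:
            rows.append({"gene": expr.index[g], "subtype": clusters[i],
                         "auroc": aur[i, g], "p": pvals[i, g],
                         "p_adj": padj[i, g]})
    table = pd.DataFrame(rows, columns=["gene", "subtype", "auroc", "p", "p_adj"])
    if not table.empty:
        table = table.sort_values(["subtype", "auroc", "gene"],
                                  ascending=[True, False, True],
                                  kind="stable").reset_index(drop=True)
    return table


@dataclass
class DEResult:
    """Differential-expression outcome for one contrast A vs B."""

    contrast: tuple[str, str]
    table: pd.DataFrame          # gene, log2fc, p, fdr, direction, retained
    fc_min: float
    fdr_max: float

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]


def differential_expression(counts: pd.DataFrame, samples_a, samples_b,
                            fc_min: float = 4.0, fdr_max: float = 0.05,
                            contrast: tuple[str, str] = ("A", "B")) -> DEResult:
    """Welch-t differential expression between two sample groups.

    The test runs on log2(CPM+1); the reported fold change is
    (mean CPM_A + 1)/(mean CPM_B + 1) so silent genes stay finite.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("differential expression needs >=2 samples per group")
    expr = cpm_normalize(counts[samples_a + samples_b])
    log_a = np.log2(expr[samples_a].to_numpy() + 1.0)
    log_b = np.log2(expr[samples_b].to_numpy() + 1.0)

    t, p = scipy.stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    # zero-variance-in-both-groups genes: exact separation or exact equality
    var0 = (log_a.var(axis=1) == 0) & (log_b.var(axis=1) == 0)
    equal_means = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
    p = np.where(var0 & equal_means, 1.0, p)
    p = np.where(var0 & ~equal_means, 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    mean_a = expr[samples_a].mean(axis=1).to_numpy()
    mean_b = expr[samples_b].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]
    retained = (np.abs(log2fc) > np.log2(fc_min)) & (fdr < fdr_max)
    table = pd.DataFrame({
        "gene": counts.index, "log2fc": log2fc, "p": p, "fdr": fdr,
        "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat")),
        "retained": retained,
    })
    return DEResult(contrast=contrast, table=table, fc_min=fc_min, fdr_max=fdr_max)


def overlap_sets(named_sets: dict[str, set]) -> dict[str, int]:
    """Cardinality of every region of the Venn partition of up to 3 sets.

    Keys are '&'-joined sorted set names; e.g. for sets X and Y the keys are
    'X' (exclusive to X), 'Y', and 'X&Y'.
    """
    if len(named_sets) > 3:
        raise ValidationError("overlap accounting supports at most 3 sets")
    names = sorted(named_sets)
    sets = {n: set(named_sets[n]) for n in names}
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return regions
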