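"""Statistical tests linking molecular subtypes to ordered clinical scores.

The Cochran–Armitage trend test compares the distribution of an ordered
clinical score (KL grade, osteophyte score 0–12, JSN score 0–6, binned age)
between two subtypes; every pairwise subtype contrast is tested per score
and BH-corrected within that score's family.  Wilcoxon rank-sum and
Fisher's exact test cover the remaining group comparisons.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

AGE_BIN_EDGES = (55, 65, 75)  # -> <55, 55-64, 65-74, >=75

CLINICAL_SCORES = ("age", "kl", "osteophyte", "jsn")


def cochran_armitage(table, scores=None) -> tuple[float, float]:
    """Cochran–Armitage test for trend on a 2×k contingency table.

    Rows are the two groups, columns the ordered categories with numeric
    scores ``t_i`` (defaults to 0..k−1).  With first-row counts ``r_i``,
    column totals ``n_i``, ``N = Σ n_i`` and ``p̄ = Σ r_i / N``::

        T   = Σ t_i (r_i − n_i p̄)
        Var = p̄ (1 − p̄) [Σ t_i² n_i − (Σ t_i n_i)² / N]
        Z   = T / sqrt(Var)

    Returns ``(Z, two-sided normal p)``.
    """
    table = np.asarray(table, dtype=float)
    if table.shape[0] != 2 or table.ndim != 2:
        raise ValidationError(f"need a 2×k table, got shape {table.shape}")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValidationError("table entries must be non-negative integers")
    if scores is None:
        scores = np.arange(table.shape[1], dtype=float)
    t = np.asarray(scores, dtype=float)
    if len(t) != table.shape[1] or np.any(np.diff(t) <= 0):
        raise ValidationError("scores must be strictly increasing, one per column")
    r = table[0]
    n = table.sum(axis=0)
    N = n.sum()
    if r.sum() == 0 or table[1].sum() == 0:
        raise ValidationError("both row sums must be positive")
    pbar = r.sum() / N
    T = float(np.sum(t * (r - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(t**2 * n) - np.sum(t * n) ** 2 / N)
    if var <= 0:
        raise ValidationError("degenerate table: all mass in one category")
    z = T / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses exact enumeration for small tie-free samples (n_x + n_y ≤ 12) and
    the tie-corrected normal approximation with continuity correction
    otherwise.  Returns ``(U of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    if nx + ny <= 12:
        # exact two-sided p by enumerating every assignment of pooled ranks
        # to the x group (midranks, so tied data are handled exactly)
        mu = nx * ny / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(nx + ny), nx):
            u = ranks[list(idx)].sum() - nx * (nx + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return float(u_obs), hits / total
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
    return float(u_obs), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table (hypergeometric tail sum)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValidationError(f"need a 2×2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValidationError("table entries must be non-negative")
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_exact_monte_carlo(table, n_sim: int = 100_000, seed: int = 0) -> float:
    """Fisher-style exact test for an r×k table by seeded Monte Carlo.

    Samples tables with the observed margins and estimates
    P(prob(simulated) ≤ prob(observed)) with the add-one estimator.
    """
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValidationError("table entries must be non-negative")
    row, col = table.sum(axis=1), table.sum(axis=0)

    def log_prob(t):
        return (scipy.special.gammaln(row + 1).sum()
                + scipy.special.gammaln(col + 1).sum()
                - scipy.special.gammaln(row.sum() + 1)
                - scipy.special.gammaln(t + 1).sum())

    rng = np.random.default_rng(seed)
    obs = log_prob(table)
    sims = scipy.stats.random_table(row, col).rvs(n_sim, random_state=rng)
    lp = (scipy.special.gammaln(row + 1).sum()
          + scipy.special.gammaln(col + 1).sum()
          - scipy.special.gammaln(row.sum() + 1)
          - scipy.special.gammaln(sims + 1).sum(axis=(1, 2)))
    hits = int(np.sum(lp <= obs + 1e-9))
    return (hits + 1) / (n_sim + 1)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _bin_age(age: pd.Series) -> pd.Series:
    bins = [-np.inf, *AGE_BIN_EDGES, np.inf]
    labels = list(range(len(bins) - 1))
    return pd.cut(age, bins=bins, labels=labels, right=False).astype(float)


def patient_clinical(meta: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """One row per labelled OA patient with subtype and clinical scores.

    ``labels`` may be indexed by sample id or patient id.
    """
    oa = meta[meta["status"] == "OA"].drop_duplicates("patient_id").copy()
    by_sample = meta.set_index("sample_id")["patient_id"]
    idx = pd.Index(labels.index)
    if idx.isin(by_sample.index).all():
        patient_label = pd.Series(labels.values,
                                  index=by_sample.loc[idx].values)
        patient_label = patient_label[~patient_label.index.duplicated()]
    else:
        patient_label = labels
    oa = oa[oa["patient_id"].isin(patient_label.index)]
    oa["subtype"] = patient_label.loc[oa["patient_id"]].values
    return oa.reset_index(drop=True)


def score_distributions(clin: pd.DataFrame,
                        scores=CLINICAL_SCORES) -> dict[str, pd.DataFrame]:
    """Per-subtype percentage distribution over each score's categories."""
    out = {}
    for score in scores:
        vals = _bin_age(clin["age"]) if score == "age" else clin[score]
        df = pd.DataFrame({"subtype": clin["subtype"], "value": vals}).dropna()
        counts = df.groupby(["subtype", "value"], observed=True).size().unstack(fill_value=0)
        pct = counts.div(counts.sum(axis=1), axis=0) * 100
        out[score] = pct
    return out


def pairwise_trend_tests(clin: pd.DataFrame,
                         scores=CLINICAL_SCORES) -> pd.DataFrame:
    """All pairwise Cochran–Armitage tests per score, BH-corrected per score.

    Returns columns (score, subtype_a, subtype_b, z, p, fdr); contrasts with
    a degenerate table (all mass in one category) carry NaN statistics and
    are excluded from their FDR family.
    """
    subtypes = sorted(clin["subtype"].unique())
    rows = []
    for score in scores:
        vals = _bin_age(clin["age"]) if score == "age" else clin[score]
        df = pd.DataFrame({"subtype": clin["subtype"], "value": vals}).dropna()
        for a, b in combinations(subtypes, 2):
            sub = df[df["subtype"].isin([a, b])]
            cats = np.sort(sub["value"].unique())
            table = np.array([
                [int((sub[sub["subtype"] == g]["value"] == c).sum()) for c in cats]
                for g in (a, b)])
            try:
                z, p = cochran_armitage(table, scores=cats.astype(float))
            except ValidationError:
                z, p = np.nan, np.nan
            rows.append({"score": score, "subtype_a": a, "subtype_b": b,
                         "z": z, "p": p})
    res = pd.DataFrame(rows)
    res["fdr"] = np.nan
    for score in scores:
        mask = (res["score"] == score) & res["p"].notna()
        if mask.any():
            res.loc[mask, "fdr"] = bh_fdr(res.loc[mask, "p"].to_numpy())
    return res


def subtype_clinical_report(meta: pd.DataFrame, labels: pd.Series,
                            scores=CLINICAL_SCORES):
    """Distributions plus pairwise trend tests for every clinical score."""
    clin = patient_clinical(meta, labels)
    return score_distributions(clin, scores), pairwise_trend_tests(clin, scores)
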