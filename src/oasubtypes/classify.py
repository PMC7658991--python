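"""Random-forest subtype transfer to external expression cohorts.

Cross-platform expression values are harmonized by within-sample fractional
ranks over the marker-gene feature space (monotone-transform invariant, so
FPKM/TPM/CPM externals are all comparable); a seeded random forest trained
on the discovery cohort then votes a subtype label for each external sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .io import ValidationError


def rank_normalize(expr: pd.DataFrame, genes) -> tuple[pd.DataFrame, list[str]]:
    """Within-sample fractional ranks of ``genes`` in a genes×samples matrix.

    Each sample's values over the requested genes are replaced by averaged
    ranks scaled to (0, 1].  Genes absent from the matrix are imputed at
    rank 0 and returned in the second element so callers can report them.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if not present:
        raise ValidationError("no requested genes present in expression matrix")
    ranks = scipy.stats.rankdata(expr.loc[present].to_numpy(dtype=float), axis=0)
    ranks = ranks / len(present)
    out = pd.DataFrame(0.0, index=genes, columns=expr.columns)
    out.loc[present] = ranks
    return out, missing


class SubtypeRandomForest(ClassifierMixin, BaseEstimator):
    """Random-forest subtype classifier on rank-normalized marker genes.

    Parameters
    ----------
    n_trees : forest size (500 by default).
    random_state : seeds the forest; identical seeds give identical models.

    Attributes (after ``fit``)
    --------------------------
    feature_genes_ : ordered marker genes used as features.
    classes_ : subtype labels.
    forest_ : the fitted sklearn RandomForestClassifier.
    oob_score_ : out-of-bag accuracy on the discovery cohort.
    """

    def __init__(self, n_trees: int = 500, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, expr: pd.DataFrame, labels: pd.Series, markers: pd.DataFrame):
        """Train on a genes×samples discovery matrix.

        ``labels`` maps sample id to subtype; ``markers`` is a marker table
        with a ``gene`` column defining the feature space.
        """
        feature_genes = sorted(set(markers["gene"]) & set(expr.index))
        if not feature_genes:
            raise ValidationError("no marker genes present in discovery matrix")
        y = labels.loc[expr.columns]
        counts = y.value_counts()
        if len(counts) < 2:
            raise ValidationError("need >=2 subtype classes to train")
        small = counts[counts < 2]
        if not small.empty:
            raise ValidationError(f"classes with <2 samples: {dict(small)}")
        ranked, _ = rank_normalize(expr, feature_genes)
        X = ranked.T.to_numpy()
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_features="sqrt", oob_score=True,
            random_state=self.random_state)
        self.forest_.fit(X, y.to_numpy())
        self.feature_genes_ = feature_genes
        self.classes_ = self.forest_.classes_
        self.oob_score_ = float(self.forest_.oob_score_)
        self.marker_provenance_ = markers.copy()
        return self

    def _check_fitted(self):
        if not hasattr(self, "forest_"):
            raise ValidationError("model is not trained")

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        """Subtype label per sample of an external genes×samples matrix."""
        self._check_fitted()
        shared = [g for g in self.feature_genes_ if g in expr.index]
        if not shared:
            raise ValidationError("no shared feature genes with external matrix")
        ranked, self.last_missing_genes_ = rank_normalize(expr, self.feature_genes_)
        y = self.forest_.predict(ranked.T.to_numpy())
        return pd.Series(y, index=expr.columns, name="subtype")

    def predict_proba(self, expr: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        ranked, _ = rank_normalize(expr, self.feature_genes_)
        proba = self.forest_.predict_proba(ranked.T.to_numpy())
        return pd.DataFrame(proba, index=expr.columns, columns=self.classes_)


def composition_table(labels: pd.Series, classes=None) -> pd.DataFrame:
    """Per-class counts and percentages (count/total×100, one decimal).

    Classes absent from the predictions are reported as zero-count rows.
    """
    if len(labels) == 0:
        raise ValidationError("empty prediction set")
    classes = list(classes) if classes is not None else sorted(labels.unique())
    counts = labels.value_counts()
    total = int(len(labels))
    rows = [{"subtype": c, "count": int(counts.get(c, 0)),
             "percent": round(counts.get(c, 0) / total * 100, 1)}
            for c in classes]
    return pd.DataFrame(rows)


def train_subtype_model(expr: pd.DataFrame, labels: pd.Series,
                        markers: pd.DataFrame, seed: int = 0,
                        n_trees: int = 500) -> SubtypeRandomForest:
    """Functional wrapper over `SubtypeRandomForest.fit`."""
    return SubtypeRandomForest(n_trees=n_trees, random_state=seed).fit(
        expr, labels, markers)


def predict_subtypes(model: SubtypeRandomForest,
                     external_expr: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Predict external samples and summarize the cohort composition."""
    labels = model.predict(external_expr)
    return labels, composition_table(labels, classes=model.classes_)
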