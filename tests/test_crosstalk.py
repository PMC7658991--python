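"""Occurrence-ratio crosstalk: scoring, direction recovery, enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from oasubtypes.crosstalk import (NINE_DIRECTIONS, build_network,
                                  count_expressed_pairs, crosstalk_genes,
                                  enrich_crosstalk_genes, evaluate_pair,
                                  patient_matrix, select_high_pairs)
from oasubtypes.io import ValidationError
from oasubtypes.qc import cpm, filter_samples_by_depth


def _mat(values, genes, patients):
    return pd.DataFrame(values, index=genes, columns=patients)


@pytest.fixture(scope="module")
def tissue_cpms(small_cohort):
    counts, meta, _ = small_cohort
    return {t: patient_matrix(cpm(filter_samples_by_depth(c)), meta, t)
            for t, c in counts.items()}


class TestEvaluatePair:
    def test_three_of_four_patients(self):
        src = _mat([[5.0, 5.0, 5.0, 0.2]], ["L"], list("wxyz"))
        dst = _mat([[9.0, 9.0, 9.0, 9.0]], ["R"], list("wxyz"))
        ind, ratio = evaluate_pair(src, dst, "L", "R", list("wxyz"))
        assert ratio == 0.75 and ind.sum() == 3

    def test_silent_ligand_gives_zero(self):
        src = _mat([[0.0, 0.0]], ["L"], ["a", "b"])
        dst = _mat([[50.0, 50.0]], ["R"], ["a", "b"])
        _, ratio = evaluate_pair(src, dst, "L", "R", ["a", "b"])
        assert ratio == 0.0

    def test_matches_brute_force_thresholding(self, rng):
        patients = [f"p{i}" for i in range(12)]
        src = _mat(rng.uniform(0, 3, size=(4, 12)), list("abcd"), patients)
        dst = _mat(rng.uniform(0, 3, size=(4, 12)), list("wxyz"), patients)
        ind, ratio = evaluate_pair(src, dst, "b", "x", patients, tau_expr=1.0)
        expected = [(src.loc["b", p] >= 1.0) and (dst.loc["x", p] >= 1.0)
                    for p in patients]
        assert ind.tolist() == expected
        assert ratio == pytest.approx(np.mean(expected))

    def test_missing_tissue_patients_excluded(self):
        src = _mat([[5.0, 5.0]], ["L"], ["a", "b"])
        dst = _mat([[5.0]], ["R"], ["a"])
        ind, ratio = evaluate_pair(src, dst, "L", "R", ["a", "b"])
        assert list(ind.index) == ["a"] and ratio == 1.0

    def test_unknown_gene_error_names_it(self):
        src = _mat([[1.0]], ["L"], ["a"])
        with pytest.raises(ValidationError, match="NOPE"):
            evaluate_pair(src, src, "NOPE", "L", ["a"])


class TestCountExpressedPairs:
    def test_all_high_expression_counts_everything(self):
        genes = [f"g{i}" for i in range(20)]
        patients = [f"p{i}" for i in range(5)]
        exprs = {"cartilage": _mat(np.full((20, 5), 100.0), genes, patients)}
        db = pd.DataFrame({"ligand": genes[:10], "receptor": genes[10:]})
        res = count_expressed_pairs(exprs, patients, db, "cartilage",
                                    "cartilage")
        assert res.expressed_pairs == 10

    def test_planted_direction_has_most_planted_pairs(self, small_cohort,
                                                      small_lr, tissue_cpms):
        _, _, truth = small_cohort
        subtype = "C1"
        planted = [(l, r) for l, r, s, t, ps in truth.planted_crosstalk
                   if ps == subtype]
        src, dst = next((s, t) for _, _, s, t, ps in truth.planted_crosstalk
                        if ps == subtype)
        patients = [p for p, s in truth.patient_subtype.items() if s == subtype]
        db = pd.DataFrame(planted, columns=["ligand", "receptor"])
        per_direction = {}
        for a, b in NINE_DIRECTIONS:
            res = count_expressed_pairs(tissue_cpms, patients, db, a, b)
            per_direction[(a, b)] = res.expressed_pairs
        best = max(per_direction, key=per_direction.get)
        assert best == (src, dst)
        assert all(per_direction[(src, dst)] > v
                   for k, v in per_direction.items() if k != (src, dst))

    def test_no_evaluable_patients_flagged(self, tissue_cpms, small_lr):
        res = count_expressed_pairs(tissue_cpms, ["GHOST"], small_lr,
                                    "cartilage", "synovium")
        assert res.no_evaluable and res.expressed_pairs == 0
        assert res.table["occurrence_ratio"].isna().all()

    def test_direction_asymmetry(self):
        patients = ["a", "b"]
        src = _mat([[100.0, 100.0], [0.0, 0.0]], ["L", "R"], patients)
        dst = _mat([[0.0, 0.0], [100.0, 100.0]], ["L", "R"], patients)
        exprs = {"cartilage": src, "synovium": dst}
        db = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        fwd = count_expressed_pairs(exprs, patients, db, "cartilage", "synovium")
        rev = count_expressed_pairs(exprs, patients, db, "synovium", "cartilage")
        assert fwd.expressed_pairs == 1 and rev.expressed_pairs == 0


class TestSelectHighPairs:
    @pytest.fixture()
    def scored(self, tissue_cpms, small_lr, small_cohort):
        _, _, truth = small_cohort
        patients = [p for p, s in truth.patient_subtype.items() if s == "C1"]
        return count_expressed_pairs(tissue_cpms, patients, small_lr,
                                     "cartilage", "subchondral_bone",
                                     subtype="C1")

    def test_tau_zero_marks_all_expressed(self, scored):
        out = select_high_pairs(scored, tau_or=0.0)
        assert out.high_pairs == out.expressed_pairs

    def test_tau_one_requires_every_patient(self, scored):
        out = select_high_pairs(scored, tau_or=1.0)
        tab = out.table
        assert (tab.loc[tab["high"], "occurrence_ratio"] == 1.0).all()

    def test_lowering_tau_never_decreases(self, scored):
        counts = [select_high_pairs(scored, tau_or=t).high_pairs
                  for t in (1.0, 0.9, 0.5, 0.0)]
        assert counts == sorted(counts)

    def test_high_expressed_db_ordering(self, scored, small_lr):
        out = select_high_pairs(scored)
        assert 0 <= out.high_pairs <= out.expressed_pairs <= len(small_lr)


class TestNetwork:
    def test_all_zero_gives_nine_zero_edges(self):
        genes, patients = ["L", "R"], ["a", "b"]
        exprs = {t: _mat(np.zeros((2, 2)), genes, patients)
                 for t, _ in NINE_DIRECTIONS}
        exprs = {t: exprs[t] for t in {s for s, _ in NINE_DIRECTIONS}}
        db = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        results = [select_high_pairs(count_expressed_pairs(
            exprs, patients, db, s, t)) for s, t in NINE_DIRECTIONS]
        graph, edges = build_network(results)
        assert len(edges) == 9 and (edges["weight"] == 0).all()
        assert graph.number_of_edges() == 9

    def test_weights_match_recount(self, tissue_cpms, small_lr, small_cohort):
        _, _, truth = small_cohort
        patients = [p for p, s in truth.patient_subtype.items() if s == "C2"]
        results = [select_high_pairs(count_expressed_pairs(
            tissue_cpms, patients, small_lr, s, t, subtype="C2"))
            for s, t in NINE_DIRECTIONS]
        graph, edges = build_network(results)
        for res in results:
            expected = int((res.table["high"]).sum())
            assert graph[res.source][res.target]["weight"] == expected

    def test_opposite_directions_independent(self):
        patients = ["a"]
        src = _mat([[100.0], [0.0]], ["L", "R"], patients)
        dst = _mat([[0.0], [100.0]], ["L", "R"], patients)
        exprs = {"cartilage": src, "subchondral_bone": dst}
        db = pd.DataFrame({"ligand": ["L"], "receptor": ["R"]})
        results = [select_high_pairs(count_expressed_pairs(
            exprs, patients, db, s, t))
            for s, t in (("cartilage", "subchondral_bone"),
                         ("subchondral_bone", "cartilage"))]
        graph, _ = build_network(results)
        assert graph["cartilage"]["subchondral_bone"]["weight"] == 1
        assert graph["subchondral_bone"]["cartilage"]["weight"] == 0


class TestEnrichment:
    def test_worked_hypergeometric_example(self):
        # 10-gene background, one 5-gene set, 4-gene query fully inside:
        # P(X >= 4) = C(5,4)C(5,0)/C(10,4) = 5/210
        background = [f"g{i}" for i in range(10)]
        sets = {"S": background[:5]}
        out = enrich_crosstalk_genes(background[:4], sets, background)
        assert out.loc[0, "p"] == pytest.approx(5 / comb(10, 4))

    def test_disjoint_set_has_p_one(self):
        background = [f"g{i}" for i in range(10)]
        sets = {"S": background[5:], "T": background[:5]}
        out = enrich_crosstalk_genes(background[:4], sets,
                                     background).set_index("set")
        assert out.loc["S", "p"] == pytest.approx(1.0)
        assert out.loc["T", "p"] <= out.loc["S", "p"]

    def test_positive_control_set_ranks_first(self, small_cohort, small_lr,
                                              small_genesets, tissue_cpms):
        counts, _, truth = small_cohort
        subtype = "C2"
        src, dst = next((s, t) for _, _, s, t, ps in truth.planted_crosstalk
                        if ps == subtype)
        patients = [p for p, s in truth.patient_subtype.items() if s == subtype]
        res = select_high_pairs(count_expressed_pairs(
            tissue_cpms, patients, small_lr, src, dst, subtype=subtype))
        query = crosstalk_genes(res)
        out = enrich_crosstalk_genes(query, small_genesets,
                                     counts["cartilage"].index)
        assert out.loc[0, "set"] == f"positive_control_{subtype}"

    def test_empty_query_rejected(self, small_genesets):
        with pytest.raises(ValidationError):
            enrich_crosstalk_genes([], small_genesets, ["g1"])


class TestInvariants:
    def test_or_invariant_to_patient_order_and_rescaling(self, rng):
        patients = [f"p{i}" for i in range(8)]
        src = _mat(rng.uniform(1, 50, size=(2, 8)), ["L", "R"], patients)
        dst = _mat(rng.uniform(1, 50, size=(2, 8)), ["L", "R"], patients)
        _, base = evaluate_pair(src, dst, "L", "R", patients)
        _, shuffled = evaluate_pair(src, dst, "L", "R",
                                    list(reversed(patients)))
        _, scaled = evaluate_pair(src * 3, dst * 3, "L", "R", patients)
        assert base == shuffled == scaled

    def test_no_crosstalk_above_expression_ceiling(self, small_cohort,
                                                   small_lr, tissue_cpms):
        _, _, truth = small_cohort
        patients = list(truth.patient_subtype)
        ceiling = float(np.quantile(
            tissue_cpms["cartilage"].to_numpy(), 0.99)) * 1.01
        res = count_expressed_pairs(tissue_cpms, patients, small_lr,
                                    "cartilage", "cartilage",
                                    tau_expr=ceiling)
        assert res.expressed_pairs == 0
        assert select_high_pairs(res).high_pairs == 0
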