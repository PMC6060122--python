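"""Activity filtering, TESS scoring and entity-level aggregation."""

import numpy as np
import pytest

from tesspred import (
    CrudeDrug,
    Compound,
    FeatureVector,
    Interactome,
    InteractionRecord,
    MedicineFormula,
    Registry,
    TargetPrediction,
    aggregate_predictions,
    filter_interactome,
    generalized_jaccard,
    tess_predict,
)
from tesspred.model import ConfigurationError, IntegrityError


def _records(affinities):
    return [InteractionRecord(f"c{i}", "p", affinity=a)
            for i, a in enumerate(affinities)]


class TestFilter:
    def test_strict_30uM_boundary(self):
        inter = filter_interactome(_records([10.0, 29999.0, 30000.0, 50000.0]))
        kept = {r.affinity for r in inter.records}
        assert kept == {10.0, 29999.0}

    def test_active_flag_without_affinity_is_kept(self):
        inter = filter_interactome(
            [InteractionRecord("c", "p", active_flag=True)]
        )
        assert len(inter) == 1

    def test_flagged_record_survives_weak_affinity(self):
        inter = filter_interactome(
            [InteractionRecord("c", "p", affinity=90000.0, active_flag=True)]
        )
        assert len(inter) == 1

    def test_empty_input(self):
        assert len(filter_interactome([])) == 0

    def test_custom_threshold(self):
        inter = filter_interactome(_records([10.0, 500.0]), threshold_nM=100.0)
        assert {r.affinity for r in inter.records} == {10.0}


def _random_instance(rng, n_proteins=8, n_compounds=25, n_features=30):
    feats = [f"f{i}" for i in range(n_features)]
    fps = {}
    for i in range(n_compounds):
        ids = rng.choice(n_features, size=int(rng.integers(2, 8)), replace=False)
        fps[f"c{i}"] = FeatureVector(
            {feats[j]: int(rng.integers(1, 5)) for j in ids}
        )
    records = []
    for k in range(n_proteins):
        for j in rng.choice(n_compounds, size=int(rng.integers(1, 5)), replace=False):
            records.append(InteractionRecord(f"c{j}", f"p{k}", affinity=100.0))
    return fps, Interactome.from_records(records)


def _naive_tess(query, interactome, fps, query_id=None):
    """Independent double-loop oracle: all proteins × all ligands."""
    out = []
    for protein_id, ligands in interactome.ligands_by_protein.items():
        scored = [(generalized_jaccard(query, fps[c]), c) for c in ligands]
        best = max(s for s, _ in scored)
        best_ref = min(c for s, c in scored if s == best)
        out.append((protein_id, best, best_ref,
                    query_id in ligands if query_id else False))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


class TestTessPredict:
    def test_max_over_ligands_with_best_reference(self):
        fps = {
            "q": FeatureVector({"a": 1, "b": 1}),
            "c1": FeatureVector({"a": 1, "x": 1, "y": 1, "z": 1, "w": 1, "v": 1,
                                 "u": 1, "t": 1, "s": 1}),  # sim 1/10
            "c2": FeatureVector({"a": 1, "b": 1, "x": 1}),  # sim 2/3
        }
        inter = Interactome.from_records([
            InteractionRecord("c1", "P", affinity=5.0),
            InteractionRecord("c2", "P", affinity=5.0),
        ])
        (pred,) = tess_predict(fps["q"], inter, fps)
        assert pred.score == pytest.approx(2 / 3)
        assert pred.best_reference_compound_id == "c2"

    def test_known_ligand_scores_one(self):
        fps = {"q": FeatureVector({"a": 2})}
        inter = Interactome.from_records(
            [InteractionRecord("q", "P", affinity=1.0)]
        )
        (pred,) = tess_predict(fps["q"], inter, fps, query_compound_id="q")
        assert pred.score == 1.0 and pred.is_known

    def test_all_proteins_scored_without_cutoff(self):
        rng = np.random.default_rng(0)
        fps, inter = _random_instance(rng)
        preds = tess_predict(fps["c0"], inter, fps)
        assert len(preds) == len(inter.protein_ids)

    def test_equals_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            fps, inter = _random_instance(rng)
            qid = f"c{int(rng.integers(0, 25))}"
            preds = tess_predict(fps[qid], inter, fps, query_compound_id=qid)
            oracle = _naive_tess(fps[qid], inter, fps, query_id=qid)
            assert [(p.protein_id, p.best_reference_compound_id, p.is_known)
                    for p in preds] == [(p, ref, known) for p, _, ref, known in oracle]
            assert [p.score for p in preds] == pytest.approx(
                [s for _, s, _, _ in oracle]
            )

    def test_min_score_monotone_and_top_n_prefix(self):
        rng = np.random.default_rng(7)
        fps, inter = _random_instance(rng)
        full = tess_predict(fps["c1"], inter, fps)
        for cutoff in (0.1, 0.3, 0.6):
            subset = tess_predict(fps["c1"], inter, fps, min_score=cutoff)
            assert set(p.protein_id for p in subset) <= set(
                p.protein_id for p in full
            )
            assert all(p.score >= cutoff for p in subset)
        assert tess_predict(fps["c1"], inter, fps, top_n=3) == full[:3]

    def test_known_ligand_recovery_everywhere(self):
        rng = np.random.default_rng(9)
        fps, inter = _random_instance(rng)
        for rec in inter.records:
            preds = tess_predict(fps[rec.compound_id], inter, fps,
                                 query_compound_id=rec.compound_id)
            hit = next(p for p in preds if p.protein_id == rec.protein_id)
            assert hit.score == 1.0 and hit.is_known

    def test_missing_fingerprint_lists_ids(self):
        inter = Interactome.from_records(
            [InteractionRecord("cX", "P", affinity=1.0)]
        )
        with pytest.raises(ConfigurationError, match="cX"):
            tess_predict(FeatureVector({"a": 1}), inter, {})


def _pred(cid, pid, score, known=False):
    return TargetPrediction(compound_id=cid, protein_id=pid, score=score,
                            is_known=known, best_reference_compound_id="r")


class TestAggregation:
    def test_union_max_with_provenance(self):
        drug = CrudeDrug("d", compound_ids=("A", "B"))
        preds = {"A": [_pred("A", "P1", 0.9)],
                 "B": [_pred("B", "P1", 0.6), _pred("B", "P2", 0.8)]}
        agg = aggregate_predictions(drug, preds)
        by_protein = {a.protein_id: a for a in agg}
        assert by_protein["P1"].score == 0.9
        assert by_protein["P1"].contributions == (("A", 0.9, False), ("B", 0.6, False))
        assert by_protein["P2"].score == 0.8

    def test_single_compound_identity(self):
        drug = CrudeDrug("d", compound_ids=("A",))
        preds = {"A": [_pred("A", "P1", 0.4), _pred("A", "P2", 0.7)]}
        agg = aggregate_predictions(drug, preds)
        assert [(a.protein_id, a.score) for a in agg] == [("P2", 0.7), ("P1", 0.4)]

    def test_disjoint_targets_concatenate(self):
        drug = CrudeDrug("d", compound_ids=("A", "B"))
        preds = {"A": [_pred("A", "P1", 0.5)], "B": [_pred("B", "P2", 0.5)]}
        assert len(aggregate_predictions(drug, preds)) == 2

    def test_alternative_methods(self):
        drug = CrudeDrug("d", compound_ids=("A", "B"))
        preds = {"A": [_pred("A", "P1", 0.9)], "B": [_pred("B", "P1", 0.5)]}
        (mean,) = aggregate_predictions(drug, preds, method="mean")
        (count,) = aggregate_predictions(drug, preds, method="count")
        assert mean.score == pytest.approx(0.7)
        assert count.score == 2.0

    def test_formula_needs_registry(self):
        formula = MedicineFormula("f", crude_drug_ids=("d",))
        with pytest.raises(IntegrityError):
            aggregate_predictions(formula, {})

    def test_formula_aggregates_over_all_crude_drugs(self):
        reg = Registry()
        for cid in ("A", "B"):
            reg.add_compound(Compound(cid))
        reg.add_crude_drug(CrudeDrug("d1", compound_ids=("A",)))
        reg.add_crude_drug(CrudeDrug("d2", compound_ids=("B",)))
        reg.add_formula(MedicineFormula("f", crude_drug_ids=("d1", "d2")))
        preds = {"A": [_pred("A", "P1", 0.3)], "B": [_pred("B", "P1", 0.8)]}
        (agg,) = aggregate_predictions(reg.formulas["f"], preds, registry=reg)
        assert agg.entity_id == "f" and agg.score == 0.8

    def test_missing_compound_predictions_raise(self):
        drug = CrudeDrug("d", compound_ids=("A", "B"))
        with pytest.raises(IntegrityError, match="B"):
            aggregate_predictions(drug, {"A": []})
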