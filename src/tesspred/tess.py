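"""TESS: target estimation based on similarity search.

For a query compound, every interactome protein is scored by the
maximum fingerprint similarity between the query and the protein's
known ligands; that similarity is used directly as the prediction
score.  Upstream, the curated interaction set is filtered to records
that are explicitly flagged active or have a binding affinity strictly
below 30 μM.  Downstream, per-compound predictions are grouped into
crude drugs and formulas by taking, per protein, the best score across
the constituent compounds (with full per-compound provenance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .model import (
    ConfigurationError,
    CrudeDrug,
    Interactome,
    InteractionRecord,
    IntegrityError,
    MedicineFormula,
    Registry,
)
from .similarity import FeatureVector, similarity_matrix

__all__ = [
    "DEFAULT_AFFINITY_THRESHOLD_NM",
    "TargetPrediction",
    "AggregatedPrediction",
    "filter_interactome",
    "tess_predict",
    "aggregate_predictions",
    "leave_one_out_ranks",
]

logger = logging.getLogger(__name__)

#: 30 μM expressed in nM (1 μM = 1000 nM); the filter keeps strictly
#: smaller affinities.
DEFAULT_AFFINITY_THRESHOLD_NM = 30_000.0


@dataclass(frozen=True)
class TargetPrediction:
    """One (query compound, protein) prediction.

    ``score`` is the maximum similarity between the query and the
    protein's known ligands; ``best_reference_compound_id`` is the
    ligand achieving it (ties broken by compound ID).  ``is_known`` is
    set when the query itself is a known ligand, in which case the
    score is 1 by self-similarity.
    """

    compound_id: str
    protein_id: str
    score: float
    is_known: bool
    best_reference_compound_id: str


@dataclass(frozen=True)
class AggregatedPrediction:
    """Entity-level (crude drug or formula) prediction for one protein.

    ``contributions`` records every contributing (compound_id, score,
    is_known) triple so alternative aggregations stay recomputable.
    """

    entity_id: str
    protein_id: str
    score: float
    is_known: bool
    contributions: tuple


def filter_interactome(
    records: Iterable[InteractionRecord],
    threshold_nM: float = DEFAULT_AFFINITY_THRESHOLD_NM,
) -> Interactome:
    """Keep a record iff it is flagged active OR its affinity is
    strictly below ``threshold_nM``; build the protein→ligand index.

    Records carrying neither an affinity nor an active flag are dropped
    and counted in a log message, not raised.
    """
    kept = []
    n_no_evidence = 0
    n_dropped = 0
    for rec in records:
        if not rec.has_evidence:
            n_no_evidence += 1
            continue
        if rec.active_flag or (rec.affinity is not None and rec.affinity < threshold_nM):
            kept.append(rec)
        else:
            n_dropped += 1
    if n_no_evidence:
        logger.info("dropped %d records with neither affinity nor active flag",
                    n_no_evidence)
    if n_dropped:
        logger.info("filtered out %d records at the %.0f nM threshold",
                    n_dropped, threshold_nM)
    return Interactome.from_records(kept)


def tess_predict(
    query: FeatureVector,
    interactome: Interactome,
    fingerprints: Mapping[str, FeatureVector],
    min_score: float = 0.0,
    top_n: Optional[int] = None,
    query_compound_id: Optional[str] = None,
) -> list:
    """Rank all interactome proteins for one query compound.

    For protein k with known ligand set L_k, score(q, k) =
    max_{c in L_k} sim(q, c).  Returns predictions with
    score >= ``min_score``, ranked by (score desc, protein_id asc) and
    truncated to ``top_n``.  Pass ``query_compound_id`` to mark
    proteins for which the query is itself a known ligand.
    """
    if not interactome.records:
        raise ConfigurationError("tess_predict requires a non-empty interactome")
    ref_ids = list(interactome.compound_ids)
    missing = sorted(c for c in ref_ids if c not in fingerprints)
    if missing:
        raise ConfigurationError(
            "missing fingerprints for interactome compounds: " + ", ".join(missing)
        )
    sims = similarity_matrix([query], [fingerprints[c] for c in ref_ids])[0]
    sim_by_compound = dict(zip(ref_ids, sims))

    preds = []
    for protein_id, ligands in interactome.ligands_by_protein.items():
        # ligands are sorted, so ties resolve to the smallest compound ID
        best_ref, best = None, -1.0
        for c in ligands:
            s = sim_by_compound[c]
            if s > best:
                best_ref, best = c, s
        is_known = query_compound_id is not None and query_compound_id in ligands
        preds.append(
            TargetPrediction(
                compound_id=query_compound_id or "",
                protein_id=protein_id,
                score=float(best),
                is_known=is_known,
                best_reference_compound_id=best_ref,
            )
        )
    preds = [p for p in preds if p.score >= min_score]
    preds.sort(key=lambda p: (-p.score, p.protein_id))
    if top_n is not None:
        preds = preds[:top_n]
    return preds


def aggregate_predictions(
    entity: Union[CrudeDrug, MedicineFormula],
    predictions_by_compound: Mapping[str, Sequence[TargetPrediction]],
    registry: Optional[Registry] = None,
    method: str = "max",
    min_score: float = 0.0,
) -> list:
    """Group per-compound predictions into one entity-level list.

    The entity's protein set is the union over its constituent
    compounds; per protein the retained score is, by default, the
    maximum across contributing compounds (``method='mean'`` and
    ``'count'`` are alternatives).  Every contributing (compound,
    score) pair is kept as provenance.  Results are sorted
    (score desc, protein_id asc) and cut at ``min_score``.
    """
    if isinstance(entity, MedicineFormula):
        if registry is None:
            raise IntegrityError(
                "aggregating a formula requires a registry to resolve crude drugs"
            )
        compound_ids = registry.constituent_compounds(entity.formula_id)
        entity_id = entity.formula_id
    elif isinstance(entity, CrudeDrug):
        compound_ids = entity.compound_ids
        entity_id = entity.crude_drug_id
    else:
        raise IntegrityError(f"cannot aggregate over {type(entity).__name__}")

    missing = [c for c in compound_ids if c not in predictions_by_compound]
    if missing:
        raise IntegrityError(
            f"no predictions supplied for constituent compounds: {sorted(missing)}"
        )

    by_protein: dict = {}
    for cid in compound_ids:
        for p in predictions_by_compound[cid]:
            by_protein.setdefault(p.protein_id, []).append(
                (cid, float(p.score), bool(p.is_known))
            )

    if method not in ("max", "mean", "count"):
        raise ConfigurationError(f"unknown aggregation method {method!r}")

    out = []
    for protein_id in sorted(by_protein):
        contribs = tuple(sorted(by_protein[protein_id]))
        scores = [s for _, s, _ in contribs]
        if method == "max":
            score = max(scores)
        elif method == "mean":
            score = float(np.mean(scores))
        else:
            score = float(len(scores))
        out.append(
            AggregatedPrediction(
                entity_id=entity_id,
                protein_id=protein_id,
                score=score,
                is_known=any(k for _, _, k in contribs),
                contributions=contribs,
            )
        )
    out = [p for p in out if p.score >= min_score]
    out.sort(key=lambda p: (-p.score, p.protein_id))
    return out


def leave_one_out_ranks(
    interactome: Interactome,
    fingerprints: Mapping[str, FeatureVector],
    compound_ids: Optional[Sequence[str]] = None,
) -> list:
    """Leave-one-compound-out evaluation of TESS.

    For each held-out compound, every record involving it is removed,
    the compound is re-queried against the reduced interactome, and the
    1-based rank of each of its true target proteins in the returned
    ranking is collected.  Returns a list of (compound_id, protein_id,
    rank, n_scored_proteins) tuples.
    """
    if compound_ids is None:
        compound_ids = interactome.compound_ids
    results = []
    for cid in compound_ids:
        truth = interactome.targets_by_compound.get(cid, ())
        if not truth:
            continue
        reduced = interactome.without_compound(cid)
        if not reduced.records:
            continue
        preds = tess_predict(fingerprints[cid], reduced, fingerprints)
        position = {p.protein_id: i + 1 for i, p in enumerate(preds)}
        for protein_id in truth:
            if protein_id in position:
                results.append((cid, protein_id, position[protein_id], len(preds)))
    return results
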