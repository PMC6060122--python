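"""Indication prediction by target matching.

Each target protein of a query compound (known targets and
similarity-predicted ones alike) is looked up in a disease →
therapeutic-target association map; every match links the compound to
the disease through that protein.  A link scores 1 when the matched
protein is a known target of the query, and carries the similarity
prediction score otherwise.  Diseases are ranked by their best link
score; the full link table is kept so other aggregations remain
recomputable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import DiseaseTargetMap
from .tess import TargetPrediction

__all__ = ["IndicationLink", "DiseaseRanking", "predict_indications"]


@dataclass(frozen=True)
class IndicationLink:
    """One compound–disease link via a shared target protein."""

    compound_id: str
    disease_id: str
    protein_id: str
    score: float
    via_known: bool


@dataclass(frozen=True)
class DiseaseRanking:
    """One ranked disease with all of its supporting links."""

    disease_id: str
    disease_name: str
    best_score: float
    links: tuple


def predict_indications(
    targets: Sequence[TargetPrediction],
    disease_map: DiseaseTargetMap,
) -> list:
    """Rank applicable diseases for one compound's target list.

    Emits one :class:`IndicationLink` per (disease, matched protein);
    link score = 1 for known targets, else the prediction score.
    Diseases are ordered by maximum link score (desc), ties broken by
    disease ID.  No overlap between targets and the map yields an empty
    list.
    """
    diseases_of = disease_map.diseases_by_protein()
    by_disease: dict = {}
    for t in targets:
        for disease_id in diseases_of.get(t.protein_id, ()):
            link = IndicationLink(
                compound_id=t.compound_id,
                disease_id=disease_id,
                protein_id=t.protein_id,
                score=1.0 if t.is_known else float(t.score),
                via_known=t.is_known,
            )
            by_disease.setdefault(disease_id, []).append(link)

    rankings = []
    for disease_id, links in by_disease.items():
        links = tuple(sorted(links, key=lambda x: (-x.score, x.protein_id)))
        rankings.append(
            DiseaseRanking(
                disease_id=disease_id,
                disease_name=disease_map.disease_names.get(disease_id, ""),
                best_score=max(x.score for x in links),
                links=links,
            )
        )
    rankings.sort(key=lambda d: (-d.best_score, d.disease_id))
    return rankings
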