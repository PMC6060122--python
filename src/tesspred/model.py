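"""Domain types for multi-component medicine target analysis.

The data model mirrors the four-layer organisation of a traditional
multi-herb medicine: a formula (layer 1) is composed of crude drugs
(layer 2), each of which is a set of constituent compounds (layer 3),
and each compound maps to target proteins (layer 4) either through
curated interactions or through similarity-based prediction.

All identifiers are opaque strings; nothing is validated against
external databases so the toolkit runs fully offline.  Every derived
ordering is lexicographic by identifier so outputs are byte-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "TesspredError",
    "NotFoundError",
    "IntegrityError",
    "ConfigurationError",
    "ParseError",
    "DomainError",
    "Compound",
    "Protein",
    "CrudeDrug",
    "MedicineFormula",
    "InteractionRecord",
    "Interactome",
    "DiseaseTargetMap",
    "AnnotationNamespace",
    "NAMESPACES",
    "Registry",
    "resolve_hierarchy",
    "compound_target_union",
]

NAMESPACES = ("pathway", "brite", "process", "function")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class TesspredError(Exception):
    """Base class for all toolkit errors."""


class NotFoundError(TesspredError, KeyError):
    """An identifier could not be resolved in its registry."""


class IntegrityError(TesspredError, ValueError):
    """A cross-reference between tables is dangling or inconsistent."""


class ConfigurationError(TesspredError, ValueError):
    """Inputs are individually valid but mutually unusable (e.g. a
    fingerprint is missing for an interactome compound)."""


class ParseError(TesspredError, ValueError):
    """A file or structure string could not be parsed; carries enough
    context (offending text, line number) to locate the problem."""


class DomainError(TesspredError, ValueError):
    """A numeric argument violates its mathematical domain."""


# ---------------------------------------------------------------------------
# Entity types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compound:
    """A constituent compound (layer 3).

    ``structure`` is an optional SMILES string; ``fingerprint`` an
    optional sparse substructure-count vector (see
    :mod:`tesspred.similarity`).
    """

    compound_id: str
    name: str = ""
    structure: Optional[str] = None
    fingerprint: Optional["FeatureVector"] = None  # noqa: F821

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise IntegrityError("compound_id must be non-empty")


@dataclass(frozen=True)
class Protein:
    """A target protein (layer 4)."""

    protein_id: str
    symbol: str = ""
    annotations: Optional[Mapping[str, frozenset]] = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise IntegrityError("protein_id must be non-empty")


@dataclass(frozen=True)
class CrudeDrug:
    """A single medicinal-herb ingredient (layer 2): an ordered set of
    constituent compound IDs."""

    crude_drug_id: str
    name: str = ""
    compound_ids: tuple = ()

    def __post_init__(self) -> None:
        if not self.crude_drug_id:
            raise IntegrityError("crude_drug_id must be non-empty")
        if not self.compound_ids:
            raise IntegrityError(
                f"crude drug {self.crude_drug_id!r} has no constituent compounds"
            )
        object.__setattr__(self, "compound_ids", tuple(dict.fromkeys(self.compound_ids)))


@dataclass(frozen=True)
class MedicineFormula:
    """A multi-herb formula (layer 1): an ordered set of crude-drug IDs."""

    formula_id: str
    name: str = ""
    crude_drug_ids: tuple = ()

    def __post_init__(self) -> None:
        if not self.formula_id:
            raise IntegrityError("formula_id must be non-empty")
        if not self.crude_drug_ids:
            raise IntegrityError(f"formula {self.formula_id!r} has no crude drugs")
        object.__setattr__(
            self, "crude_drug_ids", tuple(dict.fromkeys(self.crude_drug_ids))
        )


@dataclass(frozen=True)
class InteractionRecord:
    """One curated compound–protein interaction.

    ``affinity`` is in nM when present.  A record is usable by the
    activity filter only if it carries an affinity or is explicitly
    flagged active.
    """

    compound_id: str
    protein_id: str
    affinity: Optional[float] = None
    active_flag: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.affinity is not None and not self.affinity > 0:
            raise IntegrityError(
                f"affinity must be > 0 nM, got {self.affinity!r} for "
                f"({self.compound_id}, {self.protein_id})"
            )

    @property
    def has_evidence(self) -> bool:
        return self.active_flag or self.affinity is not None


def _dedup_key(rec: InteractionRecord):
    # strongest evidence first: lowest affinity, then explicit active flag
    aff = rec.affinity if rec.affinity is not None else math.inf
    return (aff, not rec.active_flag, rec.source)


@dataclass(frozen=True)
class Interactome:
    """Deduplicated compound–protein interaction set plus the
    protein → known-ligand index that drives similarity search."""

    records: tuple
    ligands_by_protein: Mapping[str, tuple] = field(default_factory=dict)
    targets_by_compound: Mapping[str, tuple] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[InteractionRecord]) -> "Interactome":
        """Build an interactome, keeping for each (compound, protein)
        pair the record with the strongest evidence (lowest affinity)."""
        best: dict = {}
        for rec in records:
            key = (rec.compound_id, rec.protein_id)
            if key not in best or _dedup_key(rec) < _dedup_key(best[key]):
                best[key] = rec
        deduped = tuple(best[k] for k in sorted(best))
        ligands: dict = {}
        targets: dict = {}
        for rec in deduped:
            ligands.setdefault(rec.protein_id, []).append(rec.compound_id)
            targets.setdefault(rec.compound_id, []).append(rec.protein_id)
        return cls(
            records=deduped,
            ligands_by_protein={p: tuple(sorted(c)) for p, c in sorted(ligands.items())},
            targets_by_compound={c: tuple(sorted(p)) for c, p in sorted(targets.items())},
        )

    @property
    def compound_ids(self) -> tuple:
        return tuple(sorted(self.targets_by_compound))

    @property
    def protein_ids(self) -> tuple:
        return tuple(sorted(self.ligands_by_protein))

    def __len__(self) -> int:
        return len(self.records)

    def without_compound(self, compound_id: str) -> "Interactome":
        """A copy with every record of ``compound_id`` removed (used by
        leave-one-out evaluation)."""
        return Interactome.from_records(
            r for r in self.records if r.compound_id != compound_id
        )


@dataclass(frozen=True)
class DiseaseTargetMap:
    """Disease → therapeutic-target associations."""

    associations: frozenset  # of (disease_id, protein_id)
    disease_names: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple],
        disease_names: Optional[Mapping[str, str]] = None,
    ) -> "DiseaseTargetMap":
        return cls(
            associations=frozenset((d, p) for d, p in pairs),
            disease_names=dict(disease_names or {}),
        )

    def diseases_by_protein(self) -> Mapping[str, tuple]:
        out: dict = {}
        for d, p in sorted(self.associations):
            out.setdefault(p, []).append(d)
        return {p: tuple(sorted(ds)) for p, ds in out.items()}

    @property
    def protein_ids(self) -> tuple:
        return tuple(sorted({p for _, p in self.associations}))

    @property
    def disease_ids(self) -> tuple:
        return tuple(sorted({d for d, _ in self.associations}))


@dataclass(frozen=True)
class AnnotationNamespace:
    """One annotation vocabulary (pathway, brite, process or function):
    term_id → (term_name, frozenset of protein IDs)."""

    namespace: str
    terms: Mapping[str, tuple]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise IntegrityError(
                f"namespace must be one of {NAMESPACES}, got {self.namespace!r}"
            )
        for term_id, (_name, proteins) in self.terms.items():
            if not proteins:
                raise IntegrityError(f"term {term_id!r} has an empty protein set")

    def term_ids(self) -> tuple:
        return tuple(sorted(self.terms))

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# Registry and the 4-layer hierarchy
# ---------------------------------------------------------------------------

@dataclass
class Registry:
    """Identifier registries for compounds, crude drugs and formulas."""

    compounds: dict = field(default_factory=dict)
    crude_drugs: dict = field(default_factory=dict)
    formulas: dict = field(default_factory=dict)

    def add_compound(self, c: Compound) -> None:
        if c.compound_id in self.compounds:
            raise IntegrityError(f"duplicate compound_id {c.compound_id!r}")
        self.compounds[c.compound_id] = c

    def add_crude_drug(self, d: CrudeDrug) -> None:
        if d.crude_drug_id in self.crude_drugs:
            raise IntegrityError(f"duplicate crude_drug_id {d.crude_drug_id!r}")
        self.crude_drugs[d.crude_drug_id] = d

    def add_formula(self, f: MedicineFormula) -> None:
        if f.formula_id in self.formulas:
            raise IntegrityError(f"duplicate formula_id {f.formula_id!r}")
        self.formulas[f.formula_id] = f

    def validate(self) -> None:
        """Check that every cross-reference resolves."""
        for d in self.crude_drugs.values():
            for cid in d.compound_ids:
                if cid not in self.compounds:
                    raise IntegrityError(
                        f"crude drug {d.crude_drug_id!r} references unknown "
                        f"compound {cid!r}"
                    )
        for f in self.formulas.values():
            for did in f.crude_drug_ids:
                if did not in self.crude_drugs:
                    raise IntegrityError(
                        f"formula {f.formula_id!r} references unknown "
                        f"crude drug {did!r}"
                    )

    def constituent_compounds(self, entity_id: str) -> tuple:
        """Constituent compound IDs of a formula, crude drug or compound,
        in first-seen order, deduplicated."""
        if entity_id in self.formulas:
            seen: dict = {}
            for did in self.formulas[entity_id].crude_drug_ids:
                if did not in self.crude_drugs:
                    raise IntegrityError(
                        f"formula {entity_id!r} references unknown crude drug {did!r}"
                    )
                for cid in self.crude_drugs[did].compound_ids:
                    seen[cid] = None
            return tuple(seen)
        if entity_id in self.crude_drugs:
            return self.crude_drugs[entity_id].compound_ids
        if entity_id in self.compounds:
            return (entity_id,)
        raise NotFoundError(f"unknown entity {entity_id!r}")


def compound_target_union(
    compound_ids: Iterable[str],
    interactome: Interactome,
    extra_targets: Optional[Mapping[str, Iterable[str]]] = None,
) -> tuple:
    """Union of (known, and optionally predicted) target proteins over a
    set of compounds, sorted by protein ID.

    An empty compound set yields an empty tuple.  ``extra_targets`` lets
    callers merge predicted targets into the known layer-4 set.
    """
    out: set = set()
    for cid in compound_ids:
        out.update(interactome.targets_by_compound.get(cid, ()))
        if extra_targets is not None:
            out.update(extra_targets.get(cid, ()))
    return tuple(sorted(out))


def resolve_hierarchy(
    formula_id: str,
    registry: Registry,
    interactome: Interactome,
    predictions: Optional[Mapping[str, Iterable[str]]] = None,
) -> dict:
    """Expand a formula into its four-layer tree.

    Layers: formula → crude drugs → constituent compounds → target
    proteins.  The layer-4 leaf set of every node is the union over its
    constituent compounds of their known (and, when ``predictions`` is
    given, predicted) targets.  Every node carries its parent chain as
    provenance.  A compound shared by two crude drugs appears under
    both; the union is still computed over the deduplicated compound
    set.
    """
    if formula_id not in registry.formulas:
        raise NotFoundError(f"unknown formula {formula_id!r}")
    formula = registry.formulas[formula_id]

    crude_nodes = []
    for did in formula.crude_drug_ids:
        if did not in registry.crude_drugs:
            raise IntegrityError(
                f"formula {formula_id!r} references unknown crude drug {did!r}"
            )
        drug = registry.crude_drugs[did]
        compound_nodes = []
        for cid in drug.compound_ids:
            if cid not in registry.compounds:
                raise IntegrityError(
                    f"crude drug {did!r} references unknown compound {cid!r}"
                )
            targets = compound_target_union([cid], interactome, predictions)
            compound_nodes.append(
                {
                    "compound_id": cid,
                    "name": registry.compounds[cid].name,
                    "parents": [formula_id, did],
                    "targets": list(targets),
                }
            )
        crude_nodes.append(
            {
                "crude_drug_id": did,
                "name": drug.name,
                "parents": [formula_id],
                "compounds": compound_nodes,
                "targets": list(
                    compound_target_union(drug.compound_ids, interactome, predictions)
                ),
            }
        )

    all_compounds = registry.constituent_compounds(formula_id)
    return {
        "formula_id": formula_id,
        "name": formula.name,
        "parents": [],
        "crude_drugs": crude_nodes,
        "targets": list(
            compound_target_union(all_compounds, interactome, predictions)
        ),
    }
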