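"""Readers and writers for the interchange formats, plus the
run-configuration object behind the command-line workflows.

All tables are UTF-8 TSV with a header row; missing values are empty
fields.  Annotation term sets use the GMT convention
(term_id<TAB>term_name<TAB>protein ...), one file per namespace.
Hierarchies and ground truth are JSON.  Every writer's output is
readable by its paired reader (round-trip identity), and all rows are
emitted in deterministic (lexicographic) order so repeated runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .enrichment import EnrichmentQuery, enrich
from .model import (
    AnnotationNamespace,
    Compound,
    ConfigurationError,
    CrudeDrug,
    DiseaseTargetMap,
    IntegrityError,
    InteractionRecord,
    Interactome,
    MedicineFormula,
    NAMESPACES,
    NotFoundError,
    ParseError,
    Registry,
    compound_target_union,
)
from .similarity import FeatureVector
from .tess import (
    AggregatedPrediction,
    DEFAULT_AFFINITY_THRESHOLD_NM,
    TargetPrediction,
    filter_interactome,
)

__all__ = [
    "RunConfig",
    "read_fingerprints", "write_fingerprints",
    "read_interactome", "write_interactome",
    "read_compounds", "write_compounds",
    "read_compositions", "write_compositions",
    "read_gmt", "write_gmt",
    "read_disease_map", "write_disease_map",
    "read_predictions", "write_predictions",
    "write_aggregated", "write_enrichment", "write_indications",
    "write_hierarchy", "echo_config",
    "run_functional_analysis",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "{:.10g}"


def _read_tsv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Fingerprints (long sparse format: compound_id, feature_id, count)
# ---------------------------------------------------------------------------

def read_fingerprints(path) -> dict:
    df = _read_tsv(path, ["compound_id", "feature_id", "count"])
    out: dict = {}
    for cid, fid, count in df.itertuples(index=False):
        try:
            value = float(count)
        except ValueError:
            raise ParseError(f"{path}: non-numeric count {count!r} for "
                             f"({cid}, {fid})") from None
        out.setdefault(cid, {})[fid] = value
    return {cid: FeatureVector(counts) for cid, counts in out.items()}


def write_fingerprints(path, fingerprints: Mapping[str, FeatureVector]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tfeature_id\tcount\n")
        for cid in sorted(fingerprints):
            for fid in sorted(fingerprints[cid].counts):
                fh.write(f"{cid}\t{fid}\t"
                         + _FLOAT_FMT.format(fingerprints[cid].counts[fid]) + "\n")


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def read_interactome(path) -> tuple:
    """Read raw interaction records (unfiltered)."""
    df = _read_tsv(path, ["compound_id", "protein_id", "affinity_nM",
                          "active_flag", "source"])
    records = []
    for cid, pid, aff, flag, source in df.itertuples(index=False):
        affinity = None
        if aff != "":
            try:
                affinity = float(aff)
            except ValueError:
                raise ParseError(f"{path}: non-numeric affinity {aff!r} for "
                                 f"({cid}, {pid})") from None
        if flag not in ("0", "1"):
            raise ParseError(f"{path}: active_flag must be 0/1, got {flag!r}")
        records.append(
            InteractionRecord(compound_id=cid, protein_id=pid, affinity=affinity,
                              active_flag=flag == "1", source=source)
        )
    return tuple(records)


def write_interactome(path, records: Iterable[InteractionRecord]) -> None:
    rows = sorted(records, key=lambda r: (r.compound_id, r.protein_id, r.source))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tprotein_id\taffinity_nM\tactive_flag\tsource\n")
        for r in rows:
            aff = "" if r.affinity is None else _FLOAT_FMT.format(r.affinity)
            fh.write(f"{r.compound_id}\t{r.protein_id}\t{aff}\t"
                     f"{1 if r.active_flag else 0}\t{r.source}\n")


# ---------------------------------------------------------------------------
# Compound registry and composition tables
# ---------------------------------------------------------------------------

def read_compounds(path) -> dict:
    df = _read_tsv(path, ["compound_id", "name"])
    has_smiles = "smiles" in df.columns
    out = {}
    for row in df.itertuples(index=False):
        c = Compound(
            compound_id=row.compound_id,
            name=row.name,
            structure=(row.smiles or None) if has_smiles else None,
        )
        if c.compound_id in out:
            raise IntegrityError(f"{path}: duplicate compound_id {c.compound_id!r}")
        out[c.compound_id] = c
    return out


def write_compounds(path, registry: Registry) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tname\tsmiles\n")
        for cid in sorted(registry.compounds):
            c = registry.compounds[cid]
            fh.write(f"{c.compound_id}\t{c.name}\t{c.structure or ''}\n")


def read_compositions(formulas_path, crude_drugs_path,
                      compounds: Optional[Mapping[str, Compound]] = None) -> Registry:
    """Load formulas.tsv and crude_drugs.tsv (one row per edge) into a
    registry.  When ``compounds`` is omitted, bare compound entries are
    created from the composition table."""
    fdf = _read_tsv(formulas_path, ["formula_id", "formula_name", "crude_drug_id"])
    ddf = _read_tsv(crude_drugs_path, ["crude_drug_id", "crude_drug_name",
                                       "compound_id"])
    registry = Registry()

    drug_members: dict = {}
    drug_names: dict = {}
    for did, name, cid in ddf.itertuples(index=False):
        drug_members.setdefault(did, []).append(cid)
        drug_names[did] = name

    if compounds is None:
        for members in drug_members.values():
            for cid in members:
                if cid not in registry.compounds:
                    registry.add_compound(Compound(compound_id=cid))
    else:
        registry.compounds = dict(compounds)

    for did in drug_members:
        registry.add_crude_drug(
            CrudeDrug(crude_drug_id=did, name=drug_names[did],
                      compound_ids=tuple(drug_members[did]))
        )

    formula_members: dict = {}
    formula_names: dict = {}
    for fid, name, did in fdf.itertuples(index=False):
        formula_members.setdefault(fid, []).append(did)
        formula_names[fid] = name
    for fid in formula_members:
        registry.add_formula(
            MedicineFormula(formula_id=fid, name=formula_names[fid],
                            crude_drug_ids=tuple(formula_members[fid]))
        )
    registry.validate()
    return registry


def write_compositions(formulas_path, crude_drugs_path, registry: Registry) -> None:
    with open(formulas_path, "w", encoding="utf-8") as fh:
        fh.write("formula_id\tformula_name\tcrude_drug_id\n")
        for fid in sorted(registry.formulas):
            f = registry.formulas[fid]
            for did in f.crude_drug_ids:
                fh.write(f"{fid}\t{f.name}\t{did}\n")
    with open(crude_drugs_path, "w", encoding="utf-8") as fh:
        fh.write("crude_drug_id\tcrude_drug_name\tcompound_id\n")
        for did in sorted(registry.crude_drugs):
            d = registry.crude_drugs[did]
            for cid in d.compound_ids:
                fh.write(f"{did}\t{d.name}\t{cid}\n")


# ---------------------------------------------------------------------------
# GMT term sets
# ---------------------------------------------------------------------------

def read_gmt(path, namespace: str) -> AnnotationNamespace:
    """Parse a GMT file: term_id<TAB>term_name<TAB>protein ...

    Duplicate proteins within a term are deduplicated with a warning;
    a line with fewer than three fields is a parse error naming the
    line number.
    """
    terms = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs term_id, term_name and "
                    f"at least one protein"
                )
            term_id, term_name, proteins = parts[0], parts[1], parts[2:]
            proteins = [p for p in proteins if p]
            if len(set(proteins)) < len(proteins):
                warnings.warn(
                    f"{path}:{lineno}: duplicate protein IDs in term "
                    f"{term_id!r}; deduplicated",
                    stacklevel=2,
                )
            if term_id in terms:
                raise ParseError(f"{path}:{lineno}: duplicate term {term_id!r}")
            if not proteins:
                raise ParseError(f"{path}:{lineno}: term {term_id!r} has no proteins")
            terms[term_id] = (term_name, frozenset(proteins))
    return AnnotationNamespace(namespace=namespace, terms=terms)


def write_gmt(path, namespace: AnnotationNamespace) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(namespace.terms):
            name, proteins = namespace.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(proteins)]) + "\n")


# ---------------------------------------------------------------------------
# Disease map
# ---------------------------------------------------------------------------

def read_disease_map(path) -> DiseaseTargetMap:
    df = _read_tsv(path, ["disease_id", "disease_name", "protein_id"])
    pairs = []
    names = {}
    for did, name, pid in df.itertuples(index=False):
        pairs.append((did, pid))
        names[did] = name
    return DiseaseTargetMap.from_pairs(pairs, names)


def write_disease_map(path, disease_map: DiseaseTargetMap) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tdisease_name\tprotein_id\n")
        for did, pid in sorted(disease_map.associations):
            fh.write(f"{did}\t{disease_map.disease_names.get(did, '')}\t{pid}\n")


# ---------------------------------------------------------------------------
# Predictions and reports
# ---------------------------------------------------------------------------

def read_predictions(path) -> dict:
    """Per-compound prediction table → {compound_id: [TargetPrediction]}."""
    df = _read_tsv(path, ["compound_id", "protein_id", "score", "is_known",
                          "best_reference"])
    out: dict = {}
    for cid, pid, score, known, ref in df.itertuples(index=False):
        out.setdefault(cid, []).append(
            TargetPrediction(compound_id=cid, protein_id=pid, score=float(score),
                             is_known=known == "1", best_reference_compound_id=ref)
        )
    return out


def write_predictions(path, predictions: Sequence[TargetPrediction]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tprotein_id\tscore\tis_known\tbest_reference\n")
        for p in predictions:
            fh.write(f"{p.compound_id}\t{p.protein_id}\t"
                     + _FLOAT_FMT.format(p.score)
                     + f"\t{1 if p.is_known else 0}\t{p.best_reference_compound_id}\n")


def write_aggregated(path, predictions: Sequence[AggregatedPrediction]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tprotein_id\tscore\tis_known\tcontributions\n")
        for p in predictions:
            contribs = ";".join(
                f"{cid}:" + _FLOAT_FMT.format(s) for cid, s, _ in p.contributions
            )
            fh.write(f"{p.entity_id}\t{p.protein_id}\t"
                     + _FLOAT_FMT.format(p.score)
                     + f"\t{1 if p.is_known else 0}\t{contribs}\n")


def write_enrichment(path, rows) -> None:
    """Report table: term, name, enrichment ratio, p, q (+ the z/k/r
    counts behind them)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tenrichment_ratio\tp_value\tq_value\tz\tk\tr\n")
        for row in rows:
            fh.write(f"{row.term_id}\t{row.term_name}\t"
                     + _FLOAT_FMT.format(row.ratio) + "\t"
                     + _FLOAT_FMT.format(row.p_value) + "\t"
                     + _FLOAT_FMT.format(row.q_value)
                     + f"\t{row.z}\t{row.k}\t{row.r}\n")


def write_indications(rankings_path, links_path, rankings) -> None:
    with open(rankings_path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tdisease_name\tbest_score\tn_links\n")
        for d in rankings:
            fh.write(f"{d.disease_id}\t{d.disease_name}\t"
                     + _FLOAT_FMT.format(d.best_score) + f"\t{len(d.links)}\n")
    with open(links_path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tdisease_id\tprotein_id\tscore\tvia_known\n")
        for d in rankings:
            for x in d.links:
                fh.write(f"{x.compound_id}\t{x.disease_id}\t{x.protein_id}\t"
                         + _FLOAT_FMT.format(x.score)
                         + f"\t{1 if x.via_known else 0}\n")


def write_hierarchy(path, tree: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree, fh, indent=2, sort_keys=True)
        fh.write("\n")


def echo_config(outdir, name: str, params: Mapping) -> None:
    """Record parameter provenance for a run (no timestamps, so reruns
    stay byte-identical)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{name}.config.json", "w", encoding="utf-8") as fh:
        json.dump({k: str(v) for k, v in sorted(params.items())}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Functional-analysis workflow
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and options for the enrichment workflow.

    ``background`` selects the hypergeometric universe: the default
    ``"interactome"`` uses every protein of the activity-filtered
    interaction set (plus the query's own targets); a path to a
    one-ID-per-line file supplies an explicit universe.
    """

    formulas_path: str
    crude_drugs_path: str
    interactome_path: str
    gmt_paths: Mapping[str, str]
    out_dir: str
    background: str = "interactome"
    min_score: float = 0.0
    top_n: Optional[int] = None
    fdr_method: str = "bh"
    threshold_nM: float = DEFAULT_AFFINITY_THRESHOLD_NM
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        for p in (self.formulas_path, self.crude_drugs_path, self.interactome_path,
                  *self.gmt_paths.values()):
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        for ns in self.gmt_paths:
            if ns not in NAMESPACES:
                raise ConfigurationError(f"unknown namespace {ns!r}")
        if self.fdr_method != "bh":
            raise ConfigurationError(f"unsupported FDR method {self.fdr_method!r}")
        if not 0.0 <= self.min_score <= 1.0:
            raise ConfigurationError("min_score must lie in [0, 1]")


def run_functional_analysis(config: RunConfig, query: str) -> dict:
    """Enrich the known-target set of a formula, crude drug or compound
    against every configured namespace; one sorted TSV per namespace.

    Returns {namespace: report path}.  An unknown query raises
    :class:`NotFoundError`; a query with no targets yields header-only
    reports with a warning.
    """
    config.validate()
    registry = read_compositions(config.formulas_path, config.crude_drugs_path)
    records = read_interactome(config.interactome_path)
    interactome = filter_interactome(records, config.threshold_nM)

    compound_ids = registry.constituent_compounds(query)  # raises NotFoundError
    g_comp = frozenset(compound_target_union(compound_ids, interactome))

    if config.background == "interactome":
        background = frozenset(interactome.protein_ids) | g_comp
    else:
        with open(config.background, encoding="utf-8") as fh:
            background = frozenset(line.strip() for line in fh if line.strip())
        if not g_comp <= background:
            raise ConfigurationError(
                "explicit background does not cover the query's targets"
            )

    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    echo_config(outdir, "enrich",
                {**dataclasses.asdict(config), "query": query,
                 "n_targets": len(g_comp), "background_size": len(background)})

    if not g_comp:
        warnings.warn(f"query {query!r} has no known targets; reports are empty",
                      stacklevel=2)

    out_paths = {}
    for ns in sorted(config.gmt_paths):
        namespace = read_gmt(config.gmt_paths[ns], ns)
        rows = (
            enrich(EnrichmentQuery(g_comp=g_comp, namespace=namespace,
                                   background=background))
            if g_comp else []
        )
        path = outdir / f"enrichment_{ns}.tsv"
        write_enrichment(path, rows)
        out_paths[ns] = str(path)
    return out_paths
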