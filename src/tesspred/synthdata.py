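"""Seeded generator of synthetic inputs with the structure the method
assumes.

The generator emulates the statistical backbone that makes
similarity-search target prediction work on real chemogenomic data:

* compounds come in *ligand families* that share a core substructure
  profile (plus private noise features), so chemical similarity is
  informative;
* each protein's known ligands are drawn mostly from one family, so a
  held-out ligand's family mates point back to its targets;
* affinities are log-uniform across [1 nM, 1 mM], guaranteeing records
  on both sides of the 30 μM activity filter;
* medicines are built as formula → crude drug → compound trees whose
  crude drugs sample one family each, giving coherent target sets;
* annotation namespaces contain one *planted* term enriched for the
  designated query formula's target set, plus random terms;
* a disease–target map overlaps the protein universe.

Everything is driven by ``numpy``'s PCG64 generator seeded from
``SynthConfig.seed``; the same seed and config yield byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    AnnotationNamespace,
    Compound,
    ConfigurationError,
    CrudeDrug,
    DiseaseTargetMap,
    InteractionRecord,
    Interactome,
    MedicineFormula,
    NAMESPACES,
    Registry,
)
from .similarity import FeatureVector

__all__ = [
    "SynthConfig",
    "simulate_interactome",
    "simulate_medicines",
    "simulate_annotations_and_diseases",
    "simulate_bundle",
    "benchmark_loo_ranks",
    "benchmark_planted_enrichment",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults are sized like a small curated chemogenomic study: a few
    hundred compounds in a dozen ligand families against 150 proteins,
    with four formulas of three single-family herbs each.
    """

    seed: int = 0
    n_proteins: int = 150
    n_compounds: int = 400
    n_features: int = 600
    n_families: int = 12
    family_feature_overlap: float = 0.8
    interactions_per_protein: int = 8
    n_formulas: int = 4
    crude_drugs_per_formula: int = 3
    compounds_per_crude_drug: int = 5
    n_terms_per_namespace: int = 25
    planted_term_effect: float = 0.8
    n_diseases: int = 25
    # secondary knobs
    n_noise_features: int = 6
    core_features_per_family: int = 25
    within_family_ligand_fraction: float = 0.85
    affinity_range_nM: tuple = (1.0, 1_000_000.0)
    flag_only_fraction: float = 0.08
    active_flag_fraction: float = 0.05
    term_size_range: tuple = (5, 40)
    disease_size_range: tuple = (3, 12)

    def __post_init__(self) -> None:
        positive = (
            "n_proteins", "n_compounds", "n_features", "n_families",
            "interactions_per_protein", "n_formulas", "crude_drugs_per_formula",
            "compounds_per_crude_drug", "n_terms_per_namespace", "n_diseases",
            "core_features_per_family",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("family_feature_overlap", "planted_term_effect",
                     "within_family_ligand_fraction", "flag_only_fraction",
                     "active_flag_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_families > self.n_compounds:
            raise ConfigurationError(
                f"n_families ({self.n_families}) exceeds n_compounds "
                f"({self.n_compounds})"
            )
        if self.n_families * self.core_features_per_family > self.n_features:
            raise ConfigurationError(
                "n_features too small for disjoint family core feature blocks"
            )
        if self.n_noise_features < 0:
            raise ConfigurationError("n_noise_features must be >= 0")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _protein_ids(config: SynthConfig) -> list:
    return [f"P{i + 1:04d}" for i in range(config.n_proteins)]


def _compound_ids(config: SynthConfig) -> list:
    return [f"C{i + 1:05d}" for i in range(config.n_compounds)]


def simulate_interactome(config: SynthConfig):
    """Generate fingerprints, interaction records and family labels.

    Returns ``(fingerprints, interactome, families)`` where
    ``fingerprints`` maps compound_id → :class:`FeatureVector`,
    ``interactome`` holds the *unfiltered* deduplicated records (apply
    :func:`tesspred.tess.filter_interactome` to its ``records`` for the
    activity-filtered view), and ``families`` maps compound and protein
    IDs to their ground-truth family index.
    """
    rng = _rng(config, 1)
    compound_ids = _compound_ids(config)
    protein_ids = _protein_ids(config)
    features = [f"f{i + 1:05d}" for i in range(config.n_features)]

    # disjoint core feature blocks, one per family; leftovers are noise pool
    order = rng.permutation(config.n_features)
    cores = []
    for fam in range(config.n_families):
        lo = fam * config.core_features_per_family
        cores.append([features[j] for j in order[lo:lo + config.core_features_per_family]])
    noise_pool = [features[j]
                  for j in order[config.n_families * config.core_features_per_family:]]
    # a fixed per-family count profile over its core features
    core_counts = [rng.integers(1, 5, size=config.core_features_per_family)
                   for _ in range(config.n_families)]

    fam_of_compound = {
        cid: int(rng.integers(0, config.n_families)) for cid in compound_ids
    }
    fingerprints = {}
    for cid in compound_ids:
        fam = fam_of_compound[cid]
        counts = {}
        keep = rng.random(config.core_features_per_family) < config.family_feature_overlap
        for j, fid in enumerate(cores[fam]):
            if keep[j]:
                counts[fid] = int(core_counts[fam][j])
        if config.n_noise_features and noise_pool:
            picks = rng.choice(len(noise_pool),
                               size=min(config.n_noise_features, len(noise_pool)),
                               replace=False)
            for j in picks:
                counts[noise_pool[int(j)]] = counts.get(noise_pool[int(j)], 0) + 1
        fingerprints[cid] = FeatureVector(counts)

    compounds_by_family: dict = {}
    for cid, fam in fam_of_compound.items():
        compounds_by_family.setdefault(fam, []).append(cid)

    fam_of_protein = {
        pid: int(rng.integers(0, config.n_families)) for pid in protein_ids
    }
    lo_nM, hi_nM = config.affinity_range_nM
    records = []
    for pid in protein_ids:
        fam = fam_of_protein[pid]
        pool = compounds_by_family.get(fam, compound_ids)
        picked = set()
        for _ in range(config.interactions_per_protein):
            if rng.random() < config.within_family_ligand_fraction and pool:
                cid = pool[int(rng.integers(0, len(pool)))]
            else:
                cid = compound_ids[int(rng.integers(0, config.n_compounds))]
            if cid in picked:
                continue
            picked.add(cid)
            if rng.random() < config.flag_only_fraction:
                affinity, flag = None, True
            else:
                affinity = float(np.exp(rng.uniform(np.log(lo_nM), np.log(hi_nM))))
                flag = bool(rng.random() < config.active_flag_fraction)
            records.append(
                InteractionRecord(
                    compound_id=cid,
                    protein_id=pid,
                    affinity=affinity,
                    active_flag=flag,
                    source="synthetic",
                )
            )
    families = {**fam_of_compound, **fam_of_protein}
    return fingerprints, Interactome.from_records(records), families


def simulate_medicines(config: SynthConfig, families: Mapping[str, int]) -> Registry:
    """Build the formula → crude drug → compound registry.

    Each crude drug samples its constituent compounds from a single
    ligand family (a herb's chemistry is coherent), so a formula's
    known-target set is family-structured like a real medicine's.
    """
    rng = _rng(config, 2)
    compound_ids = _compound_ids(config)
    by_family: dict = {}
    for cid in compound_ids:
        by_family.setdefault(families[cid], []).append(cid)

    registry = Registry()
    for cid in compound_ids:
        registry.add_compound(Compound(compound_id=cid, name=f"compound {cid[1:]}"))

    drug_idx = 0
    for f in range(config.n_formulas):
        drug_ids = []
        for _ in range(config.crude_drugs_per_formula):
            drug_idx += 1
            fam = int(rng.integers(0, config.n_families))
            pool = by_family.get(fam) or compound_ids
            n = min(config.compounds_per_crude_drug, len(pool))
            members = sorted(
                pool[int(j)] for j in rng.choice(len(pool), size=n, replace=False)
            )
            did = f"D{drug_idx:03d}"
            registry.add_crude_drug(
                CrudeDrug(crude_drug_id=did, name=f"crude drug {drug_idx}",
                          compound_ids=tuple(members))
            )
            drug_ids.append(did)
        fid = f"F{f + 1:03d}"
        registry.add_formula(
            MedicineFormula(formula_id=fid, name=f"formula {f + 1}",
                            crude_drug_ids=tuple(drug_ids))
        )
    registry.validate()
    return registry


def simulate_annotations_and_diseases(
    config: SynthConfig,
    universe: Sequence[str],
    query_targets: Sequence[str],
):
    """Generate the four annotation namespaces and the disease map.

    In each namespace one designated term is *planted*: it receives
    ``round(planted_term_effect * len(query_targets))`` members of the
    query target set (its remaining members are random non-query
    proteins).  All other terms, and all disease target sets, are
    uniform draws from the universe.  Returns ``(namespaces,
    disease_map, truth)`` where ``truth`` records the planted term IDs.
    """
    if not len(universe):
        raise ConfigurationError("protein universe must be non-empty")
    rng = _rng(config, 3)
    universe = sorted(universe)
    query_targets = sorted(set(query_targets) & set(universe))
    n_plant = int(round(config.planted_term_effect * len(query_targets)))
    lo, hi = config.term_size_range
    if n_plant > min(hi, len(universe)):
        raise ConfigurationError(
            f"planted_term_effect places {n_plant} proteins into one term, "
            f"exceeding the term capacity {min(hi, len(universe))}"
        )

    prefixes = {"pathway": "PWY", "brite": "BRT", "process": "PRC", "function": "FNC"}
    non_query = [p for p in universe if p not in set(query_targets)]
    namespaces = {}
    planted = {}
    for ns in NAMESPACES:
        terms = {}
        planted_idx = int(rng.integers(0, config.n_terms_per_namespace))
        for t in range(config.n_terms_per_namespace):
            term_id = f"{prefixes[ns]}{t + 1:04d}"
            size = int(rng.integers(lo, min(hi, len(universe)) + 1))
            if t == planted_idx and n_plant > 0:
                members = sorted(
                    query_targets[int(j)]
                    for j in rng.choice(len(query_targets), size=n_plant, replace=False)
                )
                n_fill = max(size - n_plant, 0)
                if n_fill and non_query:
                    n_fill = min(n_fill, len(non_query))
                    members += [non_query[int(j)]
                                for j in rng.choice(len(non_query), size=n_fill,
                                                    replace=False)]
                members = sorted(set(members))
            else:
                members = sorted(
                    universe[int(j)]
                    for j in rng.choice(len(universe), size=size, replace=False)
                )
            terms[term_id] = (f"{ns} term {t + 1}", frozenset(members))
            if t == planted_idx:
                planted[ns] = term_id
        namespaces[ns] = AnnotationNamespace(namespace=ns, terms=terms)

    d_lo, d_hi = config.disease_size_range
    pairs = []
    disease_names = {}
    for d in range(config.n_diseases):
        disease_id = f"DIS{d + 1:03d}"
        disease_names[disease_id] = f"disease {d + 1}"
        size = int(rng.integers(d_lo, min(d_hi, len(universe)) + 1))
        for j in rng.choice(len(universe), size=size, replace=False):
            pairs.append((disease_id, universe[int(j)]))
    disease_map = DiseaseTargetMap.from_pairs(pairs, disease_names)

    truth = {"planted_terms": planted, "n_planted_members": n_plant}
    return namespaces, disease_map, truth


def simulate_bundle(config: SynthConfig, outdir) -> dict:
    """Generate and write the full input bundle to ``outdir``.

    Files: fingerprints.tsv, interactome.tsv, compounds.tsv,
    crude_drugs.tsv, formulas.tsv, one GMT per namespace, diseases.tsv
    and truth.json (ground-truth family labels, planted terms and the
    designated query formula with its known target set).  Returns the
    truth dictionary.
    """
    import json
    from pathlib import Path

    from . import io as tio
    from .model import compound_target_union
    from .tess import filter_interactome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fingerprints, interactome, families = simulate_interactome(config)
    registry = simulate_medicines(config, families)

    filtered = filter_interactome(interactome.records)
    query_formula = sorted(registry.formulas)[0]
    g_comp = compound_target_union(
        registry.constituent_compounds(query_formula), filtered
    )
    if not g_comp:
        raise ConfigurationError(
            "designated query formula has no known targets after filtering; "
            "increase interactions_per_protein or compound counts"
        )
    universe = _protein_ids(config)
    namespaces, disease_map, truth = simulate_annotations_and_diseases(
        config, universe, g_comp
    )

    tio.write_fingerprints(outdir / "fingerprints.tsv", fingerprints)
    tio.write_interactome(outdir / "interactome.tsv", interactome.records)
    tio.write_compounds(outdir / "compounds.tsv", registry)
    tio.write_compositions(outdir / "formulas.tsv", outdir / "crude_drugs.tsv", registry)
    for ns, namespace in namespaces.items():
        tio.write_gmt(outdir / f"{ns}.gmt", namespace)
    tio.write_disease_map(outdir / "diseases.tsv", disease_map)

    truth = {
        **truth,
        "query_formula": query_formula,
        "query_targets": list(g_comp),
        "families": {k: int(v) for k, v in sorted(families.items())},
        "protein_universe": universe,
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# Benchmark studies over the generator
# ---------------------------------------------------------------------------

def benchmark_loo_ranks(config: SynthConfig, n_queries: int = 25) -> dict:
    """Leave-one-compound-out target recovery on one simulated study.

    A deterministic sample of ``n_queries`` interactome compounds is
    held out in turn; for each, the 1-based rank of every true target
    in the TESS ranking over the reduced interactome is recorded.
    Returns the rank list plus the protein count (the chance-level
    median rank is ``n_proteins / 2``).
    """
    from .tess import filter_interactome, leave_one_out_ranks

    fingerprints, interactome, _ = simulate_interactome(config)
    filtered = filter_interactome(interactome.records)
    eligible = list(filtered.compound_ids)
    rng = _rng(config, 4)
    n = min(n_queries, len(eligible))
    picked = sorted(eligible[int(j)]
                    for j in rng.choice(len(eligible), size=n, replace=False))
    ranks = [rank for _, _, rank, _ in
             leave_one_out_ranks(filtered, fingerprints, picked)]
    return {"ranks": ranks, "n_proteins": config.n_proteins, "n_queries": n}


def benchmark_planted_enrichment(config: SynthConfig,
                                 namespace: str = "pathway") -> dict:
    """One simulated enrichment study: is the planted term the
    namespace minimum?

    Simulates the interactome, medicines and annotations, enriches the
    designated query formula's known-target set against the full
    protein universe and reports the planted term's p-value alongside
    the namespace minimum.

    Because the hypergeometric tail is a discrete statistic, its raw
    p-value is super-uniform (P(p <= t) <= t) rather than uniform under
    the null; the returned ``p_planted_randomized`` applies the
    randomization transform p_rand = P(X > z) + U * P(X = z), which is
    exactly Uniform(0, 1) when no term is planted and is the calibrated
    object for null-uniformity checks.
    """
    from .enrichment import EnrichmentQuery, enrich, hypergeom_tail
    from .model import compound_target_union
    from .tess import filter_interactome

    _, interactome, families = simulate_interactome(config)
    filtered = filter_interactome(interactome.records)
    registry = simulate_medicines(config, families)
    query_formula = sorted(registry.formulas)[0]
    g_comp = compound_target_union(
        registry.constituent_compounds(query_formula), filtered
    )
    universe = _protein_ids(config)
    namespaces, _, truth = simulate_annotations_and_diseases(config, universe, g_comp)
    rows = enrich(EnrichmentQuery(g_comp=frozenset(g_comp),
                                  namespace=namespaces[namespace],
                                  background=frozenset(universe)))
    planted_id = truth["planted_terms"][namespace]
    p_by_term = {row.term_id: row.p_value for row in rows}
    min_p = min(p_by_term.values())

    planted_row = next(row for row in rows if row.term_id == planted_id)
    l = len(universe)
    p_gt = (hypergeom_tail(l, planted_row.k, planted_row.r, planted_row.z + 1)
            if planted_row.z + 1 <= min(planted_row.k, planted_row.r) else 0.0)
    pmf = planted_row.p_value - p_gt
    u = float(_rng(config, 5).random())
    return {
        "planted_term": planted_id,
        "p_planted": p_by_term[planted_id],
        "p_planted_randomized": p_gt + u * pmf,
        "min_p": min_p,
        "planted_is_min": p_by_term[planted_id] == min_p,
        "n_targets": len(g_comp),
    }
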