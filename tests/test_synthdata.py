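"""The synthetic-data generator: determinism, planted structure and
compatibility with every reader."""

import dataclasses
import filecmp
import warnings
from pathlib import Path

import pytest

import tesspred.io as tio
from tesspred import (
    SynthConfig,
    generalized_jaccard,
    simulate_annotations_and_diseases,
    simulate_bundle,
    simulate_interactome,
    simulate_medicines,
)
from tesspred.model import ConfigurationError, NAMESPACES


class TestConfig:
    def test_more_families_than_compounds_rejected(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(n_families=10, n_compounds=5)

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(family_feature_overlap=1.5)

    def test_feature_space_must_fit_family_cores(self):
        with pytest.raises(ConfigurationError):
            SynthConfig(n_features=10, n_families=4, core_features_per_family=10)


class TestInteractomeGeneration:
    def test_same_seed_same_output(self, small_config):
        a = simulate_interactome(small_config)
        b = simulate_interactome(small_config)
        assert a[0] == b[0]
        assert a[1].records == b[1].records
        assert a[2] == b[2]

    def test_different_seeds_differ(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert simulate_interactome(small_config)[1].records != \
            simulate_interactome(other)[1].records

    def test_full_overlap_no_noise_gives_identical_family_vectors(self):
        config = SynthConfig(seed=3, n_proteins=10, n_compounds=30, n_features=120,
                             n_families=3, family_feature_overlap=1.0,
                             n_noise_features=0, core_features_per_family=10)
        fps, _, families = simulate_interactome(config)
        by_family: dict = {}
        for cid, fam in families.items():
            if cid in fps:
                by_family.setdefault(fam, []).append(cid)
        for members in by_family.values():
            for cid in members[1:]:
                assert generalized_jaccard(fps[members[0]], fps[cid]) == 1.0

    def test_affinities_straddle_the_filter_boundary(self, small_config):
        _, interactome, _ = simulate_interactome(small_config)
        affinities = [r.affinity for r in interactome.records
                      if r.affinity is not None]
        assert any(a < 30000.0 for a in affinities)
        assert any(a >= 30000.0 for a in affinities)

    def test_within_family_similarity_exceeds_between(self, small_config):
        fps, _, families = simulate_interactome(small_config)
        cids = sorted(fps)
        within, between = [], []
        for i, a in enumerate(cids[:30]):
            for b in cids[i + 1:30]:
                s = generalized_jaccard(fps[a], fps[b])
                (within if families[a] == families[b] else between).append(s)
        assert sum(within) / len(within) > sum(between) / len(between)


class TestMedicines:
    def test_registry_resolves(self, small_config):
        _, _, families = simulate_interactome(small_config)
        registry = simulate_medicines(small_config, families)
        assert len(registry.formulas) == small_config.n_formulas
        registry.validate()

    def test_crude_drug_members_share_a_family(self, small_config):
        _, _, families = simulate_interactome(small_config)
        registry = simulate_medicines(small_config, families)
        for drug in registry.crude_drugs.values():
            assert len({families[c] for c in drug.compound_ids}) == 1


class TestAnnotations:
    def test_planted_term_contains_query_targets(self, small_config):
        universe = [f"P{i + 1:04d}" for i in range(small_config.n_proteins)]
        query = universe[:10]
        namespaces, _, truth = simulate_annotations_and_diseases(
            small_config, universe, query)
        assert set(namespaces) == set(NAMESPACES)
        for ns in NAMESPACES:
            _, members = namespaces[ns].terms[truth["planted_terms"][ns]]
            expected = round(small_config.planted_term_effect * len(query))
            assert len(members & set(query)) >= expected

    def test_zero_effect_plants_nothing(self, small_config):
        config = dataclasses.replace(small_config, planted_term_effect=0.0)
        universe = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
        _, _, truth = simulate_annotations_and_diseases(config, universe,
                                                        universe[:10])
        assert truth["n_planted_members"] == 0

    def test_effect_exceeding_term_capacity_rejected(self, small_config):
        config = dataclasses.replace(small_config, term_size_range=(2, 4))
        universe = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
        with pytest.raises(ConfigurationError):
            simulate_annotations_and_diseases(config, universe, universe[:15])

    def test_empty_universe_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            simulate_annotations_and_diseases(small_config, [], [])

    def test_disease_map_overlaps_universe(self, small_config):
        universe = [f"P{i + 1:04d}" for i in range(small_config.n_proteins)]
        _, dmap, _ = simulate_annotations_and_diseases(small_config, universe,
                                                       universe[:10])
        assert set(dmap.protein_ids) <= set(universe)
        assert len(dmap.disease_ids) == small_config.n_diseases


class TestBundle:
    def test_bundle_is_byte_deterministic(self, small_config, tmp_path):
        simulate_bundle(small_config, tmp_path / "a")
        simulate_bundle(small_config, tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in files:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_bundle_reads_back_without_warnings(self, small_config, tmp_path):
        simulate_bundle(small_config, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fps = tio.read_fingerprints(tmp_path / "fingerprints.tsv")
            records = tio.read_interactome(tmp_path / "interactome.tsv")
            registry = tio.read_compositions(
                tmp_path / "formulas.tsv", tmp_path / "crude_drugs.tsv",
                tio.read_compounds(tmp_path / "compounds.tsv"))
            for ns in NAMESPACES:
                tio.read_gmt(tmp_path / f"{ns}.gmt", ns)
            tio.read_disease_map(tmp_path / "diseases.tsv")
        registry.validate()
        assert len(fps) == small_config.n_compounds
        assert records
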