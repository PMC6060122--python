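import pytest

from tesspred import (
    Compound,
    CrudeDrug,
    FeatureVector,
    Interactome,
    InteractionRecord,
    MedicineFormula,
    Registry,
    SynthConfig,
)


@pytest.fixture
def toy_registry() -> Registry:
    """Formula → herb → compound tree mirroring a classic cold-remedy
    formula whose ephedrine-type alkaloid hits an adrenoceptor."""
    reg = Registry()
    for cid, name in [
        ("methylephedrine", "Methylephedrine"),
        ("puerarin", "Puerarin"),
        ("glycyrrhizin", "Glycyrrhizin"),
        ("inert", "Inert compound"),
    ]:
        reg.add_compound(Compound(compound_id=cid, name=name))
    reg.add_crude_drug(CrudeDrug("ephedra-herb", "Ephedra herb",
                                 ("methylephedrine", "glycyrrhizin")))
    reg.add_crude_drug(CrudeDrug("kudzu-root", "Kudzu root",
                                 ("puerarin", "glycyrrhizin")))
    reg.add_crude_drug(CrudeDrug("inert-herb", "Inert herb", ("inert",)))
    reg.add_formula(MedicineFormula("kakkonto", "Kakkonto",
                                    ("ephedra-herb", "kudzu-root")))
    reg.add_formula(MedicineFormula("placebo", "Placebo formula", ("inert-herb",)))
    reg.validate()
    return reg


@pytest.fixture
def toy_interactome() -> Interactome:
    return Interactome.from_records([
        InteractionRecord("methylephedrine", "ADRA1D", affinity=120.0),
        InteractionRecord("methylephedrine", "ADRB2", affinity=900.0),
        InteractionRecord("puerarin", "ADRB2", affinity=5000.0),
        InteractionRecord("puerarin", "ESR1", active_flag=True),
        InteractionRecord("glycyrrhizin", "HSD11B1", affinity=400.0),
    ])


@pytest.fixture
def small_config() -> SynthConfig:
    """Scaled-down generator settings for fast unit tests; the default
    config is exercised by the acceptance suite."""
    return SynthConfig(
        seed=11,
        n_proteins=20,
        n_compounds=60,
        n_features=200,
        n_families=4,
        interactions_per_protein=5,
        n_terms_per_namespace=10,
        n_diseases=8,
        core_features_per_family=15,
        term_size_range=(3, 10),
    )


def make_vec(d) -> FeatureVector:
    return FeatureVector(d)
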