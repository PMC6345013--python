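import logging

import pytest
from hypothesis import HealthCheck, settings

import mycoflux as mf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# silence the (intentional) unknown-gene warnings emitted while fixtures
# assemble models gene-by-gene
logging.getLogger("mycoflux.core").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mini_model():
    return mf.generate_mini_model()


@pytest.fixture(scope="session")
def glucose_minimal(mini_model):
    """Mini model on glucose minimal medium (uptake 2.0 mmol/gDW/h)."""
    return mf.set_medium(mini_model, mf.minimal_medium())


@pytest.fixture(scope="session")
def study_model(mini_model):
    """Mini model under the stilbene study constraints (glucose 1.0)."""
    return mf.set_medium(mini_model, mf.stilbene_study_medium())


@pytest.fixture(scope="session")
def pdb_model(mini_model):
    """Mini model on the rich-medium approximation."""
    return mf.set_medium(mini_model, mf.pdb_medium())


@pytest.fixture()
def toy_chain():
    """EX_A <- A -> B -> EX_B linear chain with uptake capped at 5."""
    model = mf.MetabolicModel("chain")
    for base in ("a", "b"):
        model.add_metabolite(mf.Metabolite(f"{base}[e]", compartment="e"))
        model.add_metabolite(mf.Metabolite(f"{base}[c]", compartment="c"))
    model.add_reaction(mf.Reaction(
        "EX_a", stoichiometry={"a[e]": -1}, lower_bound=-5.0,
        upper_bound=1000.0, kind="exchange"))
    model.add_reaction(mf.Reaction(
        "At", stoichiometry={"a[e]": -1, "a[c]": 1}, lower_bound=-1000.0,
        upper_bound=1000.0, kind="transport"))
    model.add_reaction(mf.Reaction(
        "AB", stoichiometry={"a[c]": -1, "b[c]": 1}, upper_bound=1000.0))
    model.add_reaction(mf.Reaction(
        "Bt", stoichiometry={"b[c]": -1, "b[e]": 1}, upper_bound=1000.0,
        kind="transport"))
    model.add_reaction(mf.Reaction(
        "EX_b", stoichiometry={"b[e]": -1}, upper_bound=1000.0,
        kind="exchange"))
    model.set_objective("EX_b")
    return model
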