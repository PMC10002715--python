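import pytest

from mcmm.community import AbundanceProfile, CommunityModel
from mcmm.medium import DietDefinition, Medium
from mcmm.synthetic import make_degenerate_taxon, make_taxon_model


@pytest.fixture
def butyrogen():
    return make_taxon_model("butyrogen")


@pytest.fixture
def non_producer():
    return make_taxon_model("non_producer")


@pytest.fixture
def toy_library(butyrogen, non_producer):
    return [butyrogen, non_producer]


@pytest.fixture
def glucose_medium():
    return Medium.from_diet(DietDefinition("glucose_dm", {"glucose": 10.0}))


@pytest.fixture
def two_taxon_community(toy_library, glucose_medium):
    """The reference two-taxon glucose community: butyrogen (yield 0.2
    biomass + 2 butyrate per glucose) and a non-producer (yield 0.4), equal
    abundance, shared glucose import capped at 10 mmol/gDW/h."""
    profile = AbundanceProfile("toy", {"butyrogen": 0.5, "non_producer": 0.5})
    return CommunityModel.build(profile, toy_library, glucose_medium)


@pytest.fixture
def degenerate_community(glucose_medium):
    """Acetate/butyrate-split producer + unique-pathway propionogen."""
    deg = make_degenerate_taxon()
    prop = make_taxon_model("propionogen")
    profile = AbundanceProfile(
        "degen", {"degenerate_producer": 0.5, "propionogen": 0.5}
    )
    return CommunityModel.build(profile, [deg, prop], glucose_medium)
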