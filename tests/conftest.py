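import pytest

from plasmabind import GroundTruth, TitrationDesign, generate_titration


@pytest.fixture
def default_design():
    """Noiseless study titration design: 1e-6 M protein, ratios 0..2
    in 0.4 steps, 297/303/308 K."""
    return TitrationDesign()


@pytest.fixture
def hsa_5a_series(default_design):
    """Noiseless titrations for the strong-binder reference complex,
    Kb(297 K) = 1.26e5 dm3/mol, 1:1 stoichiometry, exothermic binding."""
    truth = GroundTruth.from_kb_and_enthalpy(kb_ref=1.26e5, dh=-60e3)
    return generate_titration(default_design, truth)
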