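import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from panstrep import SimulationParams, build_pan_pool, simulate_pangenome


@pytest.fixture(scope="session")
def zero_div_sim():
    """3 strains; 3 core, 1 dispensable (2 strains), 2 specific per strain;
    zero divergence, so family members are byte-identical."""
    params = SimulationParams(
        n_strains=3,
        n_core=3,
        dispensable_spec=((1, 2),),
        n_specific_per_strain=2,
        gene_length_range=(150, 400),
        divergence=0.0,
        seed=42,
    )
    return simulate_pangenome(params)


@pytest.fixture(scope="session")
def zero_div_result(zero_div_sim):
    strains, _ = zero_div_sim
    return build_pan_pool(strains)
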