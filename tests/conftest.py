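import numpy as np
import pytest

from lakeomp import synthetic
from lakeomp.scenario import conical_geometry


@pytest.fixture(scope="session")
def geometry():
    return conical_geometry()


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic lake scenario shared across read-only tests."""
    return synthetic.generate_lake_scenario(seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    """Cheap scenario for simulation-heavy tests."""
    return synthetic.generate_lake_scenario(n_wastewater=2, n_mixed=2, seed=11)


def uniform_inflow_scenario(base, conc=100.0, *, k_photo=0.0, loq=25.0,
                            epilimnion_depth=None, kd=None):
    """Rebuild a scenario with one compound at the same concentration in
    every inflow (useful for closed-form limits)."""
    import dataclasses

    comp = synthetic.CompoundSpec(
        name="tracer",
        source_class="wastewater_derived",
        molecular_weight=200.0,
        photolysis_k_surface=k_photo,
        loq=loq,
    )
    inflows = tuple(
        dataclasses.replace(f, concentrations={"tracer": conc}) for f in base.inflows
    )
    kwargs = {}
    if epilimnion_depth is not None:
        kwargs["epilimnion_depth"] = epilimnion_depth
    if kd is not None:
        kwargs["light_attenuation_Kd"] = kd
    return dataclasses.replace(
        base, inflows=inflows, compounds=(comp,), **kwargs
    )
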