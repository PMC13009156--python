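import pytest

from prsecon import default_parameters, run_psa
from prsecon.params import FixedDist, Parameter, ParameterSet


def make_all_fixed(ps: ParameterSet) -> ParameterSet:
    """Degenerate copy: every distribution replaced by a point mass."""
    return ParameterSet(
        [
            Parameter(
                name=p.name,
                base_value=p.base_value,
                units=p.units,
                distribution=FixedDist(),
                source_note=p.source_note,
            )
            for p in ps.values()
        ]
    )


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def fixed_params(base_params):
    return make_all_fixed(base_params)


@pytest.fixture(scope="session")
def psa_1000(base_params):
    """One shared 1000-draw PSA run at a fixed seed."""
    return run_psa(base_params, 1000, seed=20260929)
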