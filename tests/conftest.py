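import numpy as np
import pytest

from v1gamma import ModelParams, SimSpec, StimulusSpec, run_condition


@pytest.fixture(scope="session")
def table1_params() -> ModelParams:
    """Reference parameter set (RC/FF couplings, HC and FB off)."""
    return ModelParams()


@pytest.fixture(scope="session")
def small_params() -> ModelParams:
    """A 7x7 lattice for cheap structural tests."""
    return ModelParams(grid_rows=7, grid_cols=7)


@pytest.fixture(scope="session")
def full_field() -> StimulusSpec:
    return StimulusSpec.full_field()


@pytest.fixture(scope="session")
def quick_sim() -> SimSpec:
    """Short protocol for structural checks (not spectral accuracy)."""
    return SimSpec(duration=0.5, discard=0.1, repeats=3, seed=1234)


@pytest.fixture(scope="session")
def rc_only_condition(table1_params, full_field):
    """RC-only reference run shared by spectral and oracle tests."""
    return run_condition(
        table1_params, full_field, SimSpec(repeats=40, seed=4321), condition="rc"
    )


@pytest.fixture(scope="session")
def two_gamma_params(table1_params) -> ModelParams:
    """HC setting that generates both slow and fast gamma."""
    return table1_params.replace(w_ee_hc=0.03, w_ie_hc=2.5)
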