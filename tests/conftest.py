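import dataclasses

import pytest

from corticlone.lineage import LineageParams


@pytest.fixture
def control_params() -> LineageParams:
    """Control-like defaults of the lineage model."""
    return LineageParams()


@pytest.fixture
def neurogenic_params(control_params) -> LineageParams:
    """Same model already in the neurogenic phase at labeling."""
    return dataclasses.replace(control_params, t_switch=0.0)


@pytest.fixture
def forced_params(control_params) -> LineageParams:
    """Fully forced fate sequence: RG -> 2 IPC -> 4 neurons."""
    return dataclasses.replace(
        control_params,
        p_rg_sym=0.0,
        p_rg_asym=0.0,
        p_rg_diff=1.0,
        k_max=1,
        p_ipc_terminal=1.0,
        t_switch=0.0,
    )
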