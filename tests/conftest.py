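import pytest

from ddmrd import ClassificationRules, DropletWell, Role, SimulationConfig, Target


def make_well(
    k: int,
    n: int = 20000,
    well_id: str = "A01",
    sample_id: str = "S1",
    target: Target = Target.P190,
    role: Role = Role.SAMPLE,
    replicate_group: str = "",
) -> DropletWell:
    return DropletWell(
        well_id=well_id,
        sample_id=sample_id,
        target=target,
        role=role,
        replicate_group=replicate_group,
        n_accepted=n,
        k_positive=k,
    )


@pytest.fixture
def config() -> SimulationConfig:
    return SimulationConfig(seed=20210816)


@pytest.fixture
def rules() -> ClassificationRules:
    return ClassificationRules()
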