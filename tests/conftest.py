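import pytest
from hypothesis import settings

from qlckit import PlantSpec, Proteome, ProteinRecord, generate_proteome

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def tiny_proteome() -> Proteome:
    return Proteome(
        [
            ProteinRecord(id="p1", sequence="MQQQH" + "A" * 20, description="toy one"),
            ProteinRecord(id="p2", sequence="Q" * 20),
            ProteinRecord(id="p3", sequence="HHHAAAHHH"),
        ]
    )


@pytest.fixture(scope="session")
def planted_proteome():
    """Proteome with 50 Q-rich plants, 25 generic low-complexity plants
    (QLC plants carry 1.5x the histidine density), and 25 background-only
    proteins; returned with its truth table."""
    qlc = PlantSpec(
        kind="xlc", n_tracts=50, tract_length=(40, 80),
        target_fraction=0.4, max_gap=10, his_density=0.12,
    )
    lcd = PlantSpec(kind="lcd", n_tracts=25, tract_length=(40, 80), his_density=0.08)
    return generate_proteome(100, plants=[qlc, lcd], seed=20260926)
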