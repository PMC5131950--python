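import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eaeox import Group, MouseRecord, PO2Session, Region, StudyDataset
from eaeox.simulate import default_config, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_mouse(mouse_id, group, region=Region.CEREBELLUM, sessions=(), behavior=()):
    return MouseRecord(
        mouse_id=mouse_id,
        group=group,
        region=region,
        sessions=[PO2Session(mouse_id, d, np.asarray(v, float)) for d, v in sessions],
        behavior=list(behavior),
    )


@pytest.fixture
def toy_dataset():
    """2 controls + 1 EAE mouse, constant traces, hand-checkable numbers."""
    controls = [
        make_mouse(
            f"C{i}",
            Group.CONTROL,
            sessions=[(-1, [20.0] * 4 + [22.0] * 2), (14, [20.5] * 6)],
        )
        for i in (1, 2)
    ]
    eae = make_mouse(
        "E1",
        Group.EAE,
        sessions=[(-1, [25.0] * 6), (14, [15.0, 16.0, 14.0, 15.5, 14.5, 15.0])],
        behavior=[(14, 3.0)],
    )
    return StudyDataset(mice=controls + [eae], region=Region.CEREBELLUM)


@pytest.fixture(scope="session")
def cereb_sim():
    """One default cerebellar cohort, shared across tests (seed 7)."""
    return simulate_study(default_config("cerebellum", seed=7))
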