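import pytest

from gmoscreen import calling, catalog, plates
from gmoscreen.calling import JoinedWell, WellResult


@pytest.fixture(scope="session")
def matrix():
    return catalog.load_bundled_matrix()


@pytest.fixture(scope="session")
def assays():
    return catalog.load_assays()


@pytest.fixture(scope="session")
def controls():
    return catalog.load_positive_controls()


@pytest.fixture(scope="session")
def full_layout():
    return plates.build_default_layout(11)


def join_rows(rows, layout):
    """Turn simulator output into joined well results without touching disk."""
    joined = []
    for plate, well, cq in rows:
        assignment = layout.lookup(plate, well)
        joined.append(JoinedWell(WellResult(plate, well, cq), assignment))
    return joined


def pipeline_calls(compositions, layout, matrix, seed=0, sigma=0.0):
    """simulate -> call for a list of compositions; returns ScreenCalls."""
    from gmoscreen import simulate as sim

    rows = sim.simulate_run(
        list(compositions), layout, matrix, sim.CqModel(sigma_cq=sigma), seed=seed
    )
    return calling.call_sample_profile(join_rows(rows, layout), layout)
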