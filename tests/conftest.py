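import numpy as np
import pytest

from leukoflow.fcs import ChannelMeta, EventTable
from leukoflow.pipeline import analyze_case
from leukoflow.simulate import builtin_templates, simulate_case


@pytest.fixture(scope="session")
def templates():
    return builtin_templates(blast_fraction=0.5)


@pytest.fixture(scope="session")
def normal_case(templates):
    """Clean normal-marrow case (no artifacts), 2,000 events per tube."""
    return simulate_case(templates["normal_marrow"], n_events=2000, seed=1,
                         diagnosis="Normal")


@pytest.fixture(scope="session")
def normal_case_artifacts(templates):
    """Normal marrow with 5% doublets and 8% debris injected."""
    return simulate_case(
        templates["normal_marrow"], n_events=2000, seed=1,
        doublet_frac=0.05, debris_frac=0.08, diagnosis="Normal")


@pytest.fixture(scope="session")
def ball_case(templates):
    """Typical B-ALL case (50% blasts) with artifacts."""
    return simulate_case(
        templates["B_ALL_typical"], n_events=2000, seed=2,
        doublet_frac=0.05, debris_frac=0.08, diagnosis="B_ALL")


@pytest.fixture(scope="session")
def analyzed_normal(normal_case_artifacts):
    tables, truth = normal_case_artifacts
    return analyze_case(tables), truth


@pytest.fixture(scope="session")
def analyzed_ball(ball_case):
    tables, truth = ball_case
    return analyze_case(tables), truth


def make_table(values, markers=None, scatter=True, tube_id="t",
               transform_state="raw"):
    """EventTable helper: columns = scatter triplet + time + marker channels."""
    values = np.asarray(values, dtype=float)
    chans = []
    if scatter:
        chans += [
            ChannelMeta("FSC-A", is_scatter=True),
            ChannelMeta("FSC-H", is_scatter=True),
            ChannelMeta("SSC-A", is_scatter=True),
            ChannelMeta("Time", is_time=True),
        ]
    for i, m in enumerate(markers or [], start=1):
        chans.append(ChannelMeta(f"FL{i}-A", marker=m))
    return EventTable(values=values, channels=chans, tube_id=tube_id,
                      transform_state=transform_state)
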