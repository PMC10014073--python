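import numpy as np
import pytest

from axoprop.model import (
    SectionSpec,
    assign_channel_densities,
    build_default_morphology,
    default_gating_models,
    segmentize,
)

ZERO_DENSITIES = {
    "nav12": {}, "nav16": {}, "kv": {}, "kv1": {},
}


def _zeroed(cfg_regions):
    """Density config mapping every species/region to zero."""
    out = {}
    for sp in ("nav12", "nav16", "kv", "kv1"):
        out[sp] = {r: 0.0 for r in cfg_regions}
    return out


@pytest.fixture(scope="session")
def default_graph():
    return segmentize(build_default_morphology())


@pytest.fixture(scope="session")
def default_layout(default_graph):
    return assign_channel_densities(default_graph)


@pytest.fixture()
def passive_cable():
    """Sealed passive cable: 200 um x 1.2 um, all channel densities zero."""
    secs = [SectionSpec(name="cable", length=200.0, diameter=1.2, region="soma")]
    graph = segmentize(secs)
    layout = assign_channel_densities(
        graph, _zeroed(("soma",)), gating=default_gating_models()
    )
    return graph, layout


@pytest.fixture()
def isopotential_passive():
    """Single ~isopotential passive compartment (1 um cylinder)."""
    secs = [SectionSpec(name="blob", length=1.0, diameter=10.0, region="soma")]
    graph = segmentize(secs)
    layout = assign_channel_densities(
        graph, _zeroed(("soma",)), gating=default_gating_models()
    )
    return graph, layout
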