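import pytest
from hypothesis import HealthCheck, settings

from ddiminer import build_source_graph

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


#: The canonical toy fixture: three PPIs whose domain incidence reproduces the
#: schematic tripartite example — d1/d3 on the left side, d2/d4 on the right.
TOY_ANNOTATIONS = {
    "La": {"d1", "d3"},
    "Lb": {"d1", "d3"},
    "Lc": {"d3"},
    "Ra": {"d2"},
    "Rb": {"d2", "d4"},
    "Rc": {"d4"},
}
TOY_PAIRS = [("La", "Ra"), ("Lb", "Rb"), ("Lc", "Rc")]


@pytest.fixture
def toy_annotations():
    return {p: set(d) for p, d in TOY_ANNOTATIONS.items()}


@pytest.fixture
def toy_graph(toy_annotations):
    return build_source_graph("toy", TOY_PAIRS, toy_annotations)
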