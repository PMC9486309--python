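import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_gmt(tmp_path):
    """A three-pathway GMT file on disk."""
    path = tmp_path / "tiny.gmt"
    path.write_text(
        "P1\tfirst\ta\tb\tc\td\n"
        "P2\tsecond\tc\td\te\n"
        "P3\tthird\te\tf\n"
    )
    return path


@pytest.fixture
def path_graph_file(tmp_path):
    """Edge list of the 6-node path A-B-C-D-E-F."""
    path = tmp_path / "path.tsv"
    nodes = list("ABCDEF")
    path.write_text("".join(f"{u}\t{v}\n" for u, v in zip(nodes, nodes[1:])))
    return path
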