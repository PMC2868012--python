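import pytest

from chiptile.datamodel import ProbeAnnotation, ProbeSet
from chiptile.simulate import default_fixture


@pytest.fixture(scope="session")
def fixture_seed1():
    """Desk-scale synthetic dataset shared across tests (read-only)."""
    return default_fixture(seed=1)


@pytest.fixture()
def tiny_probes():
    return ProbeSet(
        probe_ids=["p1", "p2", "p3"],
        sequences=["ACGTA", "GGGCC", "TTTTT"],
        array_x=[0, 1, 2],
        array_y=[0, 0, 0],
    )


def make_uniform_annotation(n, spacing=20, probe_length=25, chrom="chr1"):
    entries = {chrom: [(i, i * spacing, "+") for i in range(n)]}
    return ProbeAnnotation(entries=entries, probe_length=probe_length)


@pytest.fixture()
def uniform_annotation():
    return make_uniform_annotation
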