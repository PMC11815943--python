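import pytest
from hypothesis import settings

from nickhdr import demo
from nickhdr.classify import QuantWindow
from nickhdr.expression import IsoformModel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def locus():
    return demo.demo_locus()


@pytest.fixture(scope="session")
def pair(locus):
    return demo.demo_guide_pair(locus)


@pytest.fixture(scope="session")
def template(locus):
    return demo.demo_template(locus)


@pytest.fixture(scope="session")
def full_template(locus):
    return demo.demo_template(locus, "full")


@pytest.fixture(scope="session")
def window(pair):
    return QuantWindow.from_pair(pair)


@pytest.fixture(scope="session")
def isoforms(locus):
    return IsoformModel(locus, demo.TARGET_EXON)
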