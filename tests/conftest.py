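import pytest

from cancerhx.lexicon import default_lexicon
from cancerhx.parsing import Report, Section, parse_report, split_sentences


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def sentence():
    """Factory: first parsed sentence of a text snippet."""

    def make(text):
        return split_sentences(text)[0]

    return make


@pytest.fixture(scope="session")
def subjective_section():
    """A plain subjective, non-family-history section shell."""
    return Section(heading="HISTORY OF PRESENT ILLNESS", heading_line=None,
                   is_family_history=False, is_subjective=True)


@pytest.fixture(scope="session")
def fh_section():
    return Section(heading="FAMILY HISTORY", heading_line=None,
                   is_family_history=True, is_subjective=True)


@pytest.fixture(scope="session")
def report_of():
    """Factory: fully parsed single report from raw text."""

    def make(text, report_id="1"):
        return parse_report(Report(report_id, text))

    return make
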