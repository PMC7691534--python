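import pytest

from litvariant.cnv import load_cytoband_table
from litvariant.lexicon import default_keyword_lexicon
from litvariant.synth import (
    toy_cytoband_rows,
    toy_gene_lexicon,
    toy_rsid_map,
    toy_transcripts,
)


@pytest.fixture(scope="session")
def transcripts():
    return toy_transcripts()


@pytest.fixture(scope="session")
def gene_lexicon():
    return toy_gene_lexicon()


@pytest.fixture(scope="session")
def cytobands():
    return load_cytoband_table(toy_cytoband_rows())


@pytest.fixture(scope="session")
def keywords():
    return default_keyword_lexicon()


@pytest.fixture(scope="session")
def rsid_map():
    return toy_rsid_map()
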