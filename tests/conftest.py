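from pathlib import Path

import pytest

from agestereo import (
    default_stopwords,
    read_corpus,
    read_covariates,
    read_lexicon,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def fixture_documents():
    return list(read_corpus(DATA / "manifest.tsv"))


@pytest.fixture(scope="session")
def fixture_lexicon():
    return read_lexicon(DATA / "lexicon.tsv")


@pytest.fixture(scope="session")
def fixture_covariates():
    return read_covariates(DATA / "covariates.tsv")


@pytest.fixture(scope="session")
def stopwords():
    return default_stopwords()
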