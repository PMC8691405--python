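import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("fixed")

from mealdiary import FoodLexicon, fit_vectorizer, load_fixture_db


@pytest.fixture(scope="session")
def fixture_db():
    return load_fixture_db()


@pytest.fixture(scope="session")
def lexicon(fixture_db):
    return FoodLexicon.from_entries(fixture_db)


@pytest.fixture(scope="session")
def vectorizer(fixture_db):
    return fit_vectorizer(fixture_db)


@pytest.fixture(scope="session")
def entry_matrix(fixture_db, vectorizer):
    return vectorizer.transform_entries(fixture_db)
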