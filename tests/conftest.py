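import pytest
from hypothesis import HealthCheck, settings

from postopqa import app, corpus_factory
from postopqa.config import RunConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 1


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=SEED)


@pytest.fixture(scope="session")
def kb_docs():
    return corpus_factory.generate_kb(SEED)


@pytest.fixture(scope="session")
def corpus_records():
    return corpus_factory.generate_corpus(SEED)


@pytest.fixture(scope="session")
def serving_stack(run_config):
    pipeline, docs = app.build_serving_stack(run_config)
    return pipeline, docs


@pytest.fixture(scope="session")
def pipeline(serving_stack):
    return serving_stack[0]


@pytest.fixture(scope="session")
def corpus_answers(pipeline, corpus_records):
    """One full pass of the 750-query corpus through the serving pipeline."""
    return app.answer_corpus(pipeline, corpus_records)
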