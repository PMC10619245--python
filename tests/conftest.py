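import pytest
from hypothesis import settings

from skimlbd import Document, build_index
from skimlbd.simulate import _term_lists, default_chain_spec, generate_corpus

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture()
def tiny_docs():
    return [
        Document(1, "dietary fish oil", "reduces blood viscosity.", 1984),
        Document(2, "raynaud's disease", "blood viscosity is elevated.", 1980),
        Document(3, "fish oil supplements", "no effect observed.", 1990),
        Document(4, "control study", "an unrelated abstract.", 1985),
        Document(5, "undated record", "fish oil again.", None),
    ]


@pytest.fixture()
def tiny_index(tiny_docs):
    return build_index(tiny_docs)


@pytest.fixture(scope="session")
def chain_fixture():
    """Planted-chain corpus (seed 0) with its index and role term lists."""
    spec = default_chain_spec(seed=0)
    docs, manifest = generate_corpus(spec)
    index = build_index(docs)
    lists = _term_lists(spec)
    return {
        "spec": spec,
        "docs": docs,
        "manifest": manifest,
        "index": index,
        "a": lists["a"][0],
        "b_terms": lists["b"],
        "c_terms": lists["c"],
    }
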