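import numpy as np
import pytest

import pharmaconer as ph


@pytest.fixture(scope="session")
def small_corpus():
    """30 easy-level synthetic documents with short sentences."""
    spec = ph.separability_dial(
        ph.CorpusSpec(n_docs=30, sentences_per_doc_mean=5.0,
                      sentences_per_doc_sd=1.0, seed=42),
        "easy",
    )
    return ph.generate(spec)


@pytest.fixture(scope="session")
def corpus_dir(small_corpus, tmp_path_factory):
    """The small corpus written out (brat/, conll/, gazetteer, affixes)."""
    out = tmp_path_factory.mktemp("corpus")
    small_corpus.write(out)
    return out


@pytest.fixture(scope="session")
def resources(corpus_dir):
    return {
        "gazetteer": ph.load_gazetteer(corpus_dir / "gazetteer.txt"),
        "affixes": ph.load_affixes(corpus_dir / "affixes.tsv"),
    }


@pytest.fixture
def tiny_doc():
    text = "Se administró lidocaína al paciente."
    tokens = ph.tokenize(text)
    entities = [ph.Entity("Normalizables", 14, 23, "lidocaína")]
    doc = ph.Document("tiny", text, tokens, entities)
    doc.validate()
    return doc


def tiny_model(docs, labels=None, seed=0, features=None, **cfg_kwargs):
    """Small-dimension tagger used across model/training tests."""
    labels = labels or sorted({e.label for d in docs for e in d.entities})
    defaults = dict(d_char=6, d_char_lstm=6, d_token=12, d_token_lstm=12,
                    dropout_rate=0.0)
    defaults.update(cfg_kwargs)
    config = ph.ModelConfig(labels=labels, seed=seed, **defaults)
    vocab = ph.TokenVocabulary.build(docs, dim=config.d_token, seed=seed)
    chars = ph.CharVocabulary.build(docs)
    return ph.SequenceTagger(config, vocab, chars,
                             features or ph.FeatureExtractor())
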