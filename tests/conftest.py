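import numpy as np
import pytest

from sdmstylo.annotation import AnnotatedDoc, Token, UPOS_TAGS
from sdmstylo.synthetic import default_config, generate

NONPUNCT_TAGS = sorted(UPOS_TAGS - {"PUNCT"})


def make_doc(pairs, doc_id="test"):
    """Build an AnnotatedDoc from (form, upos) pairs."""
    return AnnotatedDoc(tokens=[Token(form=f, upos=u) for f, u in pairs], doc_id=doc_id)


def random_doc(rng, n_tokens, vocab=40, punct_rate=0.08):
    """A random annotated document over a small vocabulary (for oracles)."""
    pairs = []
    for _ in range(n_tokens):
        if rng.random() < punct_rate:
            pairs.append((".", "PUNCT"))
        else:
            form = f"w{rng.integers(vocab)}"
            upos = NONPUNCT_TAGS[rng.integers(len(NONPUNCT_TAGS))]
            pairs.append((form, upos))
    return make_doc(pairs)


@pytest.fixture(scope="session")
def study_corpus():
    """One study-design synthetic corpus (24+24 participants, 3 SDMs each)."""
    return generate(default_config(seed=7))
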