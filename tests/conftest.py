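import numpy as np
import pytest
from hypothesis import settings

from proofer import CorpusSpec, Lexicon

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def anatomy_lexicon() -> Lexicon:
    """Small hand-built vocabulary exercising multiword labels, synonyms and
    Latin plurals."""
    lex = Lexicon()
    lex.add_term("propleural arm", source="seed")
    lex.add_term("tergum", synonyms=["tergite"], source="seed")
    lex.add_term("carina", source="seed")
    lex.add_term("clypeus", source="seed")
    lex.add_term("mesoscutum", source="seed")
    lex.add_term("shiny", kind="qualitative", source="seed")
    return lex


@pytest.fixture
def strong_spec() -> CorpusSpec:
    """Strong planted signal: disjoint specific vocabularies, no OCR noise."""
    return CorpusSpec(
        n_groups=3,
        articles_per_group=5,
        n_common_terms=10,
        n_specific_terms_per_group=8,
        p_specific=1.0,
        ocr_error_rate=0.0,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
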