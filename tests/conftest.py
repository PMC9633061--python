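import dataclasses

import numpy as np
import pytest

from callcat.calls import (
    CallCategorySpec,
    Distribution,
    default_category_specs,
    generate_call,
    generate_corpus,
)
from callcat.cochleagram import CochleagramParams, compute_cochleagram
from callcat.mif import train_instantiations


@pytest.fixture(scope="session")
def default_specs():
    return default_category_specs()


@pytest.fixture(scope="session")
def coch_params():
    return CochleagramParams()


@pytest.fixture(scope="session")
def three_syllable_call():
    spec = CallCategorySpec(
        name="tri",
        f0_base=500.0,
        syllable_dur=Distribution(80, 120),
        isi_dur=Distribution(60, 100),
        n_syllables=Distribution(3, 3),
    )
    return generate_call(spec, seed=5)


@pytest.fixture(scope="session")
def mini_corpus(default_specs):
    """Two-category (chut/purr) corpus for cheap model tests."""
    return generate_corpus(default_specs[:2], n_train=6, n_holdout=4, seed=11)


@pytest.fixture(scope="session")
def mini_cochleagrams(mini_corpus, coch_params):
    return {
        c.exemplar_id: compute_cochleagram(c, coch_params) for c in mini_corpus.calls
    }


@pytest.fixture(scope="session")
def mini_models(mini_corpus, mini_cochleagrams):
    """Small one-vs-one ensembles for chut and purr (3 instantiations)."""
    kwargs = dict(
        n_instantiations=3,
        n_candidates=120,
        mode="one_vs_one",
        cochleagrams=mini_cochleagrams,
    )
    chut = train_instantiations(mini_corpus, "chut", partner="purr", seed=21, **kwargs)
    purr = train_instantiations(mini_corpus, "purr", partner="chut", seed=22, **kwargs)
    return {"chut": chut, "purr": purr}


@pytest.fixture(scope="session")
def std_corpus(default_specs):
    """Four-category corpus with enough exemplars for 10-fold CV."""
    return generate_corpus(default_specs, n_train=10, n_holdout=4, seed=7)


@pytest.fixture(scope="session")
def std_cochleagrams(std_corpus, coch_params):
    return {
        c.exemplar_id: compute_cochleagram(c, coch_params)
        for c in std_corpus.calls
    }
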