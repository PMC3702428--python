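"""Shared fixtures: generated corpus worlds and a hand-built evaluation scene."""

from __future__ import annotations

import pytest

from treatminer.corpus_io import SentenceRecord
from treatminer.lexicon import Lexicon, SynonymMap
from treatminer.pattern_miner import DRUG_FIRST, DrugDiseasePair, Pattern
from treatminer.synthetic_fixtures import FixtureConfig, generate_fixture


@pytest.fixture(scope="session")
def world():
    """Default generated corpus world (144 sentences, 12 treatment pairs)."""
    config = FixtureConfig(rng_seed=20260921)
    sentences, drugs, diseases, synonyms, truth = generate_fixture(config)
    return {
        "config": config,
        "sentences": sentences,
        "drugs": drugs,
        "diseases": diseases,
        "synonyms": synonyms,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def noisy_world():
    config = FixtureConfig(rng_seed=4711, noisy=True)
    sentences, drugs, diseases, synonyms, truth = generate_fixture(config)
    return {
        "config": config,
        "sentences": sentences,
        "drugs": drugs,
        "diseases": diseases,
        "synonyms": synonyms,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def eval_scene():
    """Hand-built world with controlled co-occurrence frequencies {1,5,10,20,30}.

    One anchor drug, five gold diseases whose pairs co-occur 1/5/10/20/30
    times.  The frequency-1 pair co-occurs only in a non-treatment sentence
    (never extracted); the others are linked by a selected pattern.  A sixth
    disease is pattern-linked but absent from gold (a false positive).
    Expected numbers are hand-computable: precision 4/5 at every cutoff,
    recall 4/5, 4/4, 3/3, 2/2, 1/1 at cutoffs 1, 5, 10, 20, 30.
    """
    drug = "alphadrug"
    gold_diseases = ["dermopax", "fibroxin", "glomitis", "hepatovir", "iliopax"]
    fp_disease = "keratodol"
    freqs = {"dermopax": 1, "fibroxin": 5, "glomitis": 10, "hepatovir": 20, "iliopax": 30}
    sentences = []
    n = 0

    def add(text):
        nonlocal n
        sentences.append(SentenceRecord(f"E{n:04d}", 0, text))
        n += 1

    add(f"Levels of {drug} were compared with dermopax markers.")  # co-occurs, no pattern
    for disease, freq in freqs.items():
        if disease == "dermopax":
            continue
        for _ in range(freq):
            add(f"A study of {drug} in the treatment of {disease} was performed.")
    add(f"Use of {drug} in the treatment of {fp_disease} was reported.")

    drugs = Lexicon("DRUG", frozenset({drug}))
    diseases = Lexicon("DISEASE", frozenset(gold_diseases + [fp_disease]))
    gold_pairs = frozenset(DrugDiseasePair(drug, z) for z in gold_diseases)
    return {
        "sentences": sentences,
        "drugs": drugs,
        "diseases": diseases,
        "synonyms": SynonymMap(),
        "anchor": drug,
        "gold_pairs": gold_pairs,
        "freqs": freqs,
        "selected": {Pattern(DRUG_FIRST, "in the treatment of")},
    }
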