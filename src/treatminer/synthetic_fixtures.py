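"""Seeded synthetic corpora with known ground truth.

Real inputs for this pipeline (citation corpora, trial registries,
terminology exports) are external and licensed, so every pipeline stage is
exercised against generated worlds instead: nonsense-vocabulary lexicons,
sentences that embed a drug and a disease around a planted infix pattern
with controlled per-pair sentence counts, seed subsets, anchored gold
standards, and drug-annotation tables with stratified overlaps.

The generated vocabulary is pronounceable nonsense rather than real drug
names, and generation verifies collision-freedom (no term occurs inside
another term, a filler word or a pattern), so any tagger hit is a planted
hit by construction.  Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from treatminer.corpus_io import SentenceRecord, TrialRecord
from treatminer.lexicon import Lexicon, SynonymMap
from treatminer.pattern_miner import DRUG_FIRST, DISEASE_FIRST, DrugDiseasePair, Pattern
from treatminer.semantic_analysis import AssociationTable

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


class FixtureConfigError(ValueError):
    pass


#: Default treatment infixes planted in fixtures (a subset of the shipped curation).
DEFAULT_FIXTURE_TREATMENT = (
    "in the treatment of",
    "for the treatment of",
    "in patients with",
    "therapy for",
    "against",
)

#: Default distractor infixes: relations that are real but not treatment.
DEFAULT_FIXTURE_DISTRACTORS = ("-induced", "-associated", "had no effect on")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for a generated corpus.

    ``pair_frequency_spec`` maps a per-pair sentence count to the number of
    treatment pairs planted at that count; the default covers the cutoff
    grid {1, 5, 10, 20, 30} used for frequency-stratified evaluation.
    """

    rng_seed: int
    n_drugs: int = 8
    n_diseases: int = 8
    treatment_patterns: tuple[str, ...] = DEFAULT_FIXTURE_TREATMENT
    distractor_patterns: tuple[str, ...] = DEFAULT_FIXTURE_DISTRACTORS
    pair_frequency_spec: Mapping[int, int] = field(
        default_factory=lambda: {1: 3, 5: 3, 10: 2, 20: 2, 30: 2}
    )
    distractor_pair_count: int = 3
    distractor_frequency: int = 2
    seed_fraction: float = 0.5
    n_trade_names: int = 2
    noisy: bool = False
    noisy_pair_count: int = 2

    def __post_init__(self) -> None:
        if self.n_drugs < 2 or self.n_diseases < 2:
            raise FixtureConfigError("vocabulary sizes must be >= 2")
        if any(f < 1 for f in self.pair_frequency_spec):
            raise FixtureConfigError("pair frequencies must be >= 1")
        if not 0.0 <= self.seed_fraction <= 1.0:
            raise FixtureConfigError("seed_fraction must be in [0, 1]")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth consistent with the emitted corpus by construction."""

    planted_links: frozenset[tuple[Pattern, DrugDiseasePair, int]]
    treatment_pairs: frozenset[DrugDiseasePair]
    distractor_pairs: frozenset[DrugDiseasePair]
    seed_pairs: frozenset[DrugDiseasePair]
    pair_frequencies: Mapping[DrugDiseasePair, int]
    trials: tuple[TrialRecord, ...]
    selected_patterns: frozenset[Pattern]

    def gold_for_drug(self, drug: str) -> frozenset[DrugDiseasePair]:
        return frozenset(p for p in self.treatment_pairs if p.drug == drug)

    def gold_for_disease(self, disease: str) -> frozenset[DrugDiseasePair]:
        return frozenset(p for p in self.treatment_pairs if p.disease == disease)


def _make_word(rng: random.Random, n_syllables: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables))


def _make_vocab(rng: random.Random, n: int, n_syllables: int, taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        w = _make_word(rng, n_syllables)
        if w not in taken and not any(w in t or t in w for t in taken):
            taken.add(w)
            words.append(w)
    return words


def _check_patterns_clean(patterns: Sequence[str], terms: set[str]) -> None:
    for p in patterns:
        p_words = {w.strip("-").casefold() for w in p.split()}
        for term in terms:
            if term in p_words or any(term in w for w in p.split()):
                raise FixtureConfigError(f"pattern {p!r} contains lexicon term {term!r}")


def _embed(drug_surface: str, infix: str, disease: str) -> str:
    # hyphen-leading infixes attach directly to the first entity
    if infix.startswith("-"):
        return f"{drug_surface}{infix} {disease}"
    if infix:
        return f"{drug_surface} {infix} {disease}"
    return f"{drug_surface} {disease}"


def generate_fixture(
    config: FixtureConfig,
) -> tuple[list[SentenceRecord], Lexicon, Lexicon, SynonymMap, FixtureTruth]:
    """Generate (sentences, drug lexicon, disease lexicon, synonyms, truth).

    Every planted (pattern, pair) link appears in exactly the configured
    number of sentences, each sentence embedding exactly one drug and one
    disease as ``<filler> DRUG <infix> DISEASE <filler>.``, so the corpus
    co-occurrence count of every planted pair equals its planted sentence
    count exactly.  In noisy mode, extra near-miss sentences insert words
    inside the infix; their pairs must never be pattern-extracted although
    they do co-occur.
    """
    rng = random.Random(config.rng_seed)
    taken: set[str] = set()
    drugs = _make_vocab(rng, config.n_drugs, 4, taken)
    diseases = _make_vocab(rng, config.n_diseases, 5, taken)
    trade_names = _make_vocab(rng, min(config.n_trade_names, config.n_drugs), 4, taken)
    fillers = _make_vocab(rng, 30, 3, taken)

    all_terms = set(drugs) | set(diseases) | set(trade_names)
    _check_patterns_clean(
        tuple(config.treatment_patterns) + tuple(config.distractor_patterns), all_terms
    )

    synonyms = SynonymMap.from_pairs(zip(trade_names, drugs))
    drug_lex = Lexicon("DRUG", frozenset(drugs), {d: ("synthetic",) for d in drugs})
    disease_lex = Lexicon("DISEASE", frozenset(diseases), {d: ("synthetic",) for d in diseases})

    # distinct (drug, disease) grid cells, one per planted pair of any class
    grid = [(d, z) for d in drugs for z in diseases]
    rng.shuffle(grid)
    n_treat = sum(config.pair_frequency_spec.values())
    n_needed = n_treat + config.distractor_pair_count + (
        config.noisy_pair_count if config.noisy else 0
    )
    if n_needed > len(grid):
        raise FixtureConfigError(
            f"{n_needed} planted pairs requested but only {len(grid)} grid cells exist"
        )
    cells = iter(grid)

    planted: list[tuple[Pattern, DrugDiseasePair, int]] = []
    freq_of: dict[DrugDiseasePair, int] = {}
    treatment_pairs: list[DrugDiseasePair] = []
    t_patterns = [Pattern.from_text(DRUG_FIRST, p) for p in config.treatment_patterns]
    i = 0
    for freq, n_pairs in sorted(config.pair_frequency_spec.items()):
        for _ in range(n_pairs):
            d, z = next(cells)
            pair = DrugDiseasePair(d, z)
            pattern = t_patterns[i % len(t_patterns)]
            planted.append((pattern, pair, freq))
            freq_of[pair] = freq
            treatment_pairs.append(pair)
            i += 1

    distractor_pairs: list[DrugDiseasePair] = []
    d_patterns = [Pattern.from_text(DRUG_FIRST, p) for p in config.distractor_patterns]
    for j in range(config.distractor_pair_count):
        d, z = next(cells)
        pair = DrugDiseasePair(d, z)
        planted.append((d_patterns[j % len(d_patterns)], pair, config.distractor_frequency))
        freq_of[pair] = config.distractor_frequency
        distractor_pairs.append(pair)

    noisy_pairs: list[DrugDiseasePair] = []
    if config.noisy:
        for _ in range(config.noisy_pair_count):
            d, z = next(cells)
            pair = DrugDiseasePair(d, z)
            freq_of[pair] = 1
            noisy_pairs.append(pair)

    # emit sentences; each sentence is its own single-sentence document
    sentences: list[SentenceRecord] = []
    trade_of = {generic: trade for trade, generic in synonyms.mapping.items()}

    def filler(k: int) -> str:
        return " ".join(rng.choice(fillers) for _ in range(k))

    raw: list[str] = []
    for pattern, pair, freq in planted:
        for k in range(freq):
            surface = pair.drug
            if k % 3 == 2 and pair.drug in trade_of:
                surface = trade_of[pair.drug]  # exercise trade->generic mapping
            if k % 2 == 1:
                surface = surface.capitalize()  # exercise case-insensitivity
            core = _embed(surface, pattern.infix, pair.disease)
            raw.append(f"{filler(2).capitalize()} {core} {filler(2)}.")
    for pair in noisy_pairs:
        base = t_patterns[0].infix
        noisy_infix = f"{base.split()[0]} {rng.choice(fillers)} {' '.join(base.split()[1:])}"
        raw.append(f"{filler(2).capitalize()} {_embed(pair.drug, noisy_infix, pair.disease)} {filler(2)}.")

    rng.shuffle(raw)
    for n, text in enumerate(raw):
        sentences.append(SentenceRecord(f"SYN{n:06d}", 0, text))

    # seeds: a deterministic subset of the planted treatment pairs
    n_seeds = round(config.seed_fraction * len(treatment_pairs))
    seed_pairs = sorted(rng.sample(sorted(treatment_pairs), n_seeds))
    trials = tuple(
        TrialRecord(
            trial_id=f"NCT{n:08d}",
            condition_texts=(p.disease.capitalize(),),
            intervention_texts=(trade_of.get(p.drug, p.drug).capitalize(),),
        )
        for n, p in enumerate(seed_pairs)
    )

    truth = FixtureTruth(
        planted_links=frozenset(planted),
        treatment_pairs=frozenset(treatment_pairs),
        distractor_pairs=frozenset(distractor_pairs),
        seed_pairs=frozenset(seed_pairs),
        pair_frequencies=dict(freq_of),
        trials=trials,
        selected_patterns=frozenset(t_patterns),
    )
    return sentences, drug_lex, disease_lex, synonyms, truth


# --------------------------------------------------------------------------
# Association worlds for the semantic analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapStratum:
    """n_pairs drug pairs, each sharing exactly the stated item counts."""

    n_pairs: int
    shared_diseases: int
    shared_genes: int
    shared_atc: int


def generate_association_world(
    n_drugs: int,
    overlap_spec: Sequence[OverlapStratum],
    rng_seed: int,
) -> tuple[AssociationTable, AssociationTable, AssociationTable, dict]:
    """Build disease/gene/ATC association tables with stratified overlaps.

    Each stratum pair gets its own fresh shared items, each drug gets one
    private item per table, and every drug belongs to exactly one pair, so
    a cross-stratum drug pair shares nothing.  The expected
    mean-shared-by-threshold curves are therefore computable exactly from
    the spec by enumeration and are returned alongside the tables as
    ``{"GENES": {t: mean|None}, "ATC": {...}}``.
    """
    need = 2 * sum(s.n_pairs for s in overlap_spec)
    if need != n_drugs:
        raise FixtureConfigError(
            f"overlap_spec implies {need} drugs (2 per pair) but n_drugs={n_drugs}"
        )
    rng = random.Random(rng_seed)
    taken: set[str] = set()
    names = _make_vocab(rng, n_drugs, 4, taken)
    rng.shuffle(names)
    name_iter = iter(names)

    dis: dict[str, set[str]] = {}
    gen: dict[str, set[str]] = {}
    atc: dict[str, set[str]] = {}
    pair_rows: list[OverlapStratum] = []
    uid = 0
    for stratum in overlap_spec:
        for _ in range(stratum.n_pairs):
            a, b = next(name_iter), next(name_iter)
            shared_d = {f"dis_shared_{uid}_{i}" for i in range(stratum.shared_diseases)}
            shared_g = {f"gene_shared_{uid}_{i}" for i in range(stratum.shared_genes)}
            shared_a = {f"A{uid:02d}X{i:02d}" for i in range(stratum.shared_atc)}
            dis[a] = shared_d | {f"dis_priv_{a}"}
            dis[b] = shared_d | {f"dis_priv_{b}"}
            gen[a] = shared_g | {f"gene_priv_{a}"}
            gen[b] = shared_g | {f"gene_priv_{b}"}
            atc[a] = shared_a | {f"P{uid:02d}A"}
            atc[b] = shared_a | {f"P{uid:02d}B"}
            pair_rows.append(stratum)
            uid += 1

    # expected curves by direct enumeration of the constructed design
    n_all = n_drugs * (n_drugs - 1) // 2
    max_d = max((s.shared_diseases for s in overlap_spec), default=0)
    expected: dict[str, dict[int, float | None]] = {"GENES": {}, "ATC": {}}
    for item, attr in (("GENES", "shared_genes"), ("ATC", "shared_atc")):
        for t in range(0, max_d + 2):
            if t == 0:
                rows_vals = [getattr(s, attr) for s in pair_rows]
                # cross pairs all share zero items
                expected[item][t] = sum(rows_vals) / n_all
            else:
                sel = [getattr(s, attr) for s in pair_rows if s.shared_diseases >= t]
                expected[item][t] = (sum(sel) / len(sel)) if sel else None

    tables = (
        AssociationTable("DISEASE", {d: frozenset(v) for d, v in dis.items()}),
        AssociationTable("GENE", {d: frozenset(v) for d, v in gen.items()}),
        AssociationTable("ATC", {d: frozenset(v) for d, v in atc.items()}),
    )
    return (*tables, expected)
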