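"""Dictionary-based entity tagging and sentence co-occurrence counting.

Matching is case-insensitive exact string matching under a word-boundary
constraint: a match must be flanked by the string edges or non-alphanumeric
characters, so "flu" never fires inside "influence" while hyphen-adjacent
matches like "Tamoxifen-induced" are admitted.  Overlaps are resolved
longest-match-first, then leftmost-first, with drug and disease candidates
competing in one pool.  The semantics are those of the naive
all-substrings scan; anything cleverer is an optimization only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from treatminer.corpus_io import SentenceRecord
from treatminer.lexicon import Lexicon, SynonymMap

logger = logging.getLogger(__name__)

HomonymPolicy = Literal["drug", "disease", "suppress"]


@dataclass(frozen=True)
class Mention:
    """A tagged entity occurrence: half-open character span + canonical term.

    For drugs matched via a trade name, ``term`` is the generic name while
    the span still covers the trade-name surface text.
    """

    entity_type: str  # "DRUG" | "DISEASE"
    start: int
    end: int
    term: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid mention span [{self.start},{self.end})")


@dataclass(frozen=True)
class TaggedSentence:
    sentence: SentenceRecord
    mentions: tuple[Mention, ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for m in self.mentions:
            if m.start < prev_end:
                raise ValueError("mentions must be sorted and non-overlapping")
            if m.end > len(self.sentence.text):
                raise ValueError("mention span exceeds sentence length")
            prev_end = m.end


def _fold(text: str) -> str:
    """Length-preserving case fold (offsets must survive the fold)."""
    f = text.casefold()
    if len(f) == len(text):
        return f
    f = text.lower()
    if len(f) == len(text):
        return f
    return "".join(c.casefold() if len(c.casefold()) == 1 else c for c in text)


def _boundary_ok(text: str, start: int, end: int) -> bool:
    if start > 0 and text[start - 1].isalnum():
        return False
    if end < len(text) and text[end].isalnum():
        return False
    return True


class DictionaryMatcher:
    """Find every boundary-valid, case-insensitive occurrence of a surface form.

    ``surfaces`` maps a case-folded surface string (e.g. a trade name) to
    the canonical term it stands for (e.g. the generic name).
    """

    def __init__(self, surfaces: dict[str, str]):
        self.surfaces = dict(surfaces)

    def find_all(self, text: str) -> list[tuple[int, int, str]]:
        """All (start, end, canonical_term) matches, sorted by (start, -length)."""
        folded = _fold(text)
        hits: list[tuple[int, int, str]] = []
        for surface, canonical in self.surfaces.items():
            pos = folded.find(surface)
            while pos != -1:
                end = pos + len(surface)
                if _boundary_ok(folded, pos, end):
                    hits.append((pos, end, canonical))
                pos = folded.find(surface, pos + 1)
        hits.sort(key=lambda h: (h[0], -(h[1] - h[0]), h[2]))
        return hits


def build_matchers(
    drugs: Lexicon, diseases: Lexicon, synonyms: SynonymMap | None = None
) -> tuple[DictionaryMatcher, DictionaryMatcher]:
    """Drug matcher (generic names + trade-name surfaces) and disease matcher."""
    drug_surfaces = {t: t for t in drugs.terms}
    if synonyms is not None:
        for trade, generic in synonyms.mapping.items():
            if generic in drugs.terms:
                drug_surfaces.setdefault(trade, generic)
    return DictionaryMatcher(drug_surfaces), DictionaryMatcher({t: t for t in diseases.terms})


def _resolve_overlaps(
    candidates: list[tuple[int, int, str, str]],  # (start, end, entity_type, term)
    homonym_policy: HomonymPolicy,
) -> list[Mention]:
    # same-span drug/disease homonyms are settled before greedy selection
    by_span: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for start, end, etype, term in candidates:
        by_span.setdefault((start, end), []).append((etype, term))
    settled: list[tuple[int, int, str, str]] = []
    for (start, end), entries in by_span.items():
        types = {e[0] for e in entries}
        if len(types) > 1:
            logger.warning("homonym at span [%d,%d): %s; policy=%s", start, end, entries, homonym_policy)
            if homonym_policy == "suppress":
                continue
            want = "DRUG" if homonym_policy == "drug" else "DISEASE"
            entries = [e for e in entries if e[0] == want]
        for etype, term in entries:
            settled.append((start, end, etype, term))

    # longest match first, then leftmost; DRUG before DISEASE as final tie-break
    settled.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2] != "DRUG", c[3]))
    accepted: list[tuple[int, int, str, str]] = []
    for cand in settled:
        if all(cand[1] <= a[0] or cand[0] >= a[1] for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c[0])
    return [Mention(etype, start, end, term) for start, end, etype, term in accepted]


def tag_sentence(
    sentence: SentenceRecord,
    drugs: Lexicon,
    diseases: Lexicon,
    synonyms: SynonymMap | None = None,
    homonym_policy: HomonymPolicy = "drug",
    matchers: tuple[DictionaryMatcher, DictionaryMatcher] | None = None,
) -> TaggedSentence:
    """Tag one sentence with drug and disease mentions.

    Pass prebuilt ``matchers`` (from :func:`build_matchers`) when tagging
    many sentences against the same lexicons.
    """
    drug_matcher, disease_matcher = matchers or build_matchers(drugs, diseases, synonyms)
    candidates = [(s, e, "DRUG", t) for s, e, t in drug_matcher.find_all(sentence.text)]
    candidates += [(s, e, "DISEASE", t) for s, e, t in disease_matcher.find_all(sentence.text)]
    return TaggedSentence(sentence, tuple(_resolve_overlaps(candidates, homonym_policy)))


def tag_corpus(
    corpus: Iterable[SentenceRecord],
    drugs: Lexicon,
    diseases: Lexicon,
    synonyms: SynonymMap | None = None,
    homonym_policy: HomonymPolicy = "drug",
) -> Iterator[TaggedSentence]:
    """Order-preserving element-wise tagging of a sentence stream."""
    matchers = build_matchers(drugs, diseases, synonyms)
    for sentence in corpus:
        yield tag_sentence(sentence, drugs, diseases, synonyms, homonym_policy, matchers)


@dataclass
class CooccurrenceIndex:
    """Sentence-level co-occurrence counts per (drug, disease) pair.

    A pair's count is the number of *distinct* sentences containing at
    least one mention of each member — multiple mention pairs inside one
    sentence count once.
    """

    counts: dict = field(default_factory=dict)

    def get(self, pair, default: int = 0) -> int:
        return self.counts.get(pair, default)

    def __getitem__(self, pair) -> int:
        return self.counts[pair]

    def __len__(self) -> int:
        return len(self.counts)


def build_cooccurrence_index(tagged: Iterable[TaggedSentence]) -> CooccurrenceIndex:
    from treatminer.pattern_miner import DrugDiseasePair

    counts: dict[DrugDiseasePair, int] = {}
    for ts in tagged:
        drugs = {m.term for m in ts.mentions if m.entity_type == "DRUG"}
        diseases = {m.term for m in ts.mentions if m.entity_type == "DISEASE"}
        for d in drugs:
            for z in diseases:
                pair = DrugDiseasePair(d, z)
                counts[pair] = counts.get(pair, 0) + 1
    return CooccurrenceIndex(counts)


# -- tagged-corpus TSV ------------------------------------------------------

def write_tagged_tsv(tagged: Iterable[TaggedSentence], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("doc_id\tsentence_index\tentity_type\tstart\tend\tterm\n")
        for ts in tagged:
            for m in ts.mentions:
                fh.write(
                    f"{ts.sentence.doc_id}\t{ts.sentence.sentence_index}\t"
                    f"{m.entity_type}\t{m.start}\t{m.end}\t{m.term}\n"
                )
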