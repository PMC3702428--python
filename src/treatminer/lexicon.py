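"""Lexicon construction and curation.

A lexicon is a case-folded set of canonical entity terms (drugs or
diseases) built by merging flat term lists exported from external sources
(a metathesaurus, a disease ontology, a drug database), then curated by
(1) dropping terms that never occur in the working corpus and (2) applying
explicit exclusion lists of non-disease / ambiguous / over-general terms
such as "brain", "consumption" or "disease".  Drug trade names are held in
a separate synonym map and always normalized to generic names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

EntityType = str  # "DRUG" | "DISEASE"


def canonicalize_term(term: str) -> str:
    """Case-fold and collapse internal whitespace to single spaces."""
    return " ".join(term.split()).casefold()


@dataclass(frozen=True)
class Lexicon:
    entity_type: EntityType
    terms: frozenset[str]
    provenance: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    exclusions_applied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for t in self.terms:
            if not t:
                raise ValueError("lexicon terms must be non-empty")
            if t != canonicalize_term(t):
                raise ValueError(f"lexicon term {t!r} is not canonical (case-folded, space-normalized)")

    def __contains__(self, term: str) -> bool:
        return canonicalize_term(term) in self.terms

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class SynonymMap:
    """Trade/brand name -> generic name, both case-folded.

    Values must be members of the drug lexicon they accompany; keys that
    equal their value are redundant and dropped at load time (no cycles:
    generic names map to themselves implicitly).
    """

    mapping: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SynonymMap":
        mapping = {}
        for trade, generic in pairs:
            trade_c, generic_c = canonicalize_term(trade), canonicalize_term(generic)
            if trade_c != generic_c:
                mapping[trade_c] = generic_c
        return cls(mapping)

    def validate_against(self, drugs: Lexicon) -> None:
        missing = sorted(set(self.mapping.values()) - set(drugs.terms))
        if missing:
            raise ValueError(f"synonym targets absent from drug lexicon: {missing[:5]}")


def merge_term_sources(
    entity_type: EntityType,
    sources: Sequence[tuple[str, Iterable[str]]],
) -> Lexicon:
    """Union of case-folded terms across labelled sources.

    Provenance records every contributing source per term; duplicates
    across sources collapse to one entry.  An empty union is an error — a
    usable lexicon must contain at least one term.
    """
    provenance: dict[str, list[str]] = {}
    for label, terms in sources:
        for raw in terms:
            term = canonicalize_term(raw)
            if not term:
                continue
            labels = provenance.setdefault(term, [])
            if label not in labels:
                labels.append(label)
    if not provenance:
        raise ValueError(f"merged {entity_type} lexicon is empty")
    return Lexicon(
        entity_type=entity_type,
        terms=frozenset(provenance),
        provenance={t: tuple(ls) for t, ls in provenance.items()},
    )


def frequency_filter(lexicon: Lexicon, corpus) -> Lexicon:
    """Keep exactly the terms with at least one tagged occurrence in the corpus.

    Occurrence means a boundary-constrained, case-insensitive match — the
    tagger's matching rule — not a raw substring hit, so "flu" inside
    "influence" does not count.  If no term survives, an empty lexicon is
    returned with a warning (downstream constructors will reject it).
    """
    from treatminer.tagger import DictionaryMatcher

    matcher = DictionaryMatcher({t: t for t in lexicon.terms})
    seen: set[str] = set()
    for sentence in corpus:
        for _, _, canonical in matcher.find_all(sentence.text):
            seen.add(canonical)
        if len(seen) == len(lexicon.terms):
            break
    removed = len(lexicon.terms) - len(seen)
    logger.info(
        "frequency filter: %d/%d %s terms retained (%d removed)",
        len(seen), len(lexicon.terms), lexicon.entity_type, removed,
    )
    if not seen:
        logger.warning("frequency filter removed every %s term", lexicon.entity_type)
    return replace(
        lexicon,
        terms=frozenset(seen),
        provenance={t: p for t, p in lexicon.provenance.items() if t in seen},
    )


def apply_exclusion_list(lexicon: Lexicon, exclusions: Iterable[str], list_id: str) -> Lexicon:
    """Set-difference curation; idempotent; records the applied list id."""
    excl = {canonicalize_term(e) for e in exclusions}
    kept = frozenset(lexicon.terms - excl)
    applied = lexicon.exclusions_applied
    if list_id not in applied:
        applied = applied + (list_id,)
    return replace(
        lexicon,
        terms=kept,
        provenance={t: p for t, p in lexicon.provenance.items() if t in kept},
        exclusions_applied=applied,
    )


def normalize_drug_name(name: str, synonyms: SynonymMap, drugs: Lexicon) -> str | None:
    """Map a surface drug name to its canonical generic name.

    Trade names go through the synonym map; names already generic (lexicon
    members) pass through; anything else is no-match (None).
    """
    folded = canonicalize_term(name)
    if folded in synonyms.mapping:
        return synonyms.mapping[folded]
    if folded in drugs.terms:
        return folded
    return None


def build_seed_pairs(trials, drugs: Lexicon, diseases: Lexicon, synonyms: SynonymMap) -> set:
    """Seed (drug, disease) pairs from clinical-trial registry records.

    For each trial, every drug recognized in its intervention texts is
    crossed with every disease recognized in its condition texts.
    Recognition uses the tagger's dictionary-matching rule on each free-text
    field (so "Tamoxifen 20 mg" still yields tamoxifen), trade names are
    normalized to generic, and pairs are deduplicated globally.
    """
    from treatminer.pattern_miner import DrugDiseasePair
    from treatminer.tagger import build_matchers

    drug_matcher, disease_matcher = build_matchers(drugs, diseases, synonyms)
    pairs: set[DrugDiseasePair] = set()
    n_empty = 0
    for trial in trials:
        trial_drugs: set[str] = set()
        for text in trial.intervention_texts:
            trial_drugs.update(c for _, _, c in drug_matcher.find_all(text))
        trial_diseases: set[str] = set()
        for text in trial.condition_texts:
            trial_diseases.update(c for _, _, c in disease_matcher.find_all(text))
        if not trial_drugs or not trial_diseases:
            n_empty += 1
            continue
        for d in trial_drugs:
            for z in trial_diseases:
                pairs.add(DrugDiseasePair(d, z))
    if n_empty:
        logger.info("%d trial(s) contributed no seed pair", n_empty)
    return pairs


# -- TSV interfaces ---------------------------------------------------------

def write_lexicon_tsv(lexicon: Lexicon, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term\tsources\n")
        for term in sorted(lexicon.terms):
            sources = ",".join(lexicon.provenance.get(term, ()))
            fh.write(f"{term}\t{sources}\n")


def load_lexicon_tsv(path, entity_type: EntityType) -> Lexicon:
    provenance: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "term" not in header:
            raise ValueError(f"lexicon TSV {path!s} missing column 'term'")
        term_i = header.index("term")
        src_i = header.index("sources") if "sources" in header else None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            term = canonicalize_term(fields[term_i])
            srcs = ()
            if src_i is not None and len(fields) > src_i and fields[src_i]:
                srcs = tuple(fields[src_i].split(","))
            provenance[term] = srcs
    return Lexicon(entity_type=entity_type, terms=frozenset(provenance), provenance=provenance)


def load_synonyms_tsv(path) -> SynonymMap:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["trade", "generic"]:
            raise ValueError(f"synonym TSV {path!s} must have columns trade, generic")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            pairs.append((fields[0], fields[1]))
    return SynonymMap.from_pairs(pairs)


def load_exclusions_tsv(path) -> list[str]:
    terms = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "term" not in header:
            raise ValueError(f"exclusion TSV {path!s} missing column 'term'")
        term_i = header.index("term")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            terms.append(canonicalize_term(line.split("\t")[term_i]))
    return terms
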