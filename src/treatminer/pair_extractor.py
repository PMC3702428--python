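"""Pair extraction with curated treatment-specific patterns.

A (drug, disease) pair is extracted when some sentence links the two
mentions by a pattern in the selected set, with the selected orientation:
a DRUG_FIRST "in" never fires on "DISEASE in DRUG".  Support counts
distinct sentences, mirroring the sentence-level co-occurrence frequency
used for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from treatminer.pattern_miner import (
    DrugDiseasePair,
    Pattern,
    extract_pattern_observations,
)
from treatminer.tagger import TaggedSentence


@dataclass(frozen=True)
class ExtractedPair:
    pair: DrugDiseasePair
    support: int
    matched_patterns: frozenset[Pattern]
    provenance: tuple[tuple[str, int], ...]  # (doc_id, sentence_index)

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if self.support != len(set(self.provenance)):
            raise ValueError("support must equal the number of distinct provenance entries")


def extract_pairs(
    tagged: Iterable[TaggedSentence], selected: set[Pattern]
) -> list[ExtractedPair]:
    """Extract pairs linked by a selected pattern, aggregated per pair.

    Output order is deterministic: descending support, then lexicographic
    (drug, disease).
    """
    if not selected:
        raise ValueError("selected pattern set must be non-empty")
    sentences: dict[DrugDiseasePair, set[tuple[str, int]]] = {}
    patterns: dict[DrugDiseasePair, set[Pattern]] = {}
    for ts in tagged:
        for obs in extract_pattern_observations(ts):
            if obs.pattern in selected:
                sentences.setdefault(obs.pair, set()).add((obs.doc_id, obs.sentence_index))
                patterns.setdefault(obs.pair, set()).add(obs.pattern)
    out = [
        ExtractedPair(
            pair=pair,
            support=len(provs),
            matched_patterns=frozenset(patterns[pair]),
            provenance=tuple(sorted(provs)),
        )
        for pair, provs in sentences.items()
    ]
    out.sort(key=lambda e: (-e.support, e.pair.drug, e.pair.disease))
    return out


def partition_novel(
    extracted: Sequence[ExtractedPair], seeds: set[DrugDiseasePair]
) -> tuple[list[ExtractedPair], list[ExtractedPair]]:
    """Split extracted pairs into (known-in-seeds, novel); a disjoint partition."""
    known = [e for e in extracted if e.pair in seeds]
    novel = [e for e in extracted if e.pair not in seeds]
    return known, novel


def per_pattern_summary(
    tagged: Iterable[TaggedSentence],
    selected: set[Pattern],
    seeds: set[DrugDiseasePair],
) -> list[tuple[Pattern, int, int, int]]:
    """(pattern, n_pairs_total, n_pairs_seed, n_pairs_novel) per selected pattern.

    The per-pattern view of how many of a pattern's distinct pairs were
    already known from the seed registry versus newly found in the corpus.
    """
    pairs_by_pattern: dict[Pattern, set[DrugDiseasePair]] = {p: set() for p in selected}
    for ts in tagged:
        for obs in extract_pattern_observations(ts):
            if obs.pattern in selected:
                pairs_by_pattern[obs.pattern].add(obs.pair)
    rows = []
    for pattern in sorted(selected):
        pairs = pairs_by_pattern[pattern]
        n_seed = len(pairs & seeds)
        rows.append((pattern, len(pairs), n_seed, len(pairs) - n_seed))
    return rows


# -- TSV interfaces ---------------------------------------------------------

def write_extracted_tsv(extracted: Sequence[ExtractedPair], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug\tdisease\tsupport\tpatterns\tn_provenance\n")
        for e in extracted:
            pats = ",".join(p.infix for p in sorted(e.matched_patterns))
            fh.write(
                f"{e.pair.drug}\t{e.pair.disease}\t{e.support}\t{pats}\t{len(e.provenance)}\n"
            )


def write_per_pattern_tsv(rows: Sequence[tuple[Pattern, int, int, int]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("orientation\tinfix\tn_pairs_total\tn_pairs_seed\tn_pairs_novel\n")
        for pattern, total, n_seed, n_novel in rows:
            fh.write(f"{pattern.orientation}\t{pattern.infix}\t{total}\t{n_seed}\t{n_novel}\n")
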